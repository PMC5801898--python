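import numpy as np
import pytest

from antmosaic.checkerboard import checkerboard_units, summed_cu
from antmosaic.data import (
    GroupedIncidence,
    IncidenceMatrix,
    ValidationError,
    grouped_incidence,
)
from antmosaic.nullmodels import SamplerConfig, null_cu_distribution
from antmosaic.segregation import (
    BetweenTreeSegregation,
    TestConfig,
    WithinTreeSegregation,
    apply_virtual_grouping,
    between_group_test,
    build_virtual_grouping,
    full_matrix,
    mc_p_value,
    within_group_test,
)
from antmosaic.simulate import MosaicParams, generate_mosaic, generate_null_community

from .conftest import random_incidence


def grouped_from(cells_list):
    groups = []
    universe = set()
    for g, cells in enumerate(cells_list):
        cells = np.asarray(cells, dtype=np.uint8)
        ids = tuple(f"sp{i}" for i in range(cells.shape[0]))
        universe.update(ids)
        m = IncidenceMatrix(ids, tuple(f"g{g}_s{j}" for j in range(cells.shape[1])), cells)
        groups.append((f"g{g}", m))
    return GroupedIncidence(tuple(groups), tuple(sorted(universe)))


class TestPValue:
    def test_add_one_formula(self):
        nulls = np.arange(10)  # observed 9 ties the max
        assert mc_p_value(9, nulls) == pytest.approx(2 / 11)
        assert mc_p_value(100, nulls) == pytest.approx(1 / 11)
        assert mc_p_value(-1, nulls) == 1.0

    def test_monotone_in_observed(self, rng):
        nulls = rng.integers(0, 50, size=200)
        ps = [mc_p_value(o, nulls) for o in range(-1, 55)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bounds(self, rng):
        nulls = rng.integers(0, 50, size=200)
        for o in (-5, 0, 25, 100):
            assert 0 < mc_p_value(o, nulls) <= 1


class TestWithinGroupTest:
    def test_all_ones_groups_degenerate_p_one(self):
        grouped = grouped_from([np.ones((3, 3)), np.ones((2, 4))])
        res = within_group_test(grouped, TestConfig(n_null=100), seed=0)
        assert res.p_value == 1.0
        assert (res.null_cus == res.observed_cu).all()

    def test_observed_at_class_maximum_gives_tiny_p(self):
        """Groups whose sub-matrix maximizes CU over its whole margin class:
        the observed sum sits at the extreme upper tail of the null."""
        from antmosaic.nullmodels import enumerate_margin_class

        members = enumerate_margin_class([2, 2, 2], [2, 2, 1, 1], max_cells=20)
        cus = [
            checkerboard_units(
                IncidenceMatrix(("a", "b", "c"), ("w", "x", "y", "z"), m)
            ).total_cu
            for m in members
        ]
        block = members[int(np.argmax(cus))]
        grouped = grouped_from([block] * 6)
        res = within_group_test(grouped, TestConfig(n_null=1000), seed=1)
        assert res.observed_cu == 6 * max(cus)
        assert res.p_value < 0.005

    def test_single_group_reduces_to_plain_permutation_test(self, rng):
        m = random_incidence(rng, 8, 8)
        grouped = GroupedIncidence((("g0", m),), m.species_ids)
        cfg = TestConfig(n_null=300)
        res = within_group_test(grouped, cfg, seed=5)
        ss = np.random.SeedSequence(5)
        child = ss.spawn(1)[0]
        nulls = null_cu_distribution(m.drop_empty_species(), 300, cfg.sampler, child)
        assert res.null_cus.tolist() == nulls.tolist()
        assert res.observed_cu == checkerboard_units(m).total_cu

    def test_reproducible_including_null_draws(self, rng):
        t = generate_null_community(n_groups=4, samples_per_group=5, n_species=8,
                                    occupancy=0.4, seed=3)
        grouped = grouped_incidence(t)
        a = within_group_test(grouped, TestConfig(n_null=100), seed=9)
        b = within_group_test(grouped, TestConfig(n_null=100), seed=9)
        assert a.null_cus.tolist() == b.null_cus.tolist()
        assert a.p_value == b.p_value


class TestVirtualGrouping:
    @pytest.mark.parametrize("mode", ["independent", "partition"])
    def test_no_virtual_group_repeats_a_real_group(self, mode, rng):
        t = generate_null_community(n_groups=10, samples_per_group=4, n_species=12,
                                    occupancy=0.5, seed=1)
        grouped = grouped_incidence(t)
        groups_of = {s: gid for gid, m in grouped for s in m.sample_ids}
        for seed in range(20):
            vg = build_virtual_grouping(grouped, n_virtual=10, samples_per_virtual=4,
                                        mode=mode, rng=seed)
            for members in vg.assignments.values():
                real = [groups_of[s] for s in members]
                assert len(set(real)) == len(real)

    def test_partition_uses_every_sample_exactly_once(self, rng):
        t = generate_null_community(n_groups=8, samples_per_group=6, n_species=12,
                                    occupancy=0.5, seed=2)
        grouped = grouped_incidence(t)
        all_samples = {s for _, m in grouped for s in m.sample_ids}
        for seed in range(20):
            vg = build_virtual_grouping(grouped, n_virtual=12, samples_per_virtual=4,
                                        mode="partition", rng=seed)
            used = [s for members in vg.assignments.values() for s in members]
            assert sorted(used) == sorted(all_samples)

    def test_square_partition_forces_one_sample_per_real_group(self):
        t = generate_null_community(n_groups=6, samples_per_group=6, n_species=10,
                                    occupancy=0.5, seed=4)
        grouped = grouped_incidence(t)
        groups_of = {s: gid for gid, m in grouped for s in m.sample_ids}
        vg = build_virtual_grouping(grouped, n_virtual=6, samples_per_virtual=6,
                                    mode="partition", rng=0)
        for members in vg.assignments.values():
            assert sorted({groups_of[s] for s in members}) == grouped.group_ids

    def test_oversized_virtual_group_rejected(self, small_grouped):
        with pytest.raises(ValidationError, match="distinct real groups"):
            build_virtual_grouping(small_grouped, n_virtual=2, samples_per_virtual=5)

    def test_infeasible_partition_count_rejected(self, small_grouped):
        with pytest.raises(ValidationError, match="partition"):
            build_virtual_grouping(small_grouped, n_virtual=3, samples_per_virtual=2,
                                   mode="partition")


class TestFullMatrixRoundTrip:
    def test_regrouping_preserves_fill_and_richness(self, rng):
        t = generate_null_community(n_groups=6, samples_per_group=4, n_species=10,
                                    occupancy=0.4, seed=8)
        grouped = grouped_incidence(t)
        full = full_matrix(grouped)
        assert full.fill == sum(m.fill for _, m in grouped)
        vg = build_virtual_grouping(grouped, mode="partition",
                                    n_virtual=8, samples_per_virtual=3, rng=1)
        regrouped = apply_virtual_grouping(grouped, vg)
        assert sum(m.fill for _, m in regrouped) == full.fill


class TestBetweenGroupTest:
    def test_saturated_community_gives_p_one(self):
        grouped = grouped_from([np.ones((3, 3)), np.ones((3, 3)), np.ones((3, 3))])
        res = between_group_test(
            grouped, TestConfig(n_null=50, n_virtual_repeats=3), seed=0
        )
        assert res.p_value == 1.0
        assert all(r.p_value == 1.0 for r in res.per_repeat)

    def test_single_repeat_is_one_within_test_on_virtual_grouping(self, rng):
        t = generate_null_community(n_groups=6, samples_per_group=4, n_species=10,
                                    occupancy=0.4, seed=6)
        grouped = grouped_incidence(t)
        cfg = TestConfig(n_null=200, n_virtual_repeats=1)
        res = between_group_test(grouped, cfg, seed=11)
        assert len(res.per_repeat) == 1
        assert res.p_value == res.per_repeat[0].p_value
        assert res.p_value == mc_p_value(res.observed_cu, res.null_cus)

    def test_mean_of_repeat_p_values(self, rng):
        t = generate_null_community(n_groups=6, samples_per_group=4, n_species=10,
                                    occupancy=0.4, seed=7)
        grouped = grouped_incidence(t)
        res = between_group_test(grouped, TestConfig(n_null=100, n_virtual_repeats=5), seed=3)
        assert res.p_value == pytest.approx(np.mean([r.p_value for r in res.per_repeat]))

    def test_repeat_p_values_roughly_uniform_on_identical_groups(self):
        """No false segregation from the virtual-tree machinery itself:
        on exchangeable data the per-repeat p-values behave uniformly."""
        t = generate_null_community(n_groups=12, samples_per_group=6, n_species=15,
                                    occupancy=0.35, seed=21)
        grouped = grouped_incidence(t)
        ps = []
        for seed in range(8):
            res = between_group_test(
                grouped, TestConfig(n_null=200, n_virtual_repeats=5), seed=seed
            )
            ps.extend(r.p_value for r in res.per_repeat)
        ps = np.asarray(ps)
        assert 0.15 < ps.mean() < 0.85
        assert ps.min() < 0.5 < ps.max()

    def test_full_reproducibility(self):
        t = generate_null_community(n_groups=5, samples_per_group=4, n_species=8,
                                    occupancy=0.4, seed=13)
        grouped = grouped_incidence(t)
        cfg = TestConfig(n_null=100, n_virtual_repeats=3)
        a = between_group_test(grouped, cfg, seed=17)
        b = between_group_test(grouped, cfg, seed=17)
        assert a.p_value == b.p_value
        assert a.null_cus.tolist() == b.null_cus.tolist()
        assert [r.observed_cu for r in a.per_repeat] == [r.observed_cu for r in b.per_repeat]


class TestModels:
    def test_model_fit_matches_functional_api(self):
        table, _ = generate_mosaic(MosaicParams(n_groups=5, samples_per_group=4,
                                                n_subordinates=10), seed=31)
        cfg = TestConfig(n_null=100, n_virtual_repeats=2)
        model = WithinTreeSegregation.from_table(table, config=cfg)
        res = model.fit(seed=2)
        direct = within_group_test(grouped_incidence(table), cfg, seed=2)
        assert res.p_value == direct.p_value
        assert model.observed_cu == direct.observed_cu

        bmodel = BetweenTreeSegregation.from_dataframe(table.records, config=cfg)
        bres = bmodel.fit(seed=2)
        bdirect = between_group_test(grouped_incidence(table), cfg, seed=2)
        assert bres.p_value == bdirect.p_value

    def test_results_summary_and_serialization(self):
        table, _ = generate_mosaic(MosaicParams(n_groups=5, samples_per_group=4,
                                                n_subordinates=10), seed=32)
        res = BetweenTreeSegregation.from_table(
            table, config=TestConfig(n_null=50, n_virtual_repeats=2)
        ).fit(seed=1)
        text = res.summary()
        assert "between" in text and "p-value" in text
        d = res.to_dict()
        assert d["scale"] == "between"
        assert len(d["null_cus"]) == 50
        assert len(d["per_repeat"]) == 2
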