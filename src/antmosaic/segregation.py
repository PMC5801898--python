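"""Permutation tests for species segregation at two spatial scales.

Within-group scale: checkerboard units are counted inside every group
(tree) and summed; the null distribution is obtained by randomizing each
group's sub-matrix independently under the fixed-fixed constraint and
re-summing, and the p-value is the upper-tail probability of the observed
sum.  Randomization never crosses group boundaries.

Between-group scale: "virtual trees" are assembled by drawing samples from
distinct real groups, so that the within-group machinery applied to the
virtual grouping probes co-occurrence *between* real groups while keeping
sample size and matrix structure — hence statistical power — identical to
the within-scale test.  The virtual-tree construction is repeated
(default 10 times) and the resulting p-values averaged.

Both tests are exposed functionally (:func:`within_group_test`,
:func:`between_group_test`) and as model classes
(:class:`WithinTreeSegregation`, :class:`BetweenTreeSegregation`) whose
``fit()`` returns a :class:`SegregationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .checkerboard import checkerboard_units, summed_cu
from .data import (
    AbundanceTable,
    GroupedIncidence,
    IncidenceMatrix,
    ValidationError,
    grouped_incidence,
)
from .nullmodels import SamplerConfig, null_cu_distribution

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class TestConfig:
    """Configuration shared by both segregation tests.

    n_null is the number of null matrices per test (1,000 in the original
    field analysis); n_virtual_repeats the number of independent
    virtual-tree constructions whose p-values are averaged (10).
    """

    n_null: int = 1000
    n_virtual_repeats: int = 10
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    virtual_mode: str = "independent"
    n_virtual: int | None = None
    samples_per_virtual: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.n_virtual_repeats < 1:
            raise ValueError("n_virtual_repeats must be >= 1")
        if self.virtual_mode not in ("independent", "partition"):
            raise ValueError("virtual_mode must be 'independent' or 'partition'")


@dataclass(frozen=True)
class VirtualGrouping:
    """Assignment of real samples to virtual groups.

    Invariant: within every virtual group all samples come from distinct
    real groups; in partition mode every sample is used exactly once.
    """

    assignments: dict[str, list[str]]
    mode: str
    seed: int | None = None


def mc_p_value(observed: float, null_values: np.ndarray) -> float:
    """Upper-tail Monte-Carlo p-value with the add-one correction.

    p = (1 + #{null >= observed}) / (1 + n_null): the probability of
    obtaining the observed count or more under the null, never exactly 0.
    """
    null_values = np.asarray(null_values)
    return float((1 + int((null_values >= observed).sum())) / (1 + null_values.size))


@dataclass(frozen=True)
class RepeatResult:
    """One virtual-tree construction: its observed summed CU and p-value."""

    observed_cu: int
    p_value: float


@dataclass
class SegregationResults:
    """Result of a segregation permutation test.

    For the between scale, ``observed_cu`` and ``null_cus`` belong to the
    first virtual-tree repeat (one example construction, as plotted in the
    field analysis) while ``p_value`` is the mean over all repeats, which
    are retained in ``per_repeat``.
    """

    scale: str
    observed_cu: int
    null_cus: np.ndarray
    p_value: float
    config: TestConfig
    seed: int | None
    per_repeat: list[RepeatResult] | None = None
    n_groups: int = 0
    n_samples: int = 0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_cus))

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05

    def to_dict(self) -> dict:
        out = {
            "scale": self.scale,
            "observed_cu": int(self.observed_cu),
            "p_value": self.p_value,
            "null_cus": [int(v) for v in self.null_cus],
            "n_groups": self.n_groups,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "config": {
                "n_null": self.config.n_null,
                "n_virtual_repeats": self.config.n_virtual_repeats,
                "virtual_mode": self.config.virtual_mode,
                "sampler": {
                    "algorithm": self.config.sampler.algorithm,
                    "n_steps": self.config.sampler.n_steps,
                    "burn_in": self.config.sampler.burn_in,
                    "independent_draws": self.config.sampler.independent_draws,
                },
            },
        }
        if self.per_repeat is not None:
            out["per_repeat"] = [
                {"observed_cu": r.observed_cu, "p_value": r.p_value} for r in self.per_repeat
            ]
        return out

    def summary(self) -> str:
        lines = [
            f"Species segregation test ({self.scale}-group scale)",
            "=" * 52,
            f"groups: {self.n_groups}    samples: {self.n_samples}",
            f"observed summed CU:    {self.observed_cu}",
            f"null mean (n={len(self.null_cus)}): {self.null_mean:.1f}",
            f"null range:            [{int(self.null_cus.min())}, {int(self.null_cus.max())}]",
            f"p-value (upper tail):  {self.p_value:.4g}",
        ]
        if self.per_repeat is not None:
            ps = ", ".join(f"{r.p_value:.3g}" for r in self.per_repeat)
            lines.append(f"per-repeat p-values:   {ps}")
            lines.append("(p-value above is their mean; histogram fields show repeat 1)")
        lines.append(
            "segregated at alpha=0.05" if self.significant else "not segregated at alpha=0.05"
        )
        return "\n".join(lines)

    def plot_null(self, ax=None, **kwargs):
        """Histogram of the null CU distribution with the observed count."""
        from .plotting import plot_null_distribution

        return plot_null_distribution(self, ax=ax, **kwargs)


# -- within-group test ---------------------------------------------------------


def _null_summed_distribution(
    grouped: GroupedIncidence, n_null: int, sampler: SamplerConfig, ss: np.random.SeedSequence
) -> np.ndarray:
    totals = np.zeros(n_null, dtype=np.int64)
    children = ss.spawn(len(grouped))
    for (gid, mat), child in zip(grouped, children):
        totals += null_cu_distribution(mat.drop_empty_species(), n_null, sampler, child)
    return totals


def within_group_test(
    grouped: GroupedIncidence, config: TestConfig | None = None, seed: int | None = None
) -> SegregationResults:
    """Within-group segregation test on summed checkerboard units.

    Each null replicate randomizes every group's sub-matrix independently
    under the fixed-fixed constraint and sums CUs across groups; the
    p-value is upper-tail with the add-one correction.  Deterministic
    given the seed.
    """
    config = config or TestConfig()
    if seed is None:
        seed = config.seed
    if len(grouped) < 1:
        raise ValidationError("within_group_test needs at least one group")
    observed = summed_cu(grouped)
    ss = np.random.SeedSequence(seed if seed is not None else None)
    nulls = _null_summed_distribution(grouped, config.n_null, config.sampler, ss)
    return SegregationResults(
        scale="within",
        observed_cu=observed,
        null_cus=nulls,
        p_value=mc_p_value(observed, nulls),
        config=config,
        seed=seed,
        n_groups=len(grouped),
        n_samples=grouped.total_samples,
    )


# -- virtual trees -------------------------------------------------------------


def _group_sizes(grouped: GroupedIncidence) -> list[int]:
    return [mat.n_samples for _, mat in grouped]


def _default_virtual_shape(grouped: GroupedIncidence) -> tuple[int, int]:
    sizes = _group_sizes(grouped)
    return len(grouped), min(min(sizes), len(grouped))


def build_virtual_grouping(
    grouped: GroupedIncidence,
    n_virtual: int | None = None,
    samples_per_virtual: int | None = None,
    mode: str = "independent",
    rng: np.random.Generator | int | None = None,
    max_restarts: int = 1000,
) -> VirtualGrouping:
    """Assemble virtual groups from samples of distinct real groups.

    independent mode: each virtual group draws ``samples_per_virtual``
    distinct real groups uniformly without replacement and takes one
    uniformly chosen sample from each; samples may recur across virtual
    groups.  partition mode: a feasible partition in which every sample is
    used exactly once (requires n_virtual * samples_per_virtual == total
    samples), built by random sequential assignment with restart on
    dead-ends.
    """
    if n_virtual is None or samples_per_virtual is None:
        d_nv, d_spv = _default_virtual_shape(grouped)
        n_virtual = n_virtual if n_virtual is not None else d_nv
        samples_per_virtual = samples_per_virtual if samples_per_virtual is not None else d_spv
    if samples_per_virtual > len(grouped):
        raise ValidationError(
            f"samples_per_virtual={samples_per_virtual} exceeds the number of real groups"
            f" ({len(grouped)}): virtual groups must draw from distinct real groups"
        )
    seed_echo = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    gids = grouped.group_ids
    samples = {gid: list(mat.sample_ids) for gid, mat in grouped}
    width = len(str(max(1, n_virtual - 1)))

    def vid(v: int) -> str:
        return f"V{v:0{width}d}"

    if mode == "independent":
        assignments: dict[str, list[str]] = {}
        for v in range(n_virtual):
            chosen = rng.choice(len(gids), size=samples_per_virtual, replace=False)
            assignments[vid(v)] = [
                samples[gids[g]][rng.integers(len(samples[gids[g]]))] for g in chosen
            ]
        return VirtualGrouping(assignments, "independent", seed_echo)

    if mode == "partition":
        total = grouped.total_samples
        if n_virtual * samples_per_virtual != total:
            raise ValidationError(
                f"partition mode needs n_virtual * samples_per_virtual == total samples "
                f"({n_virtual} * {samples_per_virtual} != {total})"
            )
        if max(_group_sizes(grouped)) > n_virtual:
            raise ValidationError(
                "partition infeasible: some real group has more samples than there are "
                "virtual groups, so two of its samples would share a virtual group"
            )
        for _ in range(max_restarts):
            capacity = np.full(n_virtual, samples_per_virtual, dtype=np.int64)
            assignments = {vid(v): [] for v in range(n_virtual)}
            order = rng.permutation(len(gids))
            ok = True
            for step, gi in enumerate(order):
                gid = gids[gi]
                g_samples = list(samples[gid])
                rng.shuffle(g_samples)
                k = len(g_samples)
                remaining_groups = len(gids) - step
                open_v = np.flatnonzero(capacity > 0)
                # a virtual group whose remaining capacity equals the number
                # of real groups left must receive a sample from every one
                # of them (each group contributes at most one)
                forced = open_v[capacity[open_v] >= remaining_groups]
                if len(open_v) < k or len(forced) > k:
                    ok = False
                    break
                rest = np.setdiff1d(open_v, forced)
                need = k - len(forced)
                if need:
                    weights = capacity[rest] / capacity[rest].sum()
                    extra = rng.choice(rest, size=need, replace=False, p=weights)
                else:
                    extra = np.array([], dtype=np.int64)
                chosen_v = rng.permutation(np.concatenate([forced, extra]))
                for s, v in zip(g_samples, chosen_v):
                    assignments[vid(int(v))].append(s)
                    capacity[v] -= 1
            if ok and (capacity == 0).all():
                return VirtualGrouping(assignments, "partition", seed_echo)
        raise ValidationError(
            f"no feasible partition found in {max_restarts} restarts: "
            "check that group sizes admit a one-sample-per-real-group partition"
        )

    raise ValidationError(f"unknown virtual mode {mode!r}")


def full_matrix(grouped: GroupedIncidence) -> IncidenceMatrix:
    """Reassemble the full incidence matrix over the shared species universe."""
    universe = list(grouped.species_universe)
    u_index = {s: i for i, s in enumerate(universe)}
    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    for gid, mat in grouped:
        block = np.zeros((len(universe), mat.n_samples), dtype=np.uint8)
        rows = [u_index[s] for s in mat.species_ids]
        block[rows] = mat.cells
        cols.append(block)
        sample_ids.extend(mat.sample_ids)
    cells = np.concatenate(cols, axis=1) if cols else np.zeros((len(universe), 0), np.uint8)
    return IncidenceMatrix(tuple(universe), tuple(sample_ids), cells)


def apply_virtual_grouping(
    grouped: GroupedIncidence, virtual: VirtualGrouping
) -> GroupedIncidence:
    """Re-slice the incidence data into virtual sub-matrices.

    Species absent from a virtual group are dropped from its sub-matrix,
    mirroring the treatment of real groups.  In independent mode a sample
    may serve in several virtual groups, so sample ids are namespaced by
    virtual group id to keep them globally unique.
    """
    full = full_matrix(grouped)
    vgroups = []
    for v in sorted(virtual.assignments):
        sub = full.select_samples(sorted(virtual.assignments[v])).drop_empty_species()
        if virtual.mode == "independent":
            sub = IncidenceMatrix(
                sub.species_ids,
                tuple(f"{v}:{s}" for s in sub.sample_ids),
                sub.cells,
            )
        vgroups.append((v, sub))
    return GroupedIncidence(tuple(vgroups), full.species_ids)


def between_group_test(
    grouped: GroupedIncidence, config: TestConfig | None = None, seed: int | None = None
) -> SegregationResults:
    """Between-group segregation test via repeated virtual-tree resampling.

    Builds ``n_virtual_repeats`` independent virtual groupings, runs the
    within-group test on each, and averages the p-values.  The reported
    histogram fields (observed_cu, null_cus) are those of the first
    repeat.
    """
    config = config or TestConfig()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed if seed is not None else None)
    repeats: list[RepeatResult] = []
    first: SegregationResults | None = None
    n_v = config.n_virtual
    spv = config.samples_per_virtual
    for child in ss.spawn(config.n_virtual_repeats):
        build_ss, test_ss = child.spawn(2)
        virtual = build_virtual_grouping(
            grouped,
            n_virtual=n_v,
            samples_per_virtual=spv,
            mode=config.virtual_mode,
            rng=np.random.default_rng(build_ss),
        )
        vgrouped = apply_virtual_grouping(grouped, virtual)
        observed = summed_cu(vgrouped)
        nulls = _null_summed_distribution(vgrouped, config.n_null, config.sampler, test_ss)
        p = mc_p_value(observed, nulls)
        repeats.append(RepeatResult(observed, p))
        if first is None:
            first = SegregationResults(
                scale="between",
                observed_cu=observed,
                null_cus=nulls,
                p_value=p,
                config=config,
                seed=seed,
                n_groups=len(vgrouped),
                n_samples=vgrouped.total_samples,
            )
    assert first is not None
    first.per_repeat = repeats
    first.p_value = float(np.mean([r.p_value for r in repeats]))
    return first


# -- model classes -------------------------------------------------------------


class _SegregationModel:
    """Shared scaffolding for the two segregation models."""

    scale: str = ""

    def __init__(self, grouped: GroupedIncidence, config: TestConfig | None = None):
        self.grouped = grouped
        self.config = config or TestConfig()

    @classmethod
    def from_table(cls, table: AbundanceTable, presence_threshold: int = 1, **kwargs):
        """Build the model from a long-form abundance table."""
        return cls(grouped_incidence(table, presence_threshold), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, presence_threshold: int = 1, **kwargs):
        """Build the model from a long-form records DataFrame."""
        return cls.from_table(AbundanceTable(df), presence_threshold, **kwargs)

    @property
    def observed_cu(self) -> int:
        return summed_cu(self.grouped)

    def fit(self, seed: int | None = None) -> SegregationResults:
        raise NotImplementedError


class WithinTreeSegregation(_SegregationModel):
    """Within-group (within-tree) co-occurrence segregation model.

    ``fit()`` runs the summed-CU permutation test with within-group
    fixed-fixed randomization.
    """

    scale = "within"

    def fit(self, seed: int | None = None) -> SegregationResults:
        return within_group_test(self.grouped, self.config, seed=seed)


class BetweenTreeSegregation(_SegregationModel):
    """Between-group (between-tree) segregation model via virtual trees."""

    scale = "between"

    def fit(self, seed: int | None = None) -> SegregationResults:
        return between_group_test(self.grouped, self.config, seed=seed)
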