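import numpy as np
import pandas as pd
import pytest

from antmosaic.data import AbundanceTable, IncidenceMatrix, grouped_incidence


def make_table(rows):
    cols = ["sample_id", "group_id", "method", "time", "species_id", "count"]
    return AbundanceTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def small_table():
    """Two trees x two bait samples, three species, skewed counts."""
    return make_table(
        [
            ("t1_s1", "t1", "bait", "day", "spA", 5),
            ("t1_s1", "t1", "bait", "day", "spB", 1),
            ("t1_s2", "t1", "bait", "day", "spA", 2),
            ("t2_s1", "t2", "bait", "day", "spB", 7),
            ("t2_s2", "t2", "bait", "day", "spC", 3),
        ]
    )


@pytest.fixture
def small_grouped(small_table):
    return grouped_incidence(small_table)


def random_incidence(rng, n_species, n_samples, fill=0.4):
    cells = (rng.random((n_species, n_samples)) < fill).astype(np.uint8)
    return IncidenceMatrix(
        tuple(f"sp{i}" for i in range(n_species)),
        tuple(f"s{j}" for j in range(n_samples)),
        cells,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
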