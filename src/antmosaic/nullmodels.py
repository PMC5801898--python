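"""Fixed-fixed null models for binary incidence matrices.

The null hypothesis of the co-occurrence analysis is that species occupy
samples at random subject to two constraints: each species keeps its number
of occurrences (row sums) and each sample keeps its species richness
(column sums).  Sampling from the set of binary matrices with both margins
fixed is done with local trade/swap Markov chains:

* ``curveball`` (default): random row pairs trade random subsets of the
  columns held by exactly one of them.  Fast-mixing and margin-exact.
* ``trial_swap``: classic 2x2 checkerboard swaps; attempts that find no
  swappable submatrix still count as steps.

``quasiswap`` is accepted as an alias for ``curveball``: both target the
same fixed-fixed contract, uniform sampling of the margin class.
A small exhaustive enumerator of margin classes provides the uniformity
oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import _kernels
from .data import IncidenceMatrix

_ALGORITHMS = {
    "curveball": _kernels.CURVEBALL,
    "quasiswap": _kernels.CURVEBALL,
    "quasiswap_like": _kernels.CURVEBALL,
    "trial_swap": _kernels.TRIAL_SWAP,
}

#: curveball trades per draw, as a multiple of the number of species rows
STEPS_PER_ROW = 5
#: floor on steps per draw so tiny matrices still mix fully
MIN_STEPS = 50
#: trial-swap attempts per draw, as a multiple of the matrix cell count
#: (most attempts miss a swappable 2x2, so mixing per attempt is far slower)
TRIAL_SWAP_STEPS_PER_CELL = 15

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration of the fixed-fixed sampler.

    n_steps=None resolves to ``max(MIN_STEPS, STEPS_PER_ROW * n_rows)`` per
    draw — a safety margin beyond the mixing time reported for curveball
    trade chains, with a floor so tiny matrices mix fully.
    independent_draws=True restarts every null matrix from the observed one.
    """

    algorithm: str = "curveball"
    n_steps: int | None = None
    burn_in: int = 0
    seed: int | None = None
    independent_draws: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {sorted(_ALGORITHMS)}"
            )
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    def resolve_steps(self, n_rows: int, n_cols: int = 0) -> int:
        if self.n_steps is not None:
            return self.n_steps
        if self.algorithm == "trial_swap":
            return max(MIN_STEPS, TRIAL_SWAP_STEPS_PER_CELL * n_rows * max(1, n_cols))
        return max(MIN_STEPS, STEPS_PER_ROW * n_rows)


def _seed_from(rng_or_seed) -> int:
    """Derive a 31-bit kernel seed from a Generator, SeedSequence or int."""
    if isinstance(rng_or_seed, np.random.Generator):
        return int(rng_or_seed.integers(0, _SEED_MOD))
    if isinstance(rng_or_seed, np.random.SeedSequence):
        return int(rng_or_seed.generate_state(1)[0] % _SEED_MOD)
    if rng_or_seed is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % _SEED_MOD)
    return int(rng_or_seed) % _SEED_MOD


def randomize_fixed_fixed(
    matrix: IncidenceMatrix,
    config: SamplerConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> IncidenceMatrix:
    """Draw one random binary matrix with the same row and column sums.

    Degenerate inputs (fewer than two species or samples, or a matrix that
    is the unique member of its margin class, e.g. all-ones) are returned
    unchanged — such sub-matrices are common in sparse per-tree data.
    """
    config = config or SamplerConfig()
    n_rows, n_cols = matrix.n_species, matrix.n_samples
    if n_rows < 2 or n_cols < 2:
        return matrix
    seed = _seed_from(rng if rng is not None else config.seed)
    base = _kernels.pack_rows(matrix.cells)
    words = _kernels.randomize_masks(
        base,
        n_rows,
        base.shape[1],
        n_cols,
        config.resolve_steps(n_rows, n_cols),
        config.burn_in,
        _ALGORITHMS[config.algorithm],
        seed,
    )
    cells = _kernels.unpack_rows(words, n_cols)
    return IncidenceMatrix(matrix.species_ids, matrix.sample_ids, cells)


def null_cu_distribution(
    matrix: IncidenceMatrix,
    n_null: int,
    config: SamplerConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Checkerboard-unit counts of ``n_null`` fixed-fixed randomizations.

    The counting runs inside the randomization kernel, so this is the fast
    path used by the permutation tests.  For degenerate matrices the
    distribution is constant at the observed count.
    """
    from .checkerboard import checkerboard_units  # local: avoid cycle

    config = config or SamplerConfig()
    n_rows, n_cols = matrix.n_species, matrix.n_samples
    if n_rows < 2 or n_cols < 2:
        return np.full(n_null, checkerboard_units(matrix).total_cu, dtype=np.int64)
    seed = _seed_from(rng if rng is not None else config.seed)
    base = _kernels.pack_rows(matrix.cells)
    return _kernels.null_cu_distribution(
        base,
        n_rows,
        base.shape[1],
        n_cols,
        n_null,
        config.resolve_steps(n_rows, n_cols),
        config.burn_in,
        _ALGORITHMS[config.algorithm],
        config.independent_draws,
        seed,
    )


def sample_margin_class(
    matrix: IncidenceMatrix,
    n_draws: int,
    config: SamplerConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Stack of ``n_draws`` randomized binary matrices (for diagnostics)."""
    config = config or SamplerConfig()
    n_rows, n_cols = matrix.n_species, matrix.n_samples
    if n_rows < 2 or n_cols < 2:
        return np.broadcast_to(matrix.cells, (n_draws, n_rows, n_cols)).copy()
    seed = _seed_from(rng if rng is not None else config.seed)
    base = _kernels.pack_rows(matrix.cells)
    words = _kernels.null_draws(
        base,
        n_rows,
        base.shape[1],
        n_cols,
        n_draws,
        config.resolve_steps(n_rows, n_cols),
        config.burn_in,
        _ALGORITHMS[config.algorithm],
        config.independent_draws,
        seed,
    )
    return np.stack([_kernels.unpack_rows(w, n_cols) for w in words])


def enumerate_margin_class(
    row_sums, col_sums, max_cells: int = 25
) -> list[np.ndarray]:
    """Exhaustively enumerate binary matrices with the given margins.

    Backtracking over rows; returns an empty list for infeasible margins
    (Gale-Ryser violated).  Guarded to tiny matrices — this is the
    uniformity oracle for the sampler, not a production path.
    """
    row_sums = [int(r) for r in row_sums]
    col_sums = [int(c) for c in col_sums]
    n_rows, n_cols = len(row_sums), len(col_sums)
    if n_rows * n_cols > max_cells:
        raise ValueError(
            f"margin class {n_rows}x{n_cols} exceeds the {max_cells}-cell enumeration guard"
        )
    if sum(row_sums) != sum(col_sums):
        return []
    if any(r < 0 or r > n_cols for r in row_sums) or any(c < 0 or c > n_rows for c in col_sums):
        return []

    out: list[np.ndarray] = []
    mat = np.zeros((n_rows, n_cols), dtype=np.uint8)
    remaining = list(col_sums)

    def backtrack(i: int) -> None:
        if i == n_rows:
            if all(c == 0 for c in remaining):
                out.append(mat.copy())
            return
        rows_left = n_rows - i - 1
        candidates = [j for j in range(n_cols) if remaining[j] > 0]
        if len(candidates) < row_sums[i]:
            return
        for cols in combinations(candidates, row_sums[i]):
            ok = True
            for j in cols:
                remaining[j] -= 1
            # prune: no remaining column may need more than the rows left
            for j in range(n_cols):
                if remaining[j] > rows_left:
                    ok = False
                    break
            if ok:
                mat[i, list(cols)] = 1
                backtrack(i + 1)
                mat[i, list(cols)] = 0
            for j in cols:
                remaining[j] += 1

    backtrack(0)
    return out
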