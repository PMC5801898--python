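"""Checkerboard-unit statistics (Stone & Roberts) on incidence matrices.

A checkerboard unit (CU) is a 2x2 submatrix of the species x sample
incidence matrix in which each of the two samples contains exactly one,
different, species (a 1-0 / 0-1 pattern).  For a species pair (i, j) with
occurrence counts r_i, r_j sharing S_ij samples, the number of such units
is (r_i - S_ij)(r_j - S_ij); the total is summed over unordered species
pairs.  The total is deliberately NOT standardized by matrix size into a
C-score, so that counts can be summed across per-tree sub-matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GroupedIncidence, IncidenceMatrix, ValidationError


@dataclass(frozen=True)
class PairStats:
    """Checkerboard bookkeeping for one unordered species pair."""

    species_i: str
    species_j: str
    r_i: int
    r_j: int
    shared: int
    cu: int


@dataclass(frozen=True)
class CUCount:
    """Total checkerboard units, optionally with the per-pair breakdown."""

    total_cu: int
    per_pair: tuple[PairStats, ...] | None = None


def checkerboard_units(matrix: IncidenceMatrix, detail: bool = False) -> CUCount:
    """Count checkerboard units via the closed form (r_i - S_ij)(r_j - S_ij).

    Unordered species pairs and unordered sample pairs are each counted
    once.  A species present in every sample contributes nothing (S_ij
    equals the partner's occurrence count, so one factor is zero), and
    matrices with fewer than two species or samples score 0.
    """
    cells = matrix.cells
    if cells.size and not np.isin(cells, (0, 1)).all():
        raise ValidationError("checkerboard_units requires a binary matrix")
    s = matrix.n_species
    if s < 2 or matrix.n_samples < 2:
        return CUCount(0, () if detail else None)
    c = cells.astype(np.int64)
    r = c.sum(axis=1)
    shared = c @ c.T
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    iu = np.triu_indices(s, k=1)
    total = int(cu[iu].sum())
    if not detail:
        return CUCount(total)
    pairs = tuple(
        PairStats(
            matrix.species_ids[i],
            matrix.species_ids[j],
            int(r[i]),
            int(r[j]),
            int(shared[i, j]),
            int(cu[i, j]),
        )
        for i, j in zip(*iu)
    )
    return CUCount(total, pairs)


def checkerboard_units_bruteforce(matrix: IncidenceMatrix) -> int:
    """Direct O(species^2 x samples^2) enumeration of checkerboard units.

    Independent oracle for :func:`checkerboard_units`: for every unordered
    species pair and unordered sample pair, test for the 1-0/0-1 pattern
    explicitly.  Intended for small matrices and cross-validation only.
    """
    c = matrix.cells
    s, m = c.shape
    total = 0
    for i in range(s):
        for j in range(i + 1, s):
            for a in range(m):
                for b in range(a + 1, m):
                    pattern = (c[i, a], c[i, b], c[j, a], c[j, b])
                    if pattern == (1, 0, 0, 1) or pattern == (0, 1, 1, 0):
                        total += 1
    return total


def summed_cu(grouped: GroupedIncidence) -> int:
    """Sum checkerboard units over per-group sub-matrices.

    This is the within-group observed statistic: CUs are counted inside
    each group (tree) separately and added, never across group boundaries.
    """
    return sum(checkerboard_units(mat).total_cu for _, mat in grouped)
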