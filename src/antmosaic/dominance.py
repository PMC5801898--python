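"""Numerical-dominance summaries per group (tree).

These reproduce the descriptive statistics of canopy surveys: which
species is numerically dominant on each tree, how dominant identity turns
over between sampling methods or times of day, how many trees have one
species exceeding half the total abundance, on how many trees a species is
present, and mean species richness per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .data import AbundanceTable, IncidenceMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupDominance:
    group_id: str
    top_species: str | None
    top_abundance: int
    total_abundance: int
    tie: bool

    @property
    def top_share(self) -> float:
        """Fraction of the group's total abundance held by the top species."""
        if self.total_abundance == 0:
            return 0.0
        return self.top_abundance / self.total_abundance


@dataclass(frozen=True)
class DominanceSummary:
    per_group: tuple[GroupDominance, ...]
    label: str = ""

    def group(self, group_id: str) -> GroupDominance:
        for g in self.per_group:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.per_group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": [g.group_id for g in self.per_group],
                "top_species": [g.top_species for g in self.per_group],
                "top_abundance": [g.top_abundance for g in self.per_group],
                "total_abundance": [g.total_abundance for g in self.per_group],
                "top_share": [g.top_share for g in self.per_group],
                "tie": [g.tie for g in self.per_group],
            }
        )


def most_abundant_per_group(table: AbundanceTable, label: str = "") -> DominanceSummary:
    """Most abundant species in each group, with tie flagging.

    Ties on within-group abundance are broken by larger total abundance
    across the whole dataset, then lexicographic species id; tied groups
    are flagged so downstream turnover counts stay auditable.  Groups with
    zero total abundance get ``top_species=None``.
    """
    if len(table) == 0:
        raise ValidationError("abundance table is empty")
    df = table.records
    dataset_totals = df.groupby("species_id")["count"].sum()
    per = []
    for gid, sub in df.groupby("group_id", sort=True):
        totals = sub.groupby("species_id")["count"].sum()
        totals = totals[totals > 0]
        if totals.empty:
            per.append(GroupDominance(gid, None, 0, 0, False))
            continue
        top_count = int(totals.max())
        tied = sorted(totals.index[totals == top_count])
        tie = len(tied) > 1
        # tie-break: dataset-wide abundance desc, then lexicographic asc
        winner = sorted(tied, key=lambda s: (-int(dataset_totals[s]), s))[0]
        per.append(GroupDominance(gid, winner, top_count, int(totals.sum()), tie))
    return DominanceSummary(tuple(per), label)


def dominance_turnover(
    a: DominanceSummary, b: DominanceSummary
) -> tuple[int, int, pd.DataFrame]:
    """Count groups whose numerically dominant species differs between two
    summaries (e.g. fogging vs. baiting, or day vs. night).

    Groups empty in either summary are excluded from the counts and
    reported in the detail table with ``comparable=False``.
    Returns (n_differ, n_same, per-group detail).
    """
    if set(a.group_ids) != set(b.group_ids):
        raise ValidationError(
            f"mismatched group sets: {sorted(set(a.group_ids) ^ set(b.group_ids))[:10]}"
        )
    rows = []
    n_differ = n_same = 0
    for gid in sorted(a.group_ids):
        ga, gb = a.group(gid), b.group(gid)
        comparable = ga.top_species is not None and gb.top_species is not None
        differ = comparable and ga.top_species != gb.top_species
        if comparable:
            n_differ += int(differ)
            n_same += int(not differ)
        rows.append(
            {
                "group_id": gid,
                "top_a": ga.top_species,
                "top_b": gb.top_species,
                "comparable": comparable,
                "differ": differ if comparable else None,
                "tie_a": ga.tie,
                "tie_b": gb.tie,
            }
        )
    return n_differ, n_same, pd.DataFrame(rows)


def high_dominance_count(summary: DominanceSummary, threshold: float = 0.5) -> int:
    """Number of groups where the top species holds strictly more than
    ``threshold`` of the group's total abundance ("more than 50%")."""
    return sum(
        1 for g in summary.per_group if g.total_abundance > 0 and g.top_share > threshold
    )


def presence_group_count(table: AbundanceTable, species_id: str) -> int:
    """Number of groups in which the species was recorded at all."""
    df = table.records
    if species_id not in set(df["species_id"]):
        logger.warning("species %r not found in table", species_id)
        return 0
    sub = df[(df["species_id"] == species_id) & (df["count"] > 0)]
    return int(sub["group_id"].nunique())


def mean_species_per_sample(matrix: IncidenceMatrix) -> float:
    """Mean species richness per sample, counting empty samples as zero."""
    if matrix.n_samples < 1:
        raise ValidationError("matrix has no samples")
    return float(matrix.col_sums.mean())
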