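"""Survey data model: abundance tables, incidence matrices and grouping.

The raw unit of data is a long-form abundance record: one worker count for
one species in one sample (a bait trap or a fogging tray), where every
sample belongs to exactly one group (a tree crown), one sampling method and
one time of day.  Co-occurrence analysis operates on the derived binary
species x sample incidence matrix and on its per-group sub-matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METHODS = ("bait", "fog")
TIMES = ("day", "night", "na")

#: default long-format column names; remappable via ``column_map``
LONG_COLUMNS = ("sample_id", "group_id", "method", "time", "species_id", "count")


class ValidationError(ValueError):
    """Raised when survey records violate a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted as survey data."""


@dataclass
class AbundanceTable:
    """Long-form survey abundance records.

    Parameters
    ----------
    records
        DataFrame with columns ``sample_id, group_id, method, time,
        species_id, count``.  Duplicate (sample, species) rows are summed on
        construction; counts must be non-negative integers and every sample
        must map to exactly one (group, method, time).
    metadata
        Free-form key/value annotations carried along with the table.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        df = df.loc[:, list(LONG_COLUMNS)]
        for col in ("sample_id", "group_id", "species_id", "method", "time"):
            df[col] = df[col].astype(str)

        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0) | (counts % 1 != 0)]
        if len(bad):
            raise ValidationError(
                f"counts must be non-negative integers; offending rows: {list(bad[:10])}"
            )
        df["count"] = counts.astype(np.int64)

        unknown_method = set(df["method"]) - set(METHODS)
        if unknown_method:
            raise ValidationError(f"unknown method values: {sorted(unknown_method)}")
        unknown_time = set(df["time"]) - set(TIMES)
        if unknown_time:
            raise ValidationError(f"unknown time values: {sorted(unknown_time)}")

        # each sample maps to exactly one (group, method, time)
        meta = df.groupby("sample_id")[["group_id", "method", "time"]].nunique()
        conflicted = meta.index[(meta > 1).any(axis=1)]
        if len(conflicted):
            raise ValidationError(
                f"samples assigned to more than one group/method/time: {list(conflicted[:10])}"
            )

        # duplicate (sample, species) rows are summed, with a logged warning
        dup = df.duplicated(subset=["sample_id", "species_id"])
        if dup.any():
            logger.warning(
                "summed %d duplicate (sample_id, species_id) rows at ingestion", int(dup.sum())
            )
            df = (
                df.groupby(list(LONG_COLUMNS[:-1]), as_index=False, sort=False)["count"]
                .sum()
            )
        self.records = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.records["group_id"].unique())

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    def sample_groups(self) -> dict[str, str]:
        """Mapping sample_id -> group_id."""
        sub = self.records.drop_duplicates("sample_id")
        return dict(zip(sub["sample_id"], sub["group_id"]))

    def subset(self, method: str | None = None, time: str | None = None) -> "AbundanceTable":
        """Restrict to one sampling method and/or time of day."""
        df = self.records
        if method is not None:
            df = df[df["method"] == method]
        if time is not None:
            df = df[df["time"] == time]
        return AbundanceTable(df.reset_index(drop=True), dict(self.metadata))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary species x sample presence/absence matrix.

    Rows are species, columns samples; ``row_sums`` (occurrences per
    species) and ``col_sums`` (species per sample) are the marginals held
    constant by fixed-fixed randomization.
    """

    species_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2 or cells.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValidationError(
                f"cells shape {cells.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.sample_ids)} samples"
            )
        if cells.size and not np.isin(cells, (0, 1)).all():
            raise ValidationError("incidence cells must be binary")
        object.__setattr__(self, "cells", cells.astype(np.uint8))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def row_sums(self) -> np.ndarray:
        return self.cells.sum(axis=1).astype(np.int64)

    @property
    def col_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0).astype(np.int64)

    @property
    def fill(self) -> int:
        return int(self.cells.sum())

    def drop_empty_species(self) -> "IncidenceMatrix":
        """Remove all-zero species rows (keeps every sample column)."""
        keep = self.row_sums > 0
        return IncidenceMatrix(
            tuple(s for s, k in zip(self.species_ids, keep) if k),
            self.sample_ids,
            self.cells[keep],
        )

    def select_samples(self, sample_ids: list[str]) -> "IncidenceMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return IncidenceMatrix(self.species_ids, tuple(sample_ids), self.cells[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.species_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class GroupedIncidence:
    """Ordered per-group incidence sub-matrices over a shared species universe."""

    groups: tuple[tuple[str, IncidenceMatrix], ...]
    species_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, mat in self.groups:
            if mat.n_samples < 1:
                raise ValidationError(f"group {gid!r} has no samples")
            overlap = seen.intersection(mat.sample_ids)
            if overlap:
                raise ValidationError(f"sample ids appear in more than one group: {sorted(overlap)[:5]}")
            seen.update(mat.sample_ids)

    @property
    def group_ids(self) -> list[str]:
        return [gid for gid, _ in self.groups]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def total_samples(self) -> int:
        return sum(mat.n_samples for _, mat in self.groups)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class SurveyDesign:
    """Shape of a balanced survey: groups (trees) x samples per group."""

    n_groups: int = 20
    samples_per_group: int = 8
    method: str = "bait"
    time: str = "day"

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValidationError("n_groups must be >= 2")
        if self.samples_per_group < 2:
            raise ValidationError("samples_per_group must be >= 2")


# -- readers -------------------------------------------------------------------


def read_abundance_table(
    path,
    format: str = "long",
    column_map: dict | None = None,
    sep: str = ",",
    method: str = "bait",
    time: str = "na",
) -> AbundanceTable:
    """Read survey data from a long- or wide-format delimited file.

    Long format: one row per (sample, species) with columns
    ``sample_id, group_id, method, time, species_id, count`` (rename via
    ``column_map`` mapping canonical name -> file column name).  Wide
    format: first column sample_id, second group_id, remaining columns one
    species each with integer counts; ``method``/``time`` supply the
    metadata the wide layout cannot carry (overridable per-file via
    column_map entries ``method``/``time`` if such columns exist).
    """
    df = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    if format == "long":
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing} (after column_map)")
        return AbundanceTable(df)
    if format == "wide":
        sample_col = column_map.get("sample_id", df.columns[0])
        group_col = column_map.get("group_id", df.columns[1])
        species_cols = [c for c in df.columns if c not in (sample_col, group_col)]
        if not species_cols:
            raise FormatError(f"{path}: wide format needs at least one species column")
        long = df.melt(
            id_vars=[sample_col, group_col],
            value_vars=species_cols,
            var_name="species_id",
            value_name="count",
        )
        long = long.rename(columns={sample_col: "sample_id", group_col: "group_id"})
        long["count"] = pd.to_numeric(long["count"], errors="raise").fillna(0)
        long = long[long["count"] > 0]
        long["method"] = method
        long["time"] = time
        return AbundanceTable(long.reset_index(drop=True))
    raise FormatError(f"unknown format {format!r}; expected 'long' or 'wide'")


# -- conversions ---------------------------------------------------------------


def to_incidence(table: AbundanceTable, presence_threshold: int = 1) -> IncidenceMatrix:
    """Convert counts to a binary incidence matrix.

    A cell is 1 iff the count is >= ``presence_threshold``.  Every sample is
    retained, including samples that caught nothing (all-zero columns);
    species never reaching the threshold are excluded from the rows.
    Species and sample order is lexicographic for reproducibility.
    """
    if presence_threshold < 1:
        raise ValidationError("presence_threshold must be >= 1")
    if len(table) == 0:
        raise ValidationError("abundance table is empty")
    wide = table.records.pivot_table(
        index="species_id", columns="sample_id", values="count", aggfunc="sum", fill_value=0
    )
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    cells = (wide.to_numpy() >= presence_threshold).astype(np.uint8)
    keep = cells.sum(axis=1) > 0
    return IncidenceMatrix(
        tuple(np.asarray(wide.index)[keep]),
        tuple(wide.columns),
        cells[keep],
    )


def group_by(matrix: IncidenceMatrix, table: AbundanceTable, key: str = "group_id") -> GroupedIncidence:
    """Split an incidence matrix into per-group sub-matrices.

    Within each sub-matrix, species absent from that group are dropped:
    all-zero rows contribute no checkerboard units and are invariant under
    margin-preserving randomization, so dropping them is output-equivalent
    and faster.  Groups are ordered lexicographically.
    """
    if key != "group_id":
        raise ValidationError(f"unsupported grouping key {key!r}")
    sample_to_group = table.sample_groups()
    unknown = [s for s in matrix.sample_ids if s not in sample_to_group]
    if unknown:
        raise ValidationError(f"samples without a group in the table: {unknown[:10]}")
    by_group: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        by_group.setdefault(sample_to_group[s], []).append(s)
    groups = []
    for gid in sorted(by_group):
        sub = matrix.select_samples(sorted(by_group[gid])).drop_empty_species()
        groups.append((gid, sub))
    return GroupedIncidence(tuple(groups), matrix.species_ids)


def grouped_incidence(
    table: AbundanceTable, presence_threshold: int = 1
) -> GroupedIncidence:
    """Shorthand: table -> incidence -> per-group sub-matrices."""
    matrix = to_incidence(table, presence_threshold)
    return group_by(matrix, table)
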