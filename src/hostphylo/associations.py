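"""Curated fly-host association tables and derived summaries.

The central object is an :class:`AssociationTable`: one row per recorded
(fly species, host plant species) interaction, with the host's genus and
family, plus a provenance status. From it we derive host-breadth profiles
(distinct host species / genera / families per fly), polyphagy partitions
(binary "feeds on more than k families" traits), genus-level binary
interaction matrices for the host-sharing regression, and the filtered tip
range states that feed the DEC* ancestral reconstruction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("fly_species", "host_species", "host_genus", "host_family")
VALID_STATUSES = ("valid", "excluded_doubtful", "excluded_unidentified")

__all__ = [
    "AssociationTable",
    "SchemaError",
    "ConsistencyError",
    "load_association_table",
    "host_breadth",
    "binarize_polyphagy",
    "interaction_matrix",
    "filter_for_dec",
    "main_host_families",
    "tip_range_states",
]


class SchemaError(ValueError):
    """Input file does not carry the required columns."""


class ConsistencyError(ValueError):
    """Taxonomic inconsistency (species in two genera, genus in two families)."""


def _normalize(s: str) -> str:
    return re.sub(r"\s+", " ", str(s).strip())


@dataclass
class AssociationTable:
    """Validated association records; excluded rows are retained but inert."""

    records: pd.DataFrame  # columns: REQUIRED_COLUMNS + status

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if "status" not in self.records.columns:
            self.records = self.records.assign(status="valid")
        bad = set(self.records["status"]) - set(VALID_STATUSES)
        if bad:
            raise SchemaError(f"unknown status value(s): {sorted(bad)}")
        self._check_consistency()

    def _check_consistency(self) -> None:
        valid = self.valid_records
        for rank_child, rank_parent in (
            ("host_species", "host_genus"),
            ("host_genus", "host_family"),
        ):
            mapping = valid.groupby(rank_child)[rank_parent].nunique()
            offenders = mapping[mapping > 1]
            if len(offenders):
                raise ConsistencyError(
                    f"{rank_child} mapped to multiple {rank_parent} values: "
                    f"{sorted(offenders.index)}"
                )
        dup = valid.duplicated(subset=["fly_species", "host_species"])
        if dup.any():
            raise ConsistencyError(
                "duplicate (fly_species, host_species) pairs among valid records"
            )

    @property
    def valid_records(self) -> pd.DataFrame:
        return self.records[self.records["status"] == "valid"]

    @property
    def fly_species(self) -> list[str]:
        return sorted(self.valid_records["fly_species"].unique())

    @property
    def n_valid(self) -> int:
        return len(self.valid_records)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, str, str, str]], status: str = "valid"
    ) -> "AssociationTable":
        df = pd.DataFrame(list(rows), columns=list(REQUIRED_COLUMNS))
        df["status"] = status
        return cls(df)

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.records.to_csv(path, sep=sep, index=False)


def load_association_table(path) -> AssociationTable:
    """Read a CSV/TSV association table, normalising labels and merging
    exact duplicates.

    Rows flagged ``excluded_doubtful`` / ``excluded_unidentified`` are kept
    but never enter downstream computations. Empty genus or family on a
    valid row is a hard error naming the row.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    for col in REQUIRED_COLUMNS:
        df[col] = df[col].map(_normalize)
    if "status" not in df.columns:
        df["status"] = "valid"
    else:
        df["status"] = df["status"].map(_normalize).replace("", "valid")
    for col in ("host_genus", "host_family"):
        empty = df.index[(df["status"] == "valid") & (df[col] == "")]
        if len(empty):
            # +2: header line plus 1-based numbering, as in the raw file
            raise ValueError(
                f"{path}: empty {col} on data row(s) {[i + 2 for i in empty]}"
            )
    n0 = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n0:
        logger.info("merged %d exact duplicate row(s)", n0 - len(df))
    # duplicate (fly, host) pairs that differ elsewhere are collapsed to the
    # first occurrence among valid rows
    valid_mask = df["status"] == "valid"
    dup = df[valid_mask].duplicated(subset=["fly_species", "host_species"])
    if dup.any():
        drop_idx = dup.index[dup]
        logger.info("collapsed %d duplicate (fly, host) pair(s)", len(drop_idx))
        df = df.drop(index=drop_idx).reset_index(drop=True)
    return AssociationTable(df)


def host_breadth(table: AssociationTable) -> pd.DataFrame:
    """Distinct host species / genera / families per fly (the host breadth).

    Returns a DataFrame indexed by fly species with columns
    ``n_host_species``, ``n_host_genera``, ``n_host_families``.
    """
    valid = table.valid_records
    if valid.empty:
        raise ValueError("no valid records to profile")
    prof = valid.groupby("fly_species").agg(
        n_host_species=("host_species", "nunique"),
        n_host_genera=("host_genus", "nunique"),
        n_host_families=("host_family", "nunique"),
    )
    return prof.sort_index()


def binarize_polyphagy(
    profile: pd.DataFrame, threshold: int
) -> tuple[pd.Series, int]:
    """Binary polyphagy trait: 1 iff a fly uses strictly more than
    ``threshold`` host families. Returns (trait, number of polyphages)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    trait = (profile["n_host_families"] > threshold).astype(int)
    return trait, int(trait.sum())


def interaction_matrix(table: AssociationTable) -> pd.DataFrame:
    """Fly x host-genus binary matrix (1 iff any valid association)."""
    valid = table.valid_records
    if valid.empty:
        raise ValueError("no valid records")
    mat = (
        pd.crosstab(valid["fly_species"], valid["host_genus"])
        .astype(bool)
        .astype(int)
    )
    return mat.sort_index(axis=0).sort_index(axis=1)


def filter_for_dec(
    table: AssociationTable,
    max_families: int = 20,
    exclude: Sequence[str] = (),
) -> tuple[AssociationTable, list[str]]:
    """Drop extreme polyphages (>= ``max_families`` host families) and any
    explicitly excluded flies; return the reduced table and retained flies."""
    prof = host_breadth(table)
    missing = [f for f in exclude if f not in prof.index]
    if missing:
        logger.warning("excluded fly label(s) absent from table: %s", missing)
    keep = prof.index[(prof["n_host_families"] < max_families)]
    keep = [f for f in keep if f not in set(exclude)]
    if not keep:
        logger.warning("filter removed every fly; result is empty")
        return (
            AssociationTable(table.records.iloc[0:0].copy()),
            [],
        )
    sub = table.records[
        (table.records["fly_species"].isin(keep))
        | (table.records["status"] != "valid")
    ].reset_index(drop=True)
    return AssociationTable(sub), sorted(keep)


def main_host_families(
    table: AssociationTable, k: int = 9, rank_by: str = "n_host_species"
) -> list[str]:
    """The k most-used host families.

    ``rank_by='n_host_species'`` ranks by distinct associated host species,
    ``rank_by='n_fly_species'`` by distinct fly species using the family.
    Ties at the cut are broken alphabetically (logged).
    """
    valid = table.valid_records
    if rank_by == "n_host_species":
        counts = valid.groupby("host_family")["host_species"].nunique()
    elif rank_by == "n_fly_species":
        counts = valid.groupby("host_family")["fly_species"].nunique()
    else:
        raise ValueError("rank_by must be 'n_host_species' or 'n_fly_species'")
    if k > len(counts):
        raise ValueError(f"k={k} exceeds number of families ({len(counts)})")
    ranked = counts.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) > k and ranked.iloc[k - 1] == ranked.iloc[k]:
        logger.info(
            "tie at rank %d (count %d) broken alphabetically", k, ranked.iloc[k]
        )
    return list(ranked.index[:k])


def tip_range_states(
    table: AssociationTable, families: Sequence[str]
) -> dict[str, frozenset[str]]:
    """Per-fly subset of ``families`` it has at least one valid record with.

    A fly whose diet does not intersect ``families`` at all is an error:
    the DEC* state space has no null range.
    """
    fam_set = set(families)
    valid = table.valid_records
    states: dict[str, frozenset[str]] = {}
    empty = []
    for fly, grp in valid.groupby("fly_species"):
        s = frozenset(grp["host_family"]) & fam_set
        if not s:
            empty.append(fly)
        else:
            states[fly] = frozenset(s)
    if empty:
        raise ValueError(
            f"flies with no host among the selected families (null DEC range): {sorted(empty)}"
        )
    return states
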