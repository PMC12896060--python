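"""Core in-memory containers for classified read-count data.

The pipeline moves a single pair of objects between stages: a samples x taxa
count matrix and a taxon annotation table keyed by NCBI-style taxid. Raw
integer counts and fractional transforms are kept in distinct types so that
a stage expecting raw counts (e.g. contaminant identification) cannot be fed
normalized or log values by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

KINGDOMS = ("Archaea", "Bacteria", "Fungi", "Virus", "Other")

#: per-sample read total after normalization (reads)
NORMALIZATION_TARGET = 10_000_000


class TableError(ValueError):
    """Raised when a count table violates its structural invariants."""


def _check_taxa(taxa: pd.DataFrame) -> pd.DataFrame:
    taxa = taxa.copy()
    if taxa.index.name != "taxid":
        if "taxid" in taxa.columns:
            taxa = taxa.set_index("taxid")
        else:
            taxa.index.name = "taxid"
    if taxa.index.has_duplicates:
        dups = taxa.index[taxa.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate taxids in annotation: {dups}")
    if (taxa.index <= 0).any():
        raise TableError("taxids must be positive integers")
    for col in ("name", "rank", "kingdom"):
        if col not in taxa.columns:
            raise TableError(f"taxon annotation missing column {col!r}")
    bad = set(taxa["kingdom"]) - set(KINGDOMS)
    if bad:
        raise TableError(f"unknown kingdom labels: {sorted(bad)}")
    return taxa


@dataclass
class TaxonCountTable:
    """Samples x taxa matrix of classified read counts plus taxon annotations.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and integer taxids as columns;
        entries are non-negative integer read counts.
    taxa
        DataFrame indexed by taxid with columns ``name``, ``rank``,
        ``kingdom``; must cover every column of ``counts``.
    """

    counts: pd.DataFrame
    taxa: pd.DataFrame

    def __post_init__(self) -> None:
        self.taxa = _check_taxa(self.taxa)
        counts = self.counts
        if counts.index.has_duplicates:
            raise TableError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise TableError("duplicate taxid columns")
        if (counts.to_numpy() < 0).any():
            raise TableError("negative counts")
        missing = set(counts.columns) - set(self.taxa.index)
        if missing:
            raise TableError(f"taxids without annotation: {sorted(missing)[:5]}")
        # keep annotation aligned to the matrix columns, in column order
        self.taxa = self.taxa.loc[counts.columns]
        self.taxa.index.name = "taxid"
        self.counts = counts.astype(np.int64)

    # -- conveniences -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxids(self) -> list[int]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        """Total classified reads per sample."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonCountTable":
        missing = set(sample_ids) - set(self.counts.index)
        if missing:
            raise TableError(f"unknown sample ids: {sorted(missing)[:5]}")
        return TaxonCountTable(self.counts.loc[list(sample_ids)], self.taxa)

    def subset_kingdom(self, kingdom: str) -> "TaxonCountTable":
        if kingdom not in KINGDOMS:
            raise TableError(f"unknown kingdom {kingdom!r}")
        keep = self.taxa.index[self.taxa["kingdom"] == kingdom]
        return TaxonCountTable(self.counts.loc[:, keep], self.taxa.loc[keep])

    def drop_taxa(self, taxids: Iterable[int]) -> "TaxonCountTable":
        drop = [t for t in self.taxids if t in set(taxids)]
        keep = [t for t in self.taxids if t not in set(drop)]
        return TaxonCountTable(self.counts.loc[:, keep], self.taxa.loc[keep])

    def relative(self) -> pd.DataFrame:
        """Within-sample relative abundances (rows sum to 1; zero rows stay 0)."""
        totals = self.counts.sum(axis=1)
        rel = self.counts.div(totals.replace(0, np.nan), axis=0)
        return rel.fillna(0.0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonCountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.taxa.equals(
            other.taxa.loc[self.counts.columns]
        )


@dataclass
class NormalizedTable:
    """Real-valued abundance table produced by normalization / log transform.

    ``transform_tag`` records provenance: ``scaled_1e7`` rows sum to the
    normalization target (10,000,000 reads), ``log_scaled`` holds
    log10(scaled + 1) values. ``zero_samples`` lists samples whose raw total
    was zero (their rows are all-zero and are exempt from the row-sum
    invariant).
    """

    values: pd.DataFrame
    taxa: pd.DataFrame
    transform_tag: str
    zero_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.transform_tag not in ("scaled_1e7", "log_scaled"):
            raise TableError(f"unknown transform_tag {self.transform_tag!r}")
        self.taxa = _check_taxa(self.taxa).loc[self.values.columns]
        self.taxa.index.name = "taxid"
        if (self.values.to_numpy() < 0).any():
            raise TableError("negative abundance values")
        if self.transform_tag == "scaled_1e7":
            totals = self.values.sum(axis=1)
            nonzero = ~totals.index.isin(self.zero_samples)
            off = np.abs(totals[nonzero] / NORMALIZATION_TARGET - 1.0)
            if len(off) and off.max() > 1e-9:
                raise TableError("scaled rows do not sum to the target")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxids(self) -> list[int]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "NormalizedTable":
        return replace(
            self,
            values=self.values.loc[list(sample_ids)],
            zero_samples=tuple(s for s in self.zero_samples if s in set(sample_ids)),
        )

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def make_taxa_frame(records: Iterable[tuple[int, str, str, str]]) -> pd.DataFrame:
    """Build a taxon annotation frame from (taxid, name, rank, kingdom) tuples."""
    frame = pd.DataFrame(records, columns=["taxid", "name", "rank", "kingdom"])
    return frame.set_index("taxid")
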