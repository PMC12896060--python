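"""Readers and writers for the TSV dialects the pipeline touches.

Supported inputs are the standard 6-column Kraken2 report, the 7-column
Bracken species table, and a tab-separated sample-metadata sheet. Outputs are
a merged taxa x samples count matrix with a sidecar taxon-annotation table,
and a contaminant evidence table. Everything is plain UTF-8 TSV; binary BIOM
is deliberately unsupported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import KINGDOMS, TableError, TaxonCountTable, make_taxa_frame

log = logging.getLogger(__name__)

SAMPLE_TYPES = ("air", "field_negative", "lab_negative", "positive")
NEGATIVE_TYPES = ("field_negative", "lab_negative")

#: sentinel used in metadata files for DNA concentration below detection limit
BELOW_DETECTION = "BD"

# Kraken2 domain/kingdom names -> pipeline kingdom labels
_KINGDOM_ALIASES = {
    "bacteria": "Bacteria",
    "archaea": "Archaea",
    "fungi": "Fungi",
    "viruses": "Virus",
    "virus": "Virus",
}


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass
class SampleRecord:
    """Per-sample metadata row.

    Optional numeric fields are ``None`` when not recorded; ``dna_conc`` is
    ``None`` when missing and ``dna_below_detection`` distinguishes an
    unmeasurably low concentration from an unrecorded one.
    """

    sample_id: str
    city: str
    year: int
    sample_type: str
    locality: str | None = None
    temperature: float | None = None
    humidity: float | None = None
    travellers: int | None = None
    ground_level: str | None = None
    enclosure: str | None = None
    dna_conc: float | None = None
    dna_below_detection: bool = False
    plate_position: str | None = None
    nonpareil_coverage: float | None = None

    def is_negative(self) -> bool:
        return self.sample_type in NEGATIVE_TYPES


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by sample_id."""
    frame = pd.DataFrame([vars(r) for r in records]).set_index("sample_id")
    return frame


# ---------------------------------------------------------------------------
# Kraken2 / Bracken readers
# ---------------------------------------------------------------------------


def _resolve_kingdom(name: str) -> str | None:
    return _KINGDOM_ALIASES.get(name.strip().lower())


def read_kraken_report(
    path: str | Path,
    sample_id: str | None = None,
    use_clade_counts: bool = True,
) -> TaxonCountTable:
    """Parse a Kraken2 report into a single-sample count table.

    Only species-rank rows (rank code ``S``) are retained. By default the
    clade read count is used, rolling sub-species assignments up to the
    species (``use_clade_counts=False`` switches to direct assignments).
    Kingdom labels are tracked from the enclosing ``D``/``K`` rows of the
    report hierarchy; species outside Archaea/Bacteria/Fungi/Viruses are
    labelled ``Other``.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    rows: list[tuple[int, str, str, str]] = []
    counts: dict[int, int] = {}
    current_kingdom = "Other"
    n_lines = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields, got {len(parts)}"
                )
            # last 5 of the 6 canonical columns; reports with minimizer
            # columns (8 fields) keep the same head/tail layout
            try:
                clade_reads = int(parts[1])
                direct_reads = int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer read count") from exc
            rank_code = parts[-3].strip()
            try:
                taxid = int(parts[-2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer taxid") from exc
            name = parts[-1].strip()
            if rank_code in ("D", "K", "D1", "K1"):
                current_kingdom = _resolve_kingdom(name) or "Other"
            if rank_code == "S":
                if taxid <= 0:
                    raise ParseError(f"{path}:{lineno}: non-positive taxid {taxid}")
                counts[taxid] = clade_reads if use_clade_counts else direct_reads
                rows.append((taxid, name, "species", current_kingdom))
    if n_lines == 0:
        raise ParseError(f"{path}: empty report")
    taxa = make_taxa_frame(rows)
    matrix = pd.DataFrame([counts], index=[sample_id], columns=taxa.index).fillna(0)
    return TaxonCountTable(matrix, taxa)


def read_bracken_table(
    path: str | Path,
    sample_id: str | None = None,
    kingdom_map: Mapping[int, str] | None = None,
) -> TaxonCountTable:
    """Parse a Bracken species table into a single-sample count table.

    Uses the ``new_est_reads`` column. Bracken output carries no lineage, so
    kingdoms default to ``Other`` unless a taxid -> kingdom map is supplied.
    A ``fraction_total_reads`` column summing to more than 1 (beyond rounding)
    is logged as a warning but accepted.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    kingdom_map = kingdom_map or {}
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty Bracken table") from exc
    required = {"name", "taxonomy_id", "taxonomy_lvl", "new_est_reads"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing Bracken columns {sorted(missing)}")
    species = frame[frame["taxonomy_lvl"].isin(("S", "species"))]
    if "fraction_total_reads" in frame.columns:
        total = float(species["fraction_total_reads"].sum())
        if total > 1.0 + 1e-6:
            log.warning("%s: fraction_total_reads sums to %.4f > 1", path, total)
    rows = [
        (int(t), str(n), "species", kingdom_map.get(int(t), "Other"))
        for t, n in zip(species["taxonomy_id"], species["name"])
    ]
    taxa = make_taxa_frame(rows)
    counts = pd.DataFrame(
        [species["new_est_reads"].astype(int).to_numpy()],
        index=[sample_id],
        columns=taxa.index,
    )
    return TaxonCountTable(counts, taxa)


def merge_tables(tables: Sequence[TaxonCountTable]) -> TaxonCountTable:
    """Merge single- or multi-sample tables over the union of their taxa.

    A taxon absent from a sample contributes count 0; per-sample totals are
    conserved exactly. Duplicate sample ids are an error.
    """
    if not tables:
        raise TableError("nothing to merge")
    all_samples = [s for t in tables for s in t.sample_ids]
    if len(all_samples) != len(set(all_samples)):
        raise TableError("duplicate sample ids across merged tables")
    counts = pd.concat([t.counts for t in tables], axis=0).fillna(0).astype(np.int64)
    taxa = pd.concat([t.taxa for t in tables])
    taxa = taxa[~taxa.index.duplicated(keep="first")]
    return TaxonCountTable(counts.loc[:, taxa.index.intersection(counts.columns)], taxa)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_OPTIONAL_FLOAT = ("temperature", "humidity", "nonpareil_coverage")
_ENUMS = {"ground_level": ("above", "below"), "enclosure": ("enclosed", "open")}


def _parse_float(value: str, field: str, context: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(f"{context}: bad {field} value {value!r}") from exc


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the tab-separated metadata sheet into SampleRecord rows.

    Required columns: ``sample_id``, ``city``, ``year``, ``sample_type``.
    Empty cells in optional columns become missing markers, never zeros.
    ``sample_type`` must be one of air / field_negative / lab_negative /
    positive — an unqualified "negative" is rejected so that field and lab
    blanks stay distinguishable.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("sample_id", "city", "year", "sample_type")
    missing = set(required) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        ctx = f"{path}:row {i + 2}"
        sid = row["sample_id"].strip()
        if not sid:
            raise ParseError(f"{ctx}: empty sample_id")
        if sid in seen:
            raise ParseError(f"{ctx}: duplicate sample_id {sid!r}")
        seen.add(sid)
        stype = row["sample_type"].strip()
        if stype not in SAMPLE_TYPES:
            raise ParseError(
                f"{ctx}: sample_type {stype!r} not allowed; use one of {SAMPLE_TYPES}"
            )
        rec = SampleRecord(
            sample_id=sid,
            city=row["city"].strip(),
            year=int(row["year"]),
            sample_type=stype,
        )
        get = lambda col: row[col].strip() if col in frame.columns else ""
        if get("locality"):
            rec.locality = get("locality")
        for fieldname in _OPTIONAL_FLOAT:
            raw = get(fieldname)
            if raw:
                setattr(rec, fieldname, _parse_float(raw, fieldname, ctx))
        if get("travellers"):
            rec.travellers = int(float(get("travellers")))
        for fieldname, allowed in _ENUMS.items():
            raw = get(fieldname)
            if raw:
                if raw not in allowed:
                    raise ParseError(f"{ctx}: {fieldname} {raw!r} not in {allowed}")
                setattr(rec, fieldname, raw)
        raw_dna = get("dna_conc")
        if raw_dna:
            if raw_dna.upper() == BELOW_DETECTION:
                rec.dna_below_detection = True
            else:
                rec.dna_conc = _parse_float(raw_dna, "dna_conc", ctx)
        if get("plate_position"):
            rec.plate_position = get("plate_position")
        cov = rec.nonpareil_coverage
        if cov is not None and not (0.0 <= cov <= 1.0):
            raise ParseError(f"{ctx}: nonpareil_coverage {cov} outside [0, 1]")
        records.append(rec)
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write metadata records back to the TSV dialect read_metadata accepts."""
    rows = []
    for r in records:
        row = {k: v for k, v in vars(r).items() if k != "dna_below_detection"}
        if r.dna_below_detection:
            row["dna_conc"] = BELOW_DETECTION
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Count matrix + contaminant table writers
# ---------------------------------------------------------------------------


def write_table(table: TaxonCountTable, path: str | Path) -> None:
    """Write a merged count table: taxa rows x sample columns, plus a sidecar
    ``<path>.taxa.tsv`` with the taxon annotations."""
    path = Path(path)
    matrix = table.counts.T
    matrix.index.name = "taxid"
    matrix.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".taxa.tsv")
    table.taxa.to_csv(sidecar, sep="\t")


def read_table(path: str | Path) -> TaxonCountTable:
    """Read a count table written by :func:`write_table`."""
    path = Path(path)
    matrix = pd.read_csv(path, sep="\t", index_col="taxid")
    sidecar = path.with_suffix(path.suffix + ".taxa.tsv")
    taxa = pd.read_csv(sidecar, sep="\t", index_col="taxid")
    counts = matrix.T
    counts.columns = counts.columns.astype(int)
    counts.index.name = None
    return TaxonCountTable(counts.astype(np.int64), taxa)


def write_contaminants(evidence: pd.DataFrame, path: str | Path) -> None:
    """Write a contaminant evidence table (one row per taxon).

    Expects the frame produced by ``decontam.identify_contaminants`` with
    columns taxid, name, kingdom, n_negatives_present, total_negative_reads,
    is_contaminant.
    """
    cols = [
        "taxid",
        "name",
        "kingdom",
        "n_negatives_present",
        "total_negative_reads",
        "is_contaminant",
    ]
    frame = evidence.reset_index() if "taxid" not in evidence.columns else evidence
    frame.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_contaminants(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["is_contaminant"] = frame["is_contaminant"].astype(bool)
    return frame.set_index("taxid")
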