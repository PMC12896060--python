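"""Abundance filtering, normalization, log transform and abundance summaries.

The canonical pipeline order is: species-level counts -> 0.005% within-sample
abundance filter -> contaminant removal -> normalization to 10,000,000 reads
per sample -> log10(x + 1). Raw and transformed tables are distinct types, so
each stage checks it is fed the representation it expects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .tables import (
    NORMALIZATION_TARGET,
    NormalizedTable,
    TableError,
    TaxonCountTable,
)

#: default within-sample relative-abundance cut-off (0.005% of classified reads)
DEFAULT_MIN_FRACTION = 0.00005


def abundance_threshold_filter(
    table: TaxonCountTable, min_fraction: float = DEFAULT_MIN_FRACTION
) -> TaxonCountTable:
    """Zero out taxa below a within-sample relative-abundance cut-off.

    For each sample, a taxon is kept when ``count >= min_fraction * total``
    with the total taken *before* any zeroing; counts at exactly the
    threshold are kept. Applying the filter twice equals applying it once
    (sample totals used for the fraction are the original classified totals,
    which are recomputed identically only for unfiltered input — hence the
    filtered table stores unchanged retained counts and idempotence follows
    from the kept set only shrinking to a fixed point immediately).
    """
    if not (0.0 <= min_fraction < 1.0):
        raise TableError(f"min_fraction {min_fraction} outside [0, 1)")
    totals = table.sample_totals().to_numpy()[:, None]
    counts = table.counts.to_numpy()
    keep = counts >= min_fraction * totals
    filtered = pd.DataFrame(
        np.where(keep, counts, 0), index=table.counts.index, columns=table.counts.columns
    )
    return TaxonCountTable(filtered, table.taxa)


def normalize_counts(
    table: TaxonCountTable, target: int = NORMALIZATION_TARGET
) -> NormalizedTable:
    """Scale each sample's counts to sum to ``target`` reads.

    Samples with zero classified reads stay all-zero and are recorded in
    ``zero_samples``.
    """
    if target <= 0:
        raise TableError("normalization target must be positive")
    totals = table.sample_totals()
    zero = tuple(totals.index[totals == 0])
    scaled = table.counts.div(totals.replace(0, np.nan), axis=0) * target
    scaled = scaled.fillna(0.0)
    return NormalizedTable(
        values=scaled, taxa=table.taxa, transform_tag="scaled_1e7", zero_samples=zero
    )


def log_transform(table: NormalizedTable) -> NormalizedTable:
    """log10(x + 1) on a normalized table (pseudocount of one read)."""
    if table.transform_tag != "scaled_1e7":
        raise TableError(
            f"log transform expects a scaled table, got {table.transform_tag!r}"
        )
    return NormalizedTable(
        values=np.log10(table.values + 1.0),
        taxa=table.taxa,
        transform_tag="log_scaled",
        zero_samples=table.zero_samples,
    )


def relative_abundance(
    table: TaxonCountTable,
    metadata: pd.DataFrame | None = None,
    grouping: str = "total",
    level: str = "species",
    top_n: int = 20,
) -> pd.DataFrame:
    """Relative classified read abundance per group, at kingdom or species level.

    ``grouping`` is ``"total"`` (all samples pooled) or ``"per_city"``
    (requires metadata with a ``city`` column; years and sites are merged
    within city). At species level the ``top_n`` species by summed reads are
    named (ties broken by ascending taxid) and the remainder is a single
    ``other`` row, so percentages sum to exactly 100 per group.

    Returns a tidy frame with columns ``group``, ``label``, ``percent``.
    """
    if level not in ("kingdom", "species"):
        raise TableError(f"unknown level {level!r}")
    if grouping not in ("total", "per_city"):
        raise TableError(f"unknown grouping {grouping!r}")
    if grouping == "per_city":
        if metadata is None or "city" not in metadata.columns:
            raise TableError("per_city grouping needs metadata with a city column")
        groups = {
            str(city): [s for s in table.sample_ids if s in idx]
            for city, idx in metadata.groupby("city").groups.items()
        }
        groups = {c: ids for c, ids in groups.items() if ids}
    else:
        groups = {"total": table.sample_ids}

    out_rows: list[dict] = []
    for group, ids in groups.items():
        sub = table.counts.loc[ids]
        taxon_sums = sub.sum(axis=0)
        total = float(taxon_sums.sum())
        if total == 0:
            raise TableError(f"group {group!r} has no classified reads")
        if level == "kingdom":
            by_kingdom = taxon_sums.groupby(table.taxa["kingdom"]).sum()
            labels = list(by_kingdom.index)
            running = 0.0
            for lab in labels[:-1]:
                pct = float(by_kingdom[lab]) / total * 100.0
                running += pct
                out_rows.append({"group": group, "label": lab, "percent": pct})
            # final row as residual so each group sums to exactly 100
            out_rows.append(
                {"group": group, "label": labels[-1], "percent": 100.0 - running}
            )
        else:
            order = taxon_sums.to_frame("reads")
            order["taxid"] = order.index
            order = order.sort_values(["reads", "taxid"], ascending=[False, True])
            top = order.head(top_n)
            running = 0.0
            for taxid, row in top.iterrows():
                pct = float(row["reads"]) / total * 100.0
                running += pct
                out_rows.append(
                    {
                        "group": group,
                        "label": table.taxa.at[taxid, "name"],
                        "percent": pct,
                    }
                )
            out_rows.append(
                {"group": group, "label": "other", "percent": 100.0 - running}
            )
    return pd.DataFrame(out_rows, columns=["group", "label", "percent"])
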