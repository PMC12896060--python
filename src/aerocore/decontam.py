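"""Exogenous-contaminant identification and removal from negative controls.

Low-biomass air samples are dominated by reads introduced during sampling,
extraction and library preparation (kitome, splashome, handler flora). The
rule implemented here calls a taxon a contaminant when it is present in at
least two pooled negative controls (field + lab) and its summed raw read
count across all negatives exceeds 10,000. Called taxa are removed from the
count tables outright; for prevalence-based core analyses, borderline taxa
are additionally gated by a one-sided two-proportion Z test requiring air
prevalence to significantly exceed negative-control prevalence, so that
genuinely airborne species that also leak into blanks are not discarded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleRecord, metadata_frame
from .tables import KINGDOMS, TableError, TaxonCountTable


# ---------------------------------------------------------------------------
# Contaminant rule
# ---------------------------------------------------------------------------


def identify_contaminants(
    table: TaxonCountTable,
    negative_ids: Iterable[str],
    min_negatives: int = 2,
    min_total_reads: int = 10_000,
) -> pd.DataFrame:
    """Per-taxon contaminant evidence from pooled negative controls.

    A taxon is a contaminant iff it is present (count > 0) in at least
    ``min_negatives`` negative samples and its total raw read count over all
    negatives is strictly greater than ``min_total_reads``. Presence is
    evaluated on the species-level table before any abundance filtering:
    negatives are sparse, and thresholding them would hide contaminants.

    Returns a DataFrame indexed by taxid with columns ``name``, ``kingdom``,
    ``n_negatives_present``, ``total_negative_reads``, ``is_contaminant``.
    """
    negative_ids = list(negative_ids)
    missing = set(negative_ids) - set(table.sample_ids)
    if missing:
        raise TableError(f"negative ids not in table: {sorted(missing)[:5]}")
    if len(negative_ids) < 2:
        raise TableError(
            "contaminant rule undefined with fewer than 2 negative controls"
        )
    neg = table.counts.loc[negative_ids]
    n_present = (neg > 0).sum(axis=0)
    totals = neg.sum(axis=0)
    evidence = pd.DataFrame(
        {
            "name": table.taxa["name"],
            "kingdom": table.taxa["kingdom"],
            "n_negatives_present": n_present.astype(int),
            "total_negative_reads": totals.astype(int),
        }
    )
    evidence["is_contaminant"] = (
        evidence["n_negatives_present"] >= min_negatives
    ) & (evidence["total_negative_reads"] > min_total_reads)
    evidence.index.name = "taxid"
    return evidence


def contaminant_set(evidence: pd.DataFrame) -> set[int]:
    """Taxids flagged as contaminants in an evidence table."""
    return set(evidence.index[evidence["is_contaminant"]].astype(int))


def remove_taxa(
    table: TaxonCountTable, taxids: Iterable[int]
) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Drop the given taxa and summarise what was removed per sample.

    Read conservation holds exactly: for every sample,
    ``removed_reads + retained_reads == original total``.

    The summary frame (indexed by sample) reports ``total_reads``,
    ``removed_reads``, ``removed_fraction`` and a ``removed_frac_<kingdom>``
    column per kingdom (fractions of the sample's classified reads).
    """
    taxids = set(int(t) for t in taxids)
    removed_cols = [t for t in table.taxids if t in taxids]
    cleaned = table.drop_taxa(taxids)
    totals = table.sample_totals()
    removed = table.counts.loc[:, removed_cols].sum(axis=1)
    safe_tot = totals.replace(0, np.nan)
    summary = pd.DataFrame(
        {
            "total_reads": totals,
            "removed_reads": removed,
            "removed_fraction": (removed / safe_tot).fillna(0.0),
        }
    )
    for kingdom in KINGDOMS:
        cols = [
            t for t in removed_cols if table.taxa.at[t, "kingdom"] == kingdom
        ]
        summary[f"removed_frac_{kingdom.lower()}"] = (
            table.counts.loc[:, cols].sum(axis=1) / safe_tot
        ).fillna(0.0)
    return cleaned, summary


# ---------------------------------------------------------------------------
# Two-proportion Z gate
# ---------------------------------------------------------------------------


@dataclass
class ZGateResult:
    """One-sided two-sample Z test of proportion (air vs negatives)."""

    taxid: int
    prev_air: float
    n_air: int
    prev_neg: float
    n_neg: int
    pooled_p: float
    z: float
    p_value: float
    passes: bool
    flag: str = ""


def prevalence_z_test(
    x_air: int,
    n_air: int,
    x_neg: int,
    n_neg: int,
    alpha: float = 0.05,
    taxid: int = 0,
) -> ZGateResult:
    """Pooled-variance one-sided two-proportion Z test, air vs negatives.

    z = (p1 - p2) / sqrt(p̂ (1 - p̂) (1/n1 + 1/n2)) with p̂ the pooled
    proportion; the p-value is the upper tail (air prevalence greater).
    No continuity correction and no multiple-testing adjustment.

    Degenerate cases: equal proportions (including pooled p̂ of 0 or 1)
    never pass and are flagged ``degenerate``; a taxon entirely absent from
    negatives but present in air passes with flag ``trivially_greater``.
    """
    if n_air < 1 or n_neg < 1:
        raise ValueError("both groups need at least one sample")
    if not (0 <= x_air <= n_air and 0 <= x_neg <= n_neg):
        raise ValueError("successes exceed group sizes")
    p1 = x_air / n_air
    p2 = x_neg / n_neg
    pooled = (x_air + x_neg) / (n_air + n_neg)
    flag = ""
    if pooled in (0.0, 1.0) or p1 == p2:
        z = 0.0
        p_value = 0.5
        passes = False
        flag = "degenerate" if p1 == p2 else ""
    else:
        z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n_air + 1 / n_neg))
        p_value = float(stats.norm.sf(z))
        passes = (p1 > p2) and (p_value < alpha)
    if x_neg == 0 and x_air > 0:
        passes = True
        flag = "trivially_greater"
    return ZGateResult(
        taxid=taxid,
        prev_air=p1,
        n_air=n_air,
        prev_neg=p2,
        n_neg=n_neg,
        pooled_p=pooled,
        z=z,
        p_value=p_value,
        passes=passes,
        flag=flag,
    )


def gate_all_taxa(
    table: TaxonCountTable,
    air_ids: Sequence[str],
    negative_ids: Sequence[str],
    alpha: float = 0.05,
) -> dict[int, ZGateResult]:
    """Run the prevalence Z gate for every taxon (presence = count > 0)."""
    air = table.counts.loc[list(air_ids)]
    neg = table.counts.loc[list(negative_ids)]
    x_air = (air > 0).sum(axis=0)
    x_neg = (neg > 0).sum(axis=0)
    return {
        int(t): prevalence_z_test(
            int(x_air[t]), len(air_ids), int(x_neg[t]), len(negative_ids),
            alpha=alpha, taxid=int(t),
        )
        for t in table.taxids
    }


# ---------------------------------------------------------------------------
# Cross-contamination review
# ---------------------------------------------------------------------------


@dataclass
class CrossContamFlag:
    """Candidate cross-contaminated sample and the metadata verdict.

    A sample becomes a candidate when most of its nearest neighbours in the
    beta-diversity embedding belong to another city. Exclusion additionally
    requires two independent metadata confirmations: DNA concentration below
    detection AND a library-plate position adjacent to a sample of the
    embedding-neighbour city. Candidacy alone never excludes.
    """

    sample_id: str
    assigned_city: str
    embedded_neighbor_city: str
    dna_below_detection: bool
    plate_adjacent_to_neighbor_city: bool
    verdict: str  # "exclude" | "retain"


_WELL_RE = re.compile(r"^(?:(?P<plate>[^:]+):)?(?P<row>[A-P])(?P<col>\d{1,2})$")


def _parse_well(position: str) -> tuple[str, int, int] | None:
    m = _WELL_RE.match(position.strip())
    if not m:
        return None
    return (m.group("plate") or "1", ord(m.group("row")) - ord("A"), int(m.group("col")))


def _wells_adjacent(a: str | None, b: str | None) -> bool:
    if not a or not b:
        return False
    wa, wb = _parse_well(a), _parse_well(b)
    if wa is None or wb is None or wa[0] != wb[0]:
        return False
    dr, dc = abs(wa[1] - wb[1]), abs(wa[2] - wb[2])
    return (dr, dc) != (0, 0) and dr <= 1 and dc <= 1


def flag_cross_contamination(
    embedding: pd.DataFrame,
    metadata: Sequence[SampleRecord] | pd.DataFrame,
    k: int = 10,
) -> list[CrossContamFlag]:
    """Review air samples for between-city cross-contamination.

    ``embedding`` holds 2-D coordinates indexed by sample id (air samples).
    For each sample, the majority city among its ``k`` nearest neighbours is
    compared with its assigned city; mismatches become candidates. The
    verdict is ``exclude`` only when both metadata confirmations hold.
    """
    meta = (
        metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    )
    ids = [s for s in embedding.index if s in meta.index]
    if len(ids) < 2:
        raise TableError("need at least two embedded samples")
    coords = embedding.loc[ids].to_numpy(dtype=float)
    cities = meta.loc[ids, "city"].to_numpy()
    k_eff = min(k, len(ids) - 1)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    flags: list[CrossContamFlag] = []
    for i, sid in enumerate(ids):
        nbr = np.argsort(d2[i])[:k_eff]
        nbr_cities = pd.Series(cities[nbr])
        top_city = nbr_cities.value_counts().idxmax()
        if top_city == cities[i]:
            continue
        if (nbr_cities == top_city).sum() <= k_eff / 2:
            continue
        below = bool(meta.at[sid, "dna_below_detection"])
        own_well = meta.at[sid, "plate_position"]
        neighbor_wells = meta.loc[
            (meta["city"] == top_city) & (meta.index != sid), "plate_position"
        ]
        adjacent = any(
            _wells_adjacent(own_well, w) for w in neighbor_wells.dropna()
        )
        verdict = "exclude" if (below and adjacent) else "retain"
        flags.append(
            CrossContamFlag(
                sample_id=sid,
                assigned_city=str(cities[i]),
                embedded_neighbor_city=str(top_city),
                dna_below_detection=below,
                plate_adjacent_to_neighbor_city=adjacent,
                verdict=verdict,
            )
        )
    return flags
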