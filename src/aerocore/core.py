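"""Core / sub-core microbiome inference from species prevalence.

A species is *present* in a sample when its within-sample relative abundance
(on the decontaminated, abundance-filtered count table) reaches a given
level; prevalence is the fraction of samples where it is present. Prevalence
is evaluated at four abundance levels (0.005%, 0.3%, 0.5%, 1%). A species is
``core`` when present in strictly more than 97% of samples and ``sub_core``
in 70–97% (closed interval); for the biological core the species must also
pass the negatives prevalence Z gate. Local cores repeat the computation
within each city against the pooled negatives; the contaminant core applies
the same tiers, un-gated, to the flagged contaminant taxa before removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decontam import ZGateResult
from .tables import TableError, TaxonCountTable

log = logging.getLogger(__name__)

#: within-sample relative-abundance levels at which prevalence is evaluated
ABUNDANCE_LEVELS = (0.00005, 0.003, 0.005, 0.01)

CORE_PREVALENCE = 0.97  # strict >
SUBCORE_PREVALENCE = 0.70  # closed lower bound


def species_prevalence(
    table: TaxonCountTable, abundance_level: float = ABUNDANCE_LEVELS[0]
) -> pd.DataFrame:
    """Prevalence and mean relative abundance of every taxon at one level.

    Presence in a sample means relative abundance >= ``abundance_level``.
    ``mean_abundance`` averages the relative abundance over *all* samples
    (absences contribute zero).
    """
    if table.n_samples == 0:
        raise TableError("no samples")
    if not (0.0 <= abundance_level < 1.0):
        raise TableError(f"abundance level {abundance_level} outside [0, 1)")
    rel = table.relative()
    present = rel >= abundance_level
    # a taxon absent from a sample (abundance 0) is never present, even at level 0
    present &= rel > 0
    n_present = present.sum(axis=0).astype(int)
    frame = pd.DataFrame(
        {
            "name": table.taxa["name"],
            "kingdom": table.taxa["kingdom"],
            "abundance_level": abundance_level,
            "n_present": n_present,
            "n_samples": table.n_samples,
            "prevalence": n_present / table.n_samples,
            "mean_abundance": rel.mean(axis=0),
        }
    )
    frame.index.name = "taxid"
    return frame


@dataclass
class CoreReport:
    """Tier assignment of taxa at one abundance level for one scope."""

    scope: str  # "global" | "city:<name>" | "contaminant"
    table: pd.DataFrame  # prevalence profile + tier (+ gate columns)
    abundance_level: float
    core_prevalence: float = CORE_PREVALENCE
    subcore_prevalence: float = SUBCORE_PREVALENCE
    coverage_subset_applied: bool = False

    def tier_taxids(self, tier: str) -> set[int]:
        return set(self.table.index[self.table["tier"] == tier].astype(int))

    @property
    def core_taxids(self) -> set[int]:
        return self.tier_taxids("core")

    @property
    def subcore_taxids(self) -> set[int]:
        return self.tier_taxids("sub_core")


def assign_tiers(
    profiles: pd.DataFrame,
    gate: Mapping[int, ZGateResult] | None = None,
    scope: str = "global",
    core_prevalence: float = CORE_PREVALENCE,
    subcore_prevalence: float = SUBCORE_PREVALENCE,
    coverage_subset_applied: bool = False,
) -> CoreReport:
    """Assign core / sub_core / none tiers to a prevalence profile.

    ``core``: prevalence strictly above ``core_prevalence`` (and Z gate
    passed, when a gate is supplied); ``sub_core``: prevalence in
    ``[subcore_prevalence, core_prevalence]`` with the same gating; taxa
    failing the gate are ``none`` regardless of prevalence. Rows are ordered
    by prevalence desc, mean abundance desc, taxid asc.
    """
    frame = profiles.copy()
    prev = frame["prevalence"]
    tier = np.where(
        prev > core_prevalence,
        "core",
        np.where(prev >= subcore_prevalence, "sub_core", "none"),
    )
    frame["tier"] = tier
    if gate is not None:
        passed = frame.index.map(
            lambda t: bool(gate[int(t)].passes) if int(t) in gate else False
        )
        frame["gate_pass"] = passed
        frame["z"] = frame.index.map(
            lambda t: gate[int(t)].z if int(t) in gate else np.nan
        )
        frame["p_value"] = frame.index.map(
            lambda t: gate[int(t)].p_value if int(t) in gate else np.nan
        )
        frame.loc[~frame["gate_pass"], "tier"] = "none"
    frame["ubiquitous"] = frame["prevalence"] == 1.0
    frame["_taxid"] = frame.index.astype(int)
    frame = frame.sort_values(
        ["prevalence", "mean_abundance", "_taxid"], ascending=[False, False, True]
    ).drop(columns="_taxid")
    return CoreReport(
        scope=scope,
        table=frame,
        abundance_level=float(profiles["abundance_level"].iloc[0]),
        core_prevalence=core_prevalence,
        subcore_prevalence=subcore_prevalence,
        coverage_subset_applied=coverage_subset_applied,
    )


def local_cores(
    table: TaxonCountTable,
    metadata: pd.DataFrame,
    gate: Mapping[int, ZGateResult] | None = None,
    abundance_level: float = ABUNDANCE_LEVELS[0],
    **tier_kwargs,
) -> dict[str, CoreReport]:
    """Per-city core reports; prevalence recomputed within each city's air
    samples, reusing the single pooled-negatives gate."""
    air = metadata[metadata["sample_type"] == "air"]
    reports: dict[str, CoreReport] = {}
    for city, rows in air.groupby("city"):
        ids = [s for s in rows.index if s in set(table.sample_ids)]
        if len(ids) < 2:
            raise TableError(
                f"city {city!r} has {len(ids)} sample(s); prevalence thresholds undefined"
            )
        profiles = species_prevalence(table.subset_samples(ids), abundance_level)
        reports[str(city)] = assign_tiers(
            profiles, gate=gate, scope=f"city:{city}", **tier_kwargs
        )
    return reports


def coverage_subset(
    table: TaxonCountTable, metadata: pd.DataFrame, min_coverage: float = 0.5
) -> TaxonCountTable:
    """Restrict to samples with Nonpareil coverage strictly above the cut.

    Samples with missing coverage are excluded with a warning.
    """
    ids = [s for s in table.sample_ids if s in metadata.index]
    cov = pd.to_numeric(metadata.loc[ids, "nonpareil_coverage"], errors="coerce")
    missing = cov.index[cov.isna()].tolist()
    if missing:
        log.warning(
            "%d sample(s) lack Nonpareil coverage and are excluded: %s%s",
            len(missing),
            missing[:5],
            "..." if len(missing) > 5 else "",
        )
    keep = cov.index[cov > min_coverage].tolist()
    if not keep:
        raise TableError("no samples above the coverage cut")
    return table.subset_samples(keep)


def contaminant_core(
    table_before_removal: TaxonCountTable,
    contaminant_taxids: Iterable[int],
    sample_ids: Sequence[str] | None = None,
    abundance_level: float = 0.0,
    **tier_kwargs,
) -> CoreReport:
    """Tier the flagged contaminants by prevalence across all samples.

    Computed on the table *before* contaminant removal; no Z gate (these are
    the gated-out taxa). With the default ``abundance_level`` of 0, presence
    means any classified read. Taxa at 100% prevalence carry the
    ``ubiquitous`` flag.
    """
    sub = table_before_removal
    if sample_ids is not None:
        sub = sub.subset_samples(sample_ids)
    keep = [t for t in sub.taxids if t in set(int(x) for x in contaminant_taxids)]
    sub = TaxonCountTable(sub.counts.loc[:, keep], sub.taxa.loc[keep])
    profiles = species_prevalence(sub, abundance_level)
    return assign_tiers(profiles, gate=None, scope="contaminant", **tier_kwargs)


def prevalence_curve(
    profiles_per_level: Mapping[float, pd.DataFrame],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Species counts above a grid of prevalence thresholds, per level.

    For each prevalence threshold t, counts species with prevalence >= t;
    the curve is non-increasing in t and, for nested levels, in the level.
    Returns a tidy frame (abundance_level, threshold, n_species) with the
    threshold as a percentage of samples.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    rows = []
    for level in sorted(profiles_per_level):
        prev = profiles_per_level[level]["prevalence"].to_numpy()
        for t in thresholds:
            rows.append(
                {
                    "abundance_level": level,
                    "threshold": float(t) * 100.0,
                    "n_species": int((prev >= t).sum() if t > 0 else (prev > 0).sum()),
                }
            )
    return pd.DataFrame(rows)
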