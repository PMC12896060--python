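"""Shared fixtures: synthetic surveys at two scales and pipeline products."""

from dataclasses import dataclass

import pandas as pd
import pytest

import aerocore as ac


def small_config(**overrides) -> ac.SyntheticConfig:
    """A miniature survey for plumbing tests (3 cities x 2 years x 5 samples)."""
    defaults = dict(
        n_cities=3,
        samples_per_city_year=5,
        years=(2018, 2019),
        n_negatives=6,
        n_species_shared=40,
        n_species_city_specific=12,
        n_contaminants=10,
        n_contaminants_in_air=1,
        core_species_per_city=4,
        depth_mean=30_000.0,
        neg_depth_mean=60_000.0,
        seed=7,
    )
    defaults.update(overrides)
    return ac.SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_survey():
    return ac.generate(small_config())


@pytest.fixture(scope="session")
def survey():
    """Full default-scale survey (6 cities x 3 years x 14 air samples)."""
    return ac.generate(ac.SyntheticConfig(seed=11))


@dataclass
class Pipeline:
    table: ac.TaxonCountTable
    meta: pd.DataFrame
    truth: ac.SyntheticTruth
    air_ids: list
    neg_ids: list
    evidence: pd.DataFrame
    contaminants: set
    filtered: ac.TaxonCountTable
    cleaned: ac.TaxonCountTable
    removal_summary: pd.DataFrame
    gate: dict
    log_air: ac.NormalizedTable


def run_pipeline(table, meta_records, truth) -> Pipeline:
    """Canonical order: 0.005% filter -> contaminant removal -> normalize -> log."""
    meta = ac.metadata_frame(meta_records)
    air = list(meta.index[meta["sample_type"] == "air"])
    neg = list(meta.index[meta["sample_type"].isin(("field_negative", "lab_negative"))])
    evidence = ac.identify_contaminants(table, neg)
    contaminants = ac.contaminant_set(evidence)
    filtered = ac.abundance_threshold_filter(table)
    cleaned, summary = ac.remove_taxa(filtered, contaminants)
    gate = ac.gate_all_taxa(filtered, air, neg)
    log_air = ac.log_transform(ac.normalize_counts(cleaned.subset_samples(air)))
    return Pipeline(
        table=table,
        meta=meta,
        truth=truth,
        air_ids=air,
        neg_ids=neg,
        evidence=evidence,
        contaminants=contaminants,
        filtered=filtered,
        cleaned=cleaned,
        removal_summary=summary,
        gate=gate,
        log_air=log_air,
    )


@pytest.fixture(scope="session")
def pipeline(survey) -> Pipeline:
    return run_pipeline(*survey)


@pytest.fixture(scope="session")
def small_pipeline(small_survey) -> Pipeline:
    return run_pipeline(*small_survey)
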