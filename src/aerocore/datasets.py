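"""Packaged summary tables from the six-city public-transit aerobiome survey.

Three small TSVs ship with the package:

``table1_sample_counts.tsv``
    Collected/sequenced sample counts per city, year and sample type
    (750 air samples in total, plus negative and positive controls).
``table2_species_counts.tsv``
    Classified species counts per city and kingdom after contaminant
    removal (3577 species over all cities combined).
``contaminant_prevalence.tsv``
    The 290 contaminant taxa (265 bacterial, 25 fungal) with their
    prevalence across the 750 air samples before removal. The 16 core-tier
    contaminants are the published named species; per-species prevalences
    outside the four 100%-prevalence taxa are deterministic stand-in values
    inside their published band (see the file's generation note), which tier
    assignment does not depend on.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("aerocore.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_sample_counts() -> pd.DataFrame:
    """Per city/year/sample-type sample counts (tidy)."""
    return _read("table1_sample_counts.tsv")


def total_air_samples(frame: pd.DataFrame | None = None) -> int:
    """Total air samples across all cities and years."""
    frame = load_sample_counts() if frame is None else frame
    return int(frame.loc[frame["sample_type"] == "air", "n_samples"].sum())


def city_air_samples(city: str, frame: pd.DataFrame | None = None) -> int:
    """Air samples collected in one city across all years."""
    frame = load_sample_counts() if frame is None else frame
    air = frame[(frame["sample_type"] == "air") & (frame["city"] == city)]
    if air.empty:
        raise KeyError(f"no air samples recorded for city {city!r}")
    return int(air["n_samples"].sum())


def load_species_counts() -> pd.DataFrame:
    """Classified species per city and kingdom (tidy)."""
    return _read("table2_species_counts.tsv")


def city_species_total(city: str, frame: pd.DataFrame | None = None) -> int:
    """Total classified species in one city (sum over kingdoms)."""
    frame = load_species_counts() if frame is None else frame
    sub = frame[frame["city"] == city]
    if sub.empty:
        raise KeyError(f"city {city!r} not in the species table")
    return int(sub["n_species"].sum())


def load_contaminant_prevalence() -> pd.DataFrame:
    """Contaminant prevalence profile, shaped for ``core.assign_tiers``.

    Indexed by taxid with ``name``, ``kingdom``, ``n_present``,
    ``n_samples``, ``prevalence``, ``mean_abundance`` (not published;
    zero-filled) and ``abundance_level`` columns.
    """
    frame = _read("contaminant_prevalence.tsv").set_index("taxid")
    frame["prevalence"] = frame["n_present"] / frame["n_samples"]
    frame["mean_abundance"] = 0.0
    frame["abundance_level"] = 0.0
    return frame
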