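"""Synthetic taxon-count tables with the statistical structure of a
low-biomass urban aerobiome survey.

The generator emulates the classified, species-level count tables and sample
metadata *downstream* of taxonomic classification for a multi-city,
multi-year air-sampling campaign: a handful of cities sampled over several
summers, a shared pool of transient background species, city-specific species
pools with a planted high-prevalence core, ~20 negative controls dominated by
a common contaminant profile (kitome / handler flora), and air samples whose
classified reads are a Beta-mixed blend of that contaminant profile and the
city's biological community.

Everything is driven by a single seeded RNG with a fixed draw order, so a
given :class:`SyntheticConfig` is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import SampleRecord
from .tables import TaxonCountTable, make_taxa_frame

_DEFAULT_CITIES = ("Avalon", "Brookfield", "Calder", "Dunmore", "Eastvale", "Farrow")


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic aerobiome survey.

    Defaults describe a 6-city x 3-year campaign: 14 air samples per city and
    year (252 air samples), 20 pooled negative controls, a mean planted
    contaminant read fraction of 0.6 of classified reads in air, lognormal
    per-sample depth around 100,000 classified read pairs, and 12 planted
    core species per city.
    """

    n_cities: int = 6
    samples_per_city_year: int = 14
    years: tuple[int, ...] = (2017, 2018, 2019)
    n_negatives: int = 20
    n_species_shared: int = 150
    n_species_city_specific: int = 40
    n_contaminants: int = 30
    #: contaminants also genuinely present in air (homologous taxa)
    n_contaminants_in_air: int = 3
    contaminant_read_fraction_mean: float = 0.6
    #: Beta concentration (a+b) of the per-sample contaminant fraction
    contaminant_fraction_concentration: float = 12.0
    depth_mean: float = 100_000.0
    depth_sigma: float = 0.5
    neg_depth_mean: float = 200_000.0
    neg_depth_sigma: float = 0.3
    #: lognormal sigma of species abundance weights
    abundance_shape: float = 1.5
    #: fold applied to city-specific species weights
    city_effect_size: float = 5.0
    core_species_per_city: int = 12
    #: share of a sample's biological reads carried by the planted core
    core_mass_fraction: float = 0.5
    #: per-sample presence probability of background (transient) species
    background_occupancy: float = 0.6
    #: share of negative-control reads not from the contaminant profile
    neg_background_fraction: float = 0.005
    #: multiplicative abundance shift of responsive species in humid samples
    humidity_effect_size: float = 1.0
    humidity_responsive_species: int = 40
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_cities",
            "samples_per_city_year",
            "n_negatives",
            "n_species_shared",
            "n_species_city_specific",
            "n_contaminants",
            "core_species_per_city",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "core_mass_fraction",
            "background_occupancy",
            "neg_background_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if not (0.0 <= self.contaminant_read_fraction_mean < 1.0):
            raise ConfigError("contaminant_read_fraction_mean must lie in [0, 1)")
        if self.core_species_per_city > self.n_species_city_specific:
            raise ConfigError("core species per city exceed the city-specific pool")
        if self.n_contaminants_in_air > self.n_contaminants:
            raise ConfigError("homologous contaminants exceed the contaminant pool")
        if self.n_negatives < 2:
            raise ConfigError("need at least 2 negative controls")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic table."""

    contaminant_taxids: set[int]
    city_core_taxids: dict[str, set[int]]
    #: per-sample fraction of classified reads from contaminant taxa
    contaminant_fraction: dict[str, float]
    humidity_responsive_taxids: set[int]
    config: SyntheticConfig

    def as_dict(self) -> dict:
        return {
            "contaminant_taxids": sorted(self.contaminant_taxids),
            "city_core_taxids": {
                c: sorted(t) for c, t in self.city_core_taxids.items()
            },
            "contaminant_fraction": self.contaminant_fraction,
            "humidity_responsive_taxids": sorted(self.humidity_responsive_taxids),
            "config": asdict(self.config),
        }


def _kingdom_draw(rng: np.random.Generator, n: int, p_fungi: float) -> list[str]:
    kingdoms = np.array(["Bacteria", "Fungi", "Archaea", "Virus"])
    probs = np.array([1 - p_fungi - 0.02, p_fungi, 0.01, 0.01])
    return list(rng.choice(kingdoms, size=n, p=probs))


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[TaxonCountTable, list[SampleRecord], SyntheticTruth]:
    """Generate a classified count table, metadata, and planted ground truth.

    Draw order is fixed (taxa, profiles, city covariate means, then samples
    in city/year/replicate order, then negatives) so results are
    reproducible for a given ``config.seed``.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cities = [
        _DEFAULT_CITIES[i] if i < len(_DEFAULT_CITIES) else f"City{i + 1:02d}"
        for i in range(config.n_cities)
    ]

    # --- taxon registry ---------------------------------------------------
    cont_ids = np.arange(1001, 1001 + config.n_contaminants)
    shared_ids = np.arange(2001, 2001 + config.n_species_shared)
    city_ids = {
        city: np.arange(
            10_000 * (i + 1) + 1, 10_000 * (i + 1) + 1 + config.n_species_city_specific
        )
        for i, city in enumerate(cities)
    }
    records = []
    # contaminant kingdoms mirror the dominance of bacterial kit/handler flora
    cont_kingdoms = _kingdom_draw(rng, config.n_contaminants, p_fungi=0.10)
    for t, k in zip(cont_ids, cont_kingdoms):
        records.append((int(t), f"Contaminant species {t}", "species", k))
    for t, k in zip(shared_ids, _kingdom_draw(rng, config.n_species_shared, 0.30)):
        records.append((int(t), f"Cosmopolitan species {t}", "species", k))
    for city in cities:
        ids = city_ids[city]
        for t, k in zip(ids, _kingdom_draw(rng, len(ids), 0.30)):
            records.append((int(t), f"{city} species {t}", "species", k))
    taxa = make_taxa_frame(records)
    taxids = taxa.index.to_numpy()
    col_index = {t: j for j, t in enumerate(taxids)}

    # --- profiles ---------------------------------------------------------
    cont_profile = rng.lognormal(0.0, 0.5, config.n_contaminants)
    cont_profile /= cont_profile.sum()
    shared_w = rng.lognormal(0.0, config.abundance_shape, config.n_species_shared)
    homolog_ids = cont_ids[: config.n_contaminants_in_air]
    homolog_w = np.full(config.n_contaminants_in_air, shared_w.mean())
    core_taxids: dict[str, set[int]] = {}
    city_core_w: dict[str, np.ndarray] = {}
    city_bg_ids: dict[str, np.ndarray] = {}
    city_bg_w: dict[str, np.ndarray] = {}
    for city in cities:
        ids = city_ids[city]
        core = ids[: config.core_species_per_city]
        noncore = ids[config.core_species_per_city :]
        core_taxids[city] = set(int(t) for t in core)
        city_core_w[city] = rng.lognormal(0.0, 0.5, len(core))
        noncore_w = (
            rng.lognormal(0.0, config.abundance_shape, len(noncore))
            * config.city_effect_size
        )
        city_bg_ids[city] = np.concatenate([shared_ids, noncore, homolog_ids])
        city_bg_w[city] = np.concatenate([shared_w, noncore_w, homolog_w])

    humid_ids = set(int(t) for t in shared_ids[: config.humidity_responsive_species])

    # --- city covariates --------------------------------------------------
    city_temp = rng.uniform(18.0, 30.0, config.n_cities)
    city_hum = rng.uniform(50.0, 80.0, config.n_cities)
    n_localities = 5
    locality_level = {
        (city, j): ("above" if rng.random() < 0.5 else "below")
        for city in cities
        for j in range(n_localities)
    }

    # --- air samples ------------------------------------------------------
    f_mean = config.contaminant_read_fraction_mean
    conc = config.contaminant_fraction_concentration
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    metadata: list[SampleRecord] = []
    plate_wells = [f"{r}{c}" for c in range(1, 13) for r in "ABCDEFGH"]
    well_cursor = 0

    def next_well() -> str:
        nonlocal well_cursor
        well = f"P{well_cursor // 96 + 1}:{plate_wells[well_cursor % 96]}"
        well_cursor += 1
        return well

    for ci, city in enumerate(cities):
        core = np.fromiter(sorted(core_taxids[city]), dtype=int)
        core_w = city_core_w[city]
        bg_ids = city_bg_ids[city]
        bg_base_w = city_bg_w[city]
        for year in config.years:
            for rep in range(config.samples_per_city_year):
                sid = f"{city[:3].upper()}-{year}-{rep + 1:03d}"
                loc = int(rng.integers(n_localities))
                temperature = float(rng.normal(city_temp[ci], 4.0))
                humidity = float(np.clip(rng.normal(city_hum[ci], 10.0), 15, 98))
                travellers = int(rng.lognormal(4.3, 0.8))
                # contaminant share of classified reads
                if f_mean == 0.0:
                    f_cont = 0.0
                else:
                    f_cont = float(rng.beta(f_mean * conc, (1 - f_mean) * conc))
                # background: occupancy mask + per-sample abundance jitter
                occ = rng.random(len(bg_ids)) < config.background_occupancy
                jitter = rng.lognormal(0.0, 0.5, len(bg_ids))
                bg_w = bg_base_w * occ * jitter
                if config.humidity_effect_size != 1.0 and humidity > 65.0:
                    responsive = np.isin(bg_ids, list(humid_ids))
                    bg_w = bg_w * np.where(
                        responsive, config.humidity_effect_size, 1.0
                    )
                p = np.zeros(len(taxids))
                core_share = config.core_mass_fraction * (1.0 - f_cont)
                p[[col_index[t] for t in core]] = (
                    core_w / core_w.sum() * core_share
                )
                if bg_w.sum() > 0:
                    bg_share = (1.0 - config.core_mass_fraction) * (1.0 - f_cont)
                    p[[col_index[t] for t in bg_ids]] += (
                        bg_w / bg_w.sum() * bg_share
                    )
                cont_jit = rng.dirichlet(cont_profile * 200.0)
                p[[col_index[t] for t in cont_ids]] += cont_jit * f_cont
                p /= p.sum()
                depth = int(
                    rng.lognormal(math.log(config.depth_mean), config.depth_sigma)
                )
                rows.append(rng.multinomial(depth, p))
                sample_ids.append(sid)
                metadata.append(
                    SampleRecord(
                        sample_id=sid,
                        city=city,
                        year=year,
                        sample_type="air",
                        locality=f"{city}-L{loc + 1}",
                        temperature=round(temperature, 1),
                        humidity=round(humidity, 1),
                        travellers=travellers,
                        ground_level=locality_level[(city, loc)],
                        dna_conc=round(float(rng.lognormal(-1.5, 0.8)), 4),
                        plate_position=next_well(),
                        nonpareil_coverage=round(float(rng.uniform(0.2, 0.95)), 3),
                    )
                )

    # --- negative controls ------------------------------------------------
    nbf = config.neg_background_fraction
    for j in range(config.n_negatives):
        sid = f"NEG-{j + 1:03d}"
        occ = rng.random(len(shared_ids)) < config.background_occupancy
        jitter = rng.lognormal(0.0, 0.5, len(shared_ids))
        bgw = shared_w * occ * jitter
        p = np.zeros(len(taxids))
        cont_jit = rng.dirichlet(cont_profile * 200.0)
        p[[col_index[t] for t in cont_ids]] = cont_jit * (1.0 - nbf)
        if bgw.sum() > 0:
            p[[col_index[t] for t in shared_ids]] += bgw / bgw.sum() * nbf
        p /= p.sum()
        depth = int(
            rng.lognormal(math.log(config.neg_depth_mean), config.neg_depth_sigma)
        )
        rows.append(rng.multinomial(depth, p))
        sample_ids.append(sid)
        metadata.append(
            SampleRecord(
                sample_id=sid,
                city=cities[j % len(cities)] if j % 2 == 0 else "lab",
                year=config.years[j % len(config.years)],
                sample_type="field_negative" if j % 2 == 0 else "lab_negative",
                plate_position=next_well(),
            )
        )

    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=taxids)
    table = TaxonCountTable(counts, taxa)

    cont_set = set(int(t) for t in cont_ids)
    frac = {}
    cont_cols = [col_index[t] for t in cont_ids]
    matrix = counts.to_numpy()
    for i, sid in enumerate(sample_ids):
        total = matrix[i].sum()
        frac[sid] = float(matrix[i, cont_cols].sum() / total) if total else 0.0
    truth = SyntheticTruth(
        contaminant_taxids=cont_set,
        city_core_taxids=core_taxids,
        contaminant_fraction=frac,
        humidity_responsive_taxids=humid_ids,
        config=config,
    )
    return table, metadata, truth


def generate_positive_control(
    n_species: int = 8,
    depth: int = 1_000_000,
    even: bool = True,
    seed: int = 0,
) -> TaxonCountTable:
    """An even mock community (ZymoBIOMICS-style) as a single-sample table.

    Used to sanity-check that abundance thresholds retain all mock members:
    at 8 even species each sits at 12.5%, orders of magnitude above the
    0.005% filter.
    """
    if depth <= 0:
        raise ConfigError("positive-control depth must be positive")
    if n_species <= 0:
        raise ConfigError("n_species must be positive")
    rng = np.random.default_rng(seed)
    ids = np.arange(90_001, 90_001 + n_species)
    taxa = make_taxa_frame(
        [
            (int(t), f"Mock species {t}", "species", "Bacteria" if i < n_species - 2 else "Fungi")
            for i, t in enumerate(ids)
        ]
    )
    if even:
        p = np.full(n_species, 1.0 / n_species)
    else:
        p = rng.dirichlet(np.full(n_species, 5.0))
    counts = pd.DataFrame(
        [rng.multinomial(depth, p)], index=["MOCK-001"], columns=ids
    )
    return TaxonCountTable(counts, taxa)
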