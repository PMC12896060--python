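"""Bookkeeping on the packaged survey summary tables.

The package ships the survey's sample manifest, classified-species counts
and contaminant prevalence table as small TSVs; the same aggregation and
tiering operations used in the pipeline reproduce the published totals.
"""

import aerocore as ac
from aerocore import datasets

manifest = datasets.load_sample_counts()
print(f"air samples, all cities/years: {datasets.total_air_samples(manifest)}")
print(f"air samples, Hong Kong:        {datasets.city_air_samples('Hong Kong', manifest)}")

species = datasets.load_species_counts()
for city in ("All", "Hong Kong", "Denver"):
    print(f"classified species, {city:<10} {datasets.city_species_total(city, species)}")

contam = datasets.load_contaminant_prevalence()
counts = contam["kingdom"].value_counts()
print(f"contaminant taxa: {counts.sum()} = {counts['Bacteria']} bacterial "
      f"+ {counts['Fungi']} fungal")
report = ac.assign_tiers(contam, gate=None, scope="contaminant")
print(f"contaminant core tier (prevalence > 97%): {len(report.core_taxids)} species, "
      f"of which {int(report.table['ubiquitous'].sum())} ubiquitous (100%)")
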