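# Methods

## The pipeline and its assumptions

`aerocore` operates strictly downstream of taxonomic classification: its
inputs are species-level read-count tables (one column per sample) and a
sample metadata sheet. The canonical order of operations is

1. species-level count table (Kraken2 clade counts of `S`-rank rows, or
   Bracken `new_est_reads`);
2. 0.005% within-sample abundance filter;
3. contaminant identification from pooled negative controls and removal;
4. normalization to 10,000,000 reads per sample;
5. log₁₀(x + 1).

Raw counts and transformed values are distinct types (`TaxonCountTable` vs
`NormalizedTable` with a `transform_tag`), so a stage cannot silently
receive the wrong representation: contaminant identification and prevalence
work on raw counts, ordination and MANOVA on the log-normalized table.

The decontamination model assumes a *shared* exogenous source (kitome,
reagents, handler flora) that dominates negative controls and contributes a
large, sample-varying share of air-sample reads. It is a presence/abundance
rule on pooled raw evidence, not a frequency-correlation mixture model:
a contaminant must appear in at least `min_negatives = 2` negative controls
(field and lab blanks pooled — their community profiles are
indistinguishable in this design) and exceed `min_total_reads = 10,000`
summed raw reads over all negatives (strict inequality). Both thresholds are
exposed because they trade sensitivity against specificity; raising them
retains more contamination and inflates apparent between-sample homogeneity.
Presence in a negative means any classified read *before* the abundance
filter: negatives are sparse and thresholding them would hide contaminants.

Because the sampled environment and the processing environment share taxa
(human-associated species above all), outright removal is paired with a
re-admission gate for prevalence analyses: a one-sided two-proportion Z test
with pooled variance, no continuity correction and no multiple-testing
adjustment, at α = 0.05. Degenerate inputs are handled explicitly: equal
prevalences (including pooled p̂ ∈ {0, 1}) never pass and are flagged
`degenerate`; a taxon absent from every negative but present in air passes
with flag `trivially_greater` — absence from blanks is the strongest
evidence the test can express, and the normal approximation is meaningless
there.

Cross-contamination review between cities follows a two-evidence rule: a
sample whose embedding neighbours are majority another city is only a
*candidate*; exclusion additionally requires DNA concentration below the
detection limit **and** a library-plate well adjacent (Chebyshev distance 1,
same plate) to a sample of the neighbour city. Candidacy alone never
excludes.

## Diversity and factor analysis

Alpha diversity is the Shannon index in nats, a function of within-sample
proportions only (depth-invariant). Group comparison uses Tukey's HSD with
the Tukey–Kramer harmonic-mean correction for unbalanced groups (delegated
to statsmodels), and the compact letter display is built with the
insert-and-absorb procedure, so two groups share a letter exactly when their
difference is not significant.

The factor analysis is a forward-stepwise MANOVA on the top-10 PC scores of
the log-normalized table. Continuous covariates are binarised before
modelling — temperature at 25 °C, relative humidity at 65%, travellers at
100, boundary values assigned to the lower class — which keeps group sizes
comparable and the contrasts interpretable. At each step every eligible
candidate term is added to the current model; the added-term hypothesis SSCP
is H = E_current − E_candidate and Pillai's trace V = tr[H(H + E)⁻¹] is
converted to an approximate F through the standard s/m/n parameterisation.
The candidate with the largest F among those with p < 0.001 enters;
CITY:X interactions become eligible only once CITY and X are both included
(model hierarchy); selection stops when no candidate qualifies. Rows with a
missing value in any candidate covariate are dropped once up front and the
count is reported on the model — per-term complete cases would make the
between-candidate F comparison incoherent. Candidates that add no rank
(collinear) are skipped with a note; an error SSCP with too few degrees of
freedom raises, naming the term. The procedure is deterministic given the
input ordering and uses no randomness.

UMAP (n_neighbors = 15, min_dist = 0.1, fixed seed 42 by default) is used
for visualisation and the k-NN city-purity diagnostic only; no inferential
statistic is computed from the embedding.

## Core microbiome

Presence at an abundance level means within-sample relative abundance ≥ the
level, computed on the decontaminated, filtered *count* table — prevalence
is therefore depth-invariant by construction. Tier boundaries reconcile the
two conventional phrasings: `core` is strictly > 0.97, `sub_core` is the
closed interval [0.70, 0.97]; both are configurable. The Z gate is computed
once per taxon (air vs pooled negatives, presence = any read) and reused
across scopes; negatives are not city-specific, so local cores do not
recompute it. Mean abundance averages over all samples, absences included.
The contaminant core applies the same tiers to the flagged taxa on the
pre-removal table, un-gated, with taxa at 100% prevalence flagged
`ubiquitous`. Report rows are ordered by prevalence desc, mean abundance
desc, taxid asc. The Nonpareil coverage subset keeps samples with coverage
strictly > 0.5 and warns about samples lacking a coverage estimate.

## The synthetic-data generator

The generator emulates the classified count tables of a six-city,
three-summer survey (2017–2019) at desk scale: 14 air samples per city-year
(252 air samples), 20 negative controls, and lognormal per-sample depth with
median ≈ 100,000 classified read pairs (depth and sample count are scaled
down from a deep-sequencing campaign by roughly two orders of magnitude;
all downstream statistics operate on proportions and prevalences, which
this preserves). Its components:

- a **contaminant profile** (30 species, mildly uneven lognormal weights)
  shared by all negatives with per-sample Dirichlet jitter; negatives are
  (1 − 0.005) contaminant profile plus a sparse background leak. Air samples
  mix the same profile at a Beta(μ·c, (1−μ)·c) fraction with μ = 0.6,
  c = 12, matching the regime where most classified air reads are
  exogenous; a configurable subset of contaminants is also planted in the
  air pool (the homologous-taxa hard case);
- **city-specific pools** (40 species per city) of which 12 are planted
  core species carrying half of a sample's biological reads — hence present
  far above the 0.005% level in essentially every sample of their city —
  and a **shared cosmopolitan pool** (150 species) with lognormal
  (σ = 1.5) abundance weights;
- **transient occupancy**: every background species is present in a given
  sample with probability 0.6 and its abundance gets per-sample lognormal
  jitter. This is the mechanism behind the clear margin between planted
  cores (occupancy 1, high abundance) and background (global prevalence
  well below the 70% sub-core bound), which makes exact recovery of the
  planted core sets a well-defined expectation rather than a coincidence;
- **metadata covariates** drawn per city (temperature, humidity) and per
  sample (travellers, locality with fixed ground level, DNA concentration,
  plate well, Nonpareil coverage), independent of composition unless an
  effect is planted. The optional humidity effect multiplies the abundance
  of 40 designated responsive species by a configurable fold (6 in the
  recovery tests) in samples with humidity > 65%, giving the MANOVA a
  planted environmental signal to find.

All draws come from one `numpy` Generator seeded from `config.seed`, in a
fixed order (taxa, profiles, covariate means, samples in city/year/replicate
order, negatives), so outputs are exactly reproducible.

What the generator does **not** emulate: read-level error and classifier
confusion, genome-size effects on read counts, shared species between city
pools (city signatures are cleaner than in real data), seasonal/diurnal
structure, and depth-correlated coverage. Consequently, passing recovery
tests demonstrates the correctness and calibration of the pipeline's logic
under its stated assumptions — not that real surveys will yield
precision/recall of 1; with homologous taxa, shallow negatives or
correlated covariates the published trade-offs apply.

## Numerical choices and limitations

- The 0.005% filter keeps counts exactly at the threshold (≥); it is
  idempotent because zeroing only lowers sample totals, which cannot
  un-keep a retained count.
- Normalized rows sum to 10⁷ within 1e-9 relative tolerance; all-zero
  samples stay zero and are flagged rather than dropped silently.
- Log transform is base 10 with pseudocount 1 on normalized counts; the
  base affects no rank-based downstream result and is trivially changed.
- Abundance summaries compute the last row (`other`, or the last kingdom)
  as a residual so each group sums to 100 up to float re-association
  (≤ 1e-9).
- Kraken2 ingestion uses clade counts of species rows (sub-species rolled
  up), switchable to direct counts; Bracken ingestion uses `new_est_reads`.
  Estimated read counts, not fractions, feed the abundance filter.
- Species ties in top-N summaries break by ascending taxid; tier reports
  order by prevalence, then mean abundance, then taxid.
- IO is plain UTF-8 TSV throughout (no binary BIOM); missing metadata is
  an explicit missing marker, never zero, and an unmeasurably low DNA
  concentration (`BD`) is distinct from a measured zero.

Known limitations: the MANOVA assumes the PC scores are adequate summaries
(components beyond the top 10 are discarded regardless of what they carry);
the Z gate is computed per taxon without multiplicity control, as is
conventional for this gating use; the cross-contamination reviewer requires
plate positions to share a plate naming scheme; and the CLI's contaminant
core report is only meaningful when pointed at the pre-removal table.
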