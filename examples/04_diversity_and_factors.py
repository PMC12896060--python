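"""Alpha/beta diversity and which study factors shape community structure.

Shannon diversity with Tukey-HSD letters per city; a seeded UMAP embedding;
and a forward-stepwise MANOVA on the top-10 PC scores using Pillai's trace
(inclusion threshold p < 0.001) over city, year, ground level and the
binarised environmental/human covariates.
"""

import aerocore as ac

table, records, _ = ac.generate(ac.SyntheticConfig(seed=1))
meta = ac.metadata_frame(records)
air = list(meta.index[meta["sample_type"] == "air"])
neg = list(meta.index[meta["sample_type"].isin(("field_negative", "lab_negative"))])
cleaned, _ = ac.remove_taxa(
    ac.abundance_threshold_filter(table),
    ac.contaminant_set(ac.identify_contaminants(table, neg)),
)
log_air = ac.log_transform(ac.normalize_counts(cleaned.subset_samples(air)))

alpha = ac.alpha_diversity(cleaned.subset_samples(air), meta, group_by="city")
print("Shannon diversity per city (groups sharing a letter are not")
print("significantly different, Tukey HSD at 0.05):")
for city, mean in alpha.group_means.sort_values(ascending=False).items():
    print(f"  {city:<12} H = {mean:.2f} nats   letter(s): {alpha.letters[city]}")

scores, varexp = ac.pca_scores(log_air, k=10)
print(f"top-10 PCs explain {varexp.sum():.1%} of variance")
model = ac.manova_forward_select(scores, meta.loc[air])
print(f"MANOVA forward selection included: {model.included}")
for step in model.steps:
    print(f"  {step.name}: Pillai V={step.pillai:.3f}, F={step.f_value:.1f}, "
          f"p={step.p_value:.1e}")

embedding = ac.umap_embed(log_air, seed=42)
purity = ac.knn_city_purity(embedding.coordinates, meta.loc[air, "city"])
print(f"UMAP 15-NN city purity: {purity:.3f}")
print("-> city is the dominant factor; covariates uncorrelated with the")
print("   planted structure do not enter the model.")
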