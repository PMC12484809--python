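# dietrhythm

Analysis pipeline for temporal nutrition and gut-microbiome data: diet
quality scoring (a standard density-based index plus a day-wise variant),
dietary-regularity metrics (day-to-day coefficient of variation),
microbiome diversity (alpha metrics, unweighted UniFrac, PCoA),
reference-frame log ratios of differentially associated taxa,
covariate-adjusted association testing with FDR control, stool-quality
features, and a bidirectional boosted-tree prediction harness.  A seeded
synthetic-cohort generator with planted diet-microbiome effects makes the
whole pipeline exercisable end-to-end without any external data.

## Modules

| module | what it does |
|---|---|
| `dietrhythm.synth` | seeded synthetic cohorts (food log, taxa counts, tree, metadata, stool) with planted, parameterized effects |
| `dietrhythm.foodlog` | food-log parsing/validation, per-day aggregation, energy/tracking-day QC filter |
| `dietrhythm.dietmetrics` | component-based diet-quality scoring (shipped HEI-2020 config), day-wise score, CV, diet diversity (DDS/Shannon/Gini-Simpson) |
| `dietrhythm.micro` | rarefaction, prevalence filter, CLR, Shannon/Pielou/observed/Faith PD, unweighted UniFrac, PCoA |
| `dietrhythm.diffratio` | per-taxon effect estimation (CLR-OLS + bootstrap intervals), credible-taxon reference frames, log10 ratios |
| `dietrhythm.assoc` | partial Spearman + Benjamini-Hochberg FDR, OLS diversity regressions, variance partitioning, Cohen's d/f |
| `dietrhythm.stool` | stool-report proportions, top-k user classification, stool-diet associations |
| `dietrhythm.mlharness` | extreme-quartile classification / full-range regression over repeated 80:20 splits with gain importances |

## CLI

```sh
# generate a synthetic cohort (TSVs + Newick tree) with planted effects
dietrhythm simulate --config cfg.yaml --out cohort/ --seed 1

# per-participant diet profile (HEI, daily HEI, CVs, diversity indices)
dietrhythm score-diet --log cohort/food_log.tsv --out profile.tsv

# alpha diversity and unweighted UniFrac + PCoA
dietrhythm alpha --table cohort/feature_table.tsv --tree cohort/tree.nwk --out alpha.tsv
dietrhythm beta  --table cohort/feature_table.tsv --tree cohort/tree.nwk \
    --out dist.tsv --pcoa-out pcoa.tsv

# differential taxa + log ratio against a metadata variable
dietrhythm logratio --table cohort/feature_table.tsv --metadata profile.tsv \
    --variable hei_daily --out-prefix hei

# covariate-adjusted associations with FDR
dietrhythm associate --frame frame.tsv --features hei,hei_daily \
    --targets shannon --covariates age,bmi --fdr-q 0.1 --out assoc.tsv

# boosted-tree prediction harness
dietrhythm predict --frame frame.tsv --direction diet2alpha --out pred.json
```

`simulate --config` takes YAML overrides of `SynthConfig` fields
(`n_participants`, `n_days`, `effect_hei_diversity`, `effect_cv_diversity`,
`stool_coupling`, ...).

## Notes

* Shannon diversity is reported in bits (log2), with the base switchable.
* The shipped HEI-2020 component YAML (`dietrhythm/data/hei2020.yaml`)
  transcribes the published density cut-points but converts grams to cup/oz
  equivalents with generic factors - override the config when a real
  food-group mapping is available.  The scoring engine itself is
  standard-agnostic (alternate indices can be supplied as YAML).
* Per-taxon effects use CLR-OLS slopes with bootstrap percentile intervals;
  externally computed effect tables (e.g. from a Bayesian negative-binomial
  model) can be ingested via `diffratio.read_effects` /
  `dietrhythm logratio --effects-table`.
* The boosted-tree learner is scikit-learn's gradient boosting; the
  configured L1 leaf penalty is accepted for compatibility but has no
  scikit-learn equivalent and is ignored.
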