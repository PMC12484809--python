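# HEI-2020 component standards (13 components, 100 points total).
#
# Density cut-points transcribe the published HEI-2020 scoring standards
# (adequacy components scored on cup/oz equivalents per 1000 kcal or a
# fat-quality ratio; moderation components on equivalents per 1000 kcal or
# percent of energy).
#
# APPROXIMATION NOTICE: logs record food groups in grams, not USDA cup/oz
# equivalents.  `grams_per_unit` converts summed grams of the numerator
# columns into one equivalent; the factors below are generic defaults
# (1 cup vegetables/fruit ~ 150 g, 1 cup dairy ~ 245 g, 1 oz-eq grain or
# protein ~ 28 g) and should be overridden when a real mapping is known.
# `whole_fruits` reuses the fruit column with a doubled grams_per_unit,
# i.e. it assumes half of logged fruit qualifies as whole fruit.
version: hei-2020/grams-approx-1
components:
  - name: total_vegetables
    direction: adequacy
    max_points: 5
    basis: per_1000kcal
    numerator: [vegetables, greens_beans]
    grams_per_unit: 150.0
    full_score_at: 1.1
    zero_score_at: 0.0
  - name: greens_and_beans
    direction: adequacy
    max_points: 5
    basis: per_1000kcal
    numerator: [greens_beans]
    grams_per_unit: 150.0
    full_score_at: 0.2
    zero_score_at: 0.0
  - name: total_fruits
    direction: adequacy
    max_points: 5
    basis: per_1000kcal
    numerator: [fruits]
    grams_per_unit: 150.0
    full_score_at: 0.8
    zero_score_at: 0.0
  - name: whole_fruits
    direction: adequacy
    max_points: 5
    basis: per_1000kcal
    numerator: [fruits]
    grams_per_unit: 300.0
    full_score_at: 0.4
    zero_score_at: 0.0
  - name: whole_grains
    direction: adequacy
    max_points: 10
    basis: per_1000kcal
    numerator: [whole_grains]
    grams_per_unit: 28.0
    full_score_at: 1.5
    zero_score_at: 0.0
  - name: dairy
    direction: adequacy
    max_points: 10
    basis: per_1000kcal
    numerator: [dairy]
    grams_per_unit: 245.0
    full_score_at: 1.3
    zero_score_at: 0.0
  - name: total_protein_foods
    direction: adequacy
    max_points: 5
    basis: per_1000kcal
    numerator: [meat, seafood_plant_proteins]
    grams_per_unit: 28.0
    full_score_at: 2.5
    zero_score_at: 0.0
  - name: seafood_and_plant_proteins
    direction: adequacy
    max_points: 5
    basis: per_1000kcal
    numerator: [seafood_plant_proteins, oils_nuts]
    grams_per_unit: 28.0
    full_score_at: 0.8
    zero_score_at: 0.0
  - name: fatty_acids
    direction: adequacy
    max_points: 10
    basis: ratio
    numerator: [mufa, pufa]
    denominator: [sfa]
    full_score_at: 2.5
    zero_score_at: 1.2
  - name: refined_grains
    direction: moderation
    max_points: 10
    basis: per_1000kcal
    numerator: [refined_grains]
    grams_per_unit: 28.0
    full_score_at: 1.8
    zero_score_at: 4.3
  - name: sodium
    direction: moderation
    max_points: 10
    basis: per_1000kcal
    numerator: [sodium]
    grams_per_unit: 1.0
    full_score_at: 1.1
    zero_score_at: 2.0
  - name: added_sugars
    direction: moderation
    max_points: 10
    basis: percent_energy
    numerator: [added_sugar]
    energy_per_gram: 4.0
    full_score_at: 6.5
    zero_score_at: 26.0
  - name: saturated_fats
    direction: moderation
    max_points: 10
    basis: percent_energy
    numerator: [sfa]
    energy_per_gram: 9.0
    full_score_at: 8.0
    zero_score_at: 16.0
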