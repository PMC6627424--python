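# IBRI breakfast nutrient guidelines.
#
# basis: absolute      -> bound on the nutrient amount at breakfast
#        percent_energy -> bound on the percent of breakfast energy the
#                          nutrient contributes (Atwater 4/4/9 kcal per g)
# bound: min | max | range (range carries [low, high])
# population: children | adults | both.  Where the source prints a paired
# value "(>a,>b)", the first applies to children and the second to adults.
label: IBRI-breakfast
guidelines:
  - {nutrient: energy_kcal, basis: absolute, bound: range, values: [300.0, 500.0], population: both}
  - {nutrient: added_sugar_g, basis: percent_energy, bound: max, values: [10.0], population: both}
  - {nutrient: carbohydrate_g, basis: percent_energy, bound: range, values: [55.0, 75.0], population: both}
  - {nutrient: fat_g, basis: percent_energy, bound: range, values: [20.0, 30.0], population: both}
  - {nutrient: sfa_g, basis: percent_energy, bound: max, values: [10.0], population: both}
  - {nutrient: protein_g, basis: absolute, bound: min, values: [10.0], population: both}
  - {nutrient: fiber_g, basis: absolute, bound: min, values: [5.6], population: both}
  - {nutrient: sodium_mg, basis: absolute, bound: max, values: [460.0], population: both}
  - {nutrient: vitamin_a_ug, basis: absolute, bound: min, values: [90.0], population: both}
  - {nutrient: thiamin_mg, basis: absolute, bound: min, values: [0.3], population: children}
  - {nutrient: thiamin_mg, basis: absolute, bound: min, values: [0.2], population: adults}
  - {nutrient: riboflavin_mg, basis: absolute, bound: min, values: [0.5], population: children}
  - {nutrient: riboflavin_mg, basis: absolute, bound: min, values: [0.4], population: adults}
  - {nutrient: niacin_mg, basis: absolute, bound: min, values: [4.0], population: both}
  - {nutrient: vitamin_b6_mg, basis: absolute, bound: min, values: [0.3], population: both}
  - {nutrient: vitamin_b12_ug, basis: absolute, bound: min, values: [0.6], population: children}
  - {nutrient: vitamin_b12_ug, basis: absolute, bound: min, values: [0.5], population: adults}
  - {nutrient: vitamin_c_mg, basis: absolute, bound: min, values: [18.0], population: both}
  - {nutrient: vitamin_d_ug, basis: absolute, bound: min, values: [4.0], population: both}
  - {nutrient: folate_ug, basis: absolute, bound: min, values: [80.0], population: both}
  - {nutrient: calcium_mg, basis: absolute, bound: min, values: [390.0], population: children}
  - {nutrient: calcium_mg, basis: absolute, bound: min, values: [325.0], population: adults}
  - {nutrient: iron_mg, basis: absolute, bound: min, values: [3.6], population: both}
  - {nutrient: potassium_mg, basis: absolute, bound: min, values: [940.0], population: both}
  - {nutrient: magnesium_mg, basis: absolute, bound: min, values: [84.0], population: both}
  - {nutrient: zinc_mg, basis: absolute, bound: min, values: [2.2], population: both}
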