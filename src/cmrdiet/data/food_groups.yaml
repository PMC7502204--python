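# Canonical 26 food groups for 24-h recall aggregation, with a compact
# item -> group mapping used by the synthetic cohort generator and tests.
# Group order is frozen: downstream feature matrices index columns by it.
groups:
  - rice
  - wheat
  - refined_grains
  - other_cereals
  - fried_foods
  - nuts_legumes
  - roots_tubers
  - deep_color_vegetables
  - light_color_vegetables
  - fungi_algae
  - pickled_vegetables
  - fruits
  - pork
  - poultry
  - red_meat_other_than_pork
  - animal_offal
  - processed_meat
  - seafood
  - eggs
  - milk
  - yogurt
  - dairy_products
  - sauces
  - ssb
  - candy_sugar
  - dessert
items:
  boiled rice: rice
  steamed bun: wheat
  noodles: wheat
  white bread: refined_grains
  pancake: refined_grains
  corn: other_cereals
  millet porridge: other_cereals
  fried dough stick: fried_foods
  fried rice cake: fried_foods
  peanuts: nuts_legumes
  tofu: nuts_legumes
  potato: roots_tubers
  sweet potato: roots_tubers
  carrot: deep_color_vegetables
  spinach: deep_color_vegetables
  cucumber: light_color_vegetables
  cabbage: light_color_vegetables
  mushroom: fungi_algae
  kelp: fungi_algae
  pickled radish: pickled_vegetables
  apple: fruits
  banana: fruits
  pork belly: pork
  chicken: poultry
  beef: red_meat_other_than_pork
  lamb: red_meat_other_than_pork
  pork liver: animal_offal
  ham: processed_meat
  fish: seafood
  shrimp: seafood
  boiled egg: eggs
  milk: milk
  yogurt: yogurt
  cheese: dairy_products
  soy sauce: sauces
  cola: ssb
  sweet tea drink: ssb
  candy: candy_sugar
  cake: dessert
# Approximate energy densities (kcal/g) per group; used only by the
# synthetic generator to apportion daily energy across recall records.
energy_density:
  rice: 1.2
  wheat: 2.2
  refined_grains: 2.8
  other_cereals: 1.0
  fried_foods: 4.0
  nuts_legumes: 3.0
  roots_tubers: 0.9
  deep_color_vegetables: 0.3
  light_color_vegetables: 0.2
  fungi_algae: 0.3
  pickled_vegetables: 0.3
  fruits: 0.5
  pork: 3.0
  poultry: 1.7
  red_meat_other_than_pork: 1.9
  animal_offal: 1.3
  processed_meat: 2.5
  seafood: 1.1
  eggs: 1.4
  milk: 0.6
  yogurt: 0.7
  dairy_products: 3.5
  sauces: 1.0
  ssb: 0.4
  candy_sugar: 3.9
  dessert: 3.5
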