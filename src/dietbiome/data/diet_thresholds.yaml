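# Component scoring anchors for the HEI-MON and PHEI-MON diet-quality
# indices, and component -> food-group mappings for aMED.
#
# The numeric anchors below are EDITABLE PLACEHOLDER DEFAULTS chosen for
# plausibility against German food-based dietary guidelines / the
# planetary-health diet; the authoritative anchor values live in the
# indices' original scoring publications and can be dropped in here
# without any code change. Units: g/day per 1000 kcal where
# `per_1000_kcal: true`, else raw g/day.
#
# direction:
#   adequacy   - 0 at/below `zero`, 100 at/above `full`, linear between
#   moderation - 100 at/below `full`, 0 at/above `zero`, linear between
#   optimum    - 100 inside [opt_low, opt_high], linear to 0 at
#                zero_low / zero_high

hei_mon:
  per_1000_kcal: true
  components:
    cereals:
      groups: [cereals]
      direction: optimum
      zero_low: 15.0
      opt_low: 60.0
      opt_high: 100.0
      zero_high: 200.0
    side_dishes:
      groups: [side_dishes]
      direction: optimum
      zero_low: 5.0
      opt_low: 40.0
      opt_high: 90.0
      zero_high: 200.0
    vegetables_legumes:
      groups: [vegetables, legumes]
      direction: adequacy
      zero: 0.0
      full: 130.0
    fruits_nuts:
      groups: [fruits, nuts]
      direction: adequacy
      zero: 0.0
      full: 120.0
    dairy:
      groups: [dairy]
      direction: optimum
      zero_low: 0.0
      opt_low: 80.0
      opt_high: 130.0
      zero_high: 300.0
    cheese:
      groups: [cheese]
      direction: optimum
      zero_low: 0.0
      opt_low: 10.0
      opt_high: 30.0
      zero_high: 90.0
    meat_processed_meat:
      groups: [red_processed_meat]
      direction: moderation
      full: 15.0
      zero: 80.0
    eggs:
      groups: [eggs]
      direction: optimum
      zero_low: 0.0
      opt_low: 5.0
      opt_high: 20.0
      zero_high: 60.0
    fish:
      groups: [fish]
      direction: adequacy
      zero: 0.0
      full: 20.0
    free_sugars:
      groups: [free_sugars]
      direction: moderation
      full: 10.0
      zero: 50.0

phei_mon:
  per_1000_kcal: true
  components:
    whole_grains:
      groups: [whole_grains]
      direction: adequacy
      zero: 0.0
      full: 60.0
    potatoes:
      groups: [potatoes]
      direction: moderation
      full: 20.0
      zero: 80.0
    vegetables:
      groups: [vegetables]
      direction: adequacy
      zero: 0.0
      full: 120.0
    fruits:
      groups: [fruits]
      direction: adequacy
      zero: 0.0
      full: 100.0
    legumes:
      groups: [legumes]
      direction: adequacy
      zero: 0.0
      full: 30.0
    nuts:
      groups: [nuts]
      direction: adequacy
      zero: 0.0
      full: 20.0
    dairy:
      groups: [dairy]
      direction: moderation
      full: 110.0
      zero: 300.0
    red_processed_meat:
      groups: [red_processed_meat]
      direction: moderation
      full: 7.0
      zero: 50.0
    poultry:
      groups: [poultry]
      direction: moderation
      full: 15.0
      zero: 60.0
    eggs:
      groups: [eggs]
      direction: moderation
      full: 7.0
      zero: 40.0
    fish:
      groups: [fish]
      direction: optimum
      zero_low: 0.0
      opt_low: 10.0
      opt_high: 40.0
      zero_high: 150.0
    added_sugars:
      groups: [free_sugars]
      direction: moderation
      full: 15.0
      zero: 60.0
    vegetable_oils:
      groups: [vegetable_oils]
      direction: optimum
      zero_low: 0.0
      opt_low: 10.0
      opt_high: 30.0
      zero_high: 90.0
    sweetened_beverages:
      groups: [sweetened_beverages]
      direction: moderation
      full: 0.0
      zero: 120.0

amed:
  # median-based components (raw g/day; no energy standardization)
  adequacy_components:
    vegetables: [vegetables]
    legumes: [legumes]
    fruits: [fruits]
    nuts: [nuts]
    whole_grains: [whole_grains]
    fish: [fish]
  meat_component:
    red_processed_meat: [red_processed_meat]
  alcohol_cutoffs_g_day:
    F: 10.0
    M: 25.0
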