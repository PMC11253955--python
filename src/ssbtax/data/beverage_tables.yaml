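# Serving-size and caloric-density tables for the four beverage categories.
#
# The 24-h recall reports beverages in standard servings; servings are
# converted to ml and ml to kcal with the densities below.  Individual item
# tables are not public, so these are calibration choices: the SSB density of
# 0.40 kcal/ml reproduces the national mean of ~72 kcal/day from ~180 ml/day
# and is typical of full-sugar sodas (~40 kcal per 100 ml).  Edit freely.

serving_ml:
  ssb: 350.0          # one can/cup of soda or sweetened drink
  unsweetened: 200.0  # glass of milk, water, 100% juice
  alcoholic: 350.0    # bottle/can of beer (dominant item)
  diet: 350.0

kcal_per_ml:
  ssb: 0.40
  unsweetened: 0.30   # milk/juice average; water contributes 0
  alcoholic: 0.43     # beer-weighted average
  diet: 0.02          # low-calorie / artificially sweetened
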