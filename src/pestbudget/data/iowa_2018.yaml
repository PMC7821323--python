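# 2018 Iowa soybean-aphid case study: yields, prices, probabilities and the
# itemized cost ledger (all monetary amounts in 2018 USD per hectare, yields
# in kg per hectare, crop price in USD per kg).
schema: pestbudget-config/1

metadata:
  name: iowa_2018
  currency: USD 2018
  crop: soybean
  pest: soybean aphid (Aphis glycines)
  yield_units: kg/ha

yield:
  # Ten-year (2009-2018) Iowa state average soybean yield.
  attainable: 3537.0
  # Fraction of attainable yield retained when an outbreak goes unmanaged or
  # management fails: susceptible varieties lose 12.7%, aphid-resistant
  # (Rag-gene) varieties lose nothing.
  retained_fraction:
    S: 0.873
    R: 1.0

price:
  # 2018 calendar-year Iowa market price of soybean.
  crop_price: 0.33

probabilities:
  # Outbreak probability for a high-risk Iowa location (share of 23
  # insecticide-trial site-years where aphids exceeded the economic
  # threshold before growth stage R6).
  outbreak: 0.435
  # Population mix conditional on an outbreak. The default point is pure
  # wild type; resistance sweeps move mass onto the resistant class.
  population:
    wild: 1.0
    resistant: 0.0
    cross_resistant: 0.0
  # Insecticide mode-of-action groups each population class survives.
  # 3A = pyrethroids, 1B = organophosphates, 4C = sulfoxaflor.
  resistance_profiles:
    wild: []
    resistant: ["3A"]
    cross_resistant: ["3A", "1B"]

costs:
  # Production steps identical across scenarios (USD/ha). Early-season
  # scouting is the mandatory two visits priced at 10.50 each.
  fixed:
    - {name: tillage, amount: 39.70}
    - {name: herbicide_application, amount: 43.61}
    - {name: planting, amount: 73.39}
    - {name: early_season_scouting, amount: 21.00}
    - {name: harvest, amount: 120.83}
    - {name: land_rent, amount: 548.56}
  # Seed cost by "<aphid trait>.<herbicide trait>" (USD/ha at 345,940
  # seeds/ha). R.C is the aphid-resistant all-varieties mean.
  seed:
    S.H: 155.13
    S.C: 117.65
    R.C: 111.56
  # Herbicide product cost by the variety's herbicide trait.
  herbicide:
    H: 89.70
    C: 118.61
  # Insecticide product cost per application by mode-of-action group;
  # "generic" is the mean across all surveyed products.
  insecticide:
    generic: 22.88
    "3A": 13.83
    "1B": 21.98
    "4C": 61.78
  application: 20.02        # USD per insecticide application
  scouting_activity: 10.50  # USD per scouting visit
  scouting_counts:
    early: 2
    monitoring: 6

spray:
  # First-choice product: wild-type scenarios are costed at the generic
  # all-products mean; resistant-pest scenarios start with the cheapest
  # class, a pyrethroid (3A).
  first_group_by_pest:
    W: generic
    I: "3A"
  # Rescue after a failed first application: organophosphate (1B).
  rescue_group: "1B"

availability:
  # Seed trait combinations on the 2018 market: aphid resistance is only
  # sold in conventional (non herbicide-tolerant) backgrounds.
  varieties: ["S.H", "S.C", "R.C"]

grammar:
  allow_standalone_monitoring: false

grid:
  step: 0.1

sensitivity_presets:
  yield_low: {attainable_yield: 3026.0}
  yield_high: {attainable_yield: 4035.0}
  price_avg: {crop_price: 0.40}
  price_high: {crop_price: 0.52}
  tech_fee: {technology_fee: true}
  input_scale_88: {input_cost_scale: 0.88}
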