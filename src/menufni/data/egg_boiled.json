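{
  "label": "Egg, boiled (hard or soft)",
  "source_code": "NDSR 975",
  "grams": 44.0,
  "note": "Per-100 g densities are generic whole-boiled-egg composition reference values (USDA-style), not values published with any specific menu analysis; supply your own profile for exact replication work.",
  "density_per_100g": {
    "choline": 293.8,
    "potassium": 126.0,
    "calcium": 50.0,
    "folate": 44.0,
    "magnesium": 10.0,
    "zinc": 1.05,
    "vitamin_d": 2.175,
    "vitamin_c": 0.0,
    "energy": 155.0,
    "protein": 12.58
  }
}
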