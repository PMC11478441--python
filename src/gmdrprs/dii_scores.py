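"""Default inflammatory-effect score table for the simplified dietary
inflammatory index (DII).

The simplified DII used here is
``DII = sum_c(score_c * intake_c) / 100`` over 38 food and nutrient
components (the four spice components garlic, ginger, saffron and turmeric
are excluded for lack of intake data).  The effect scores below follow the
widely used literature-derived convention (positive = pro-inflammatory,
negative = anti-inflammatory) and ship as a sensible default; studies with
their own calibrated score table should pass it explicitly to
:func:`gmdrprs.gxe.compute_dii`.

``TYPICAL_DAILY_INTAKE`` holds rough adult daily-intake means (component
units per day) used by the synthetic cohort generator to draw plausible
intake distributions; they are illustrative scale parameters, not survey
estimates.
"""

# component -> inflammatory effect score (dimensionless)
DEFAULT_DII_SCORES: dict[str, float] = {
    "energy": 0.180,
    "protein": 0.021,
    "carbohydrate": 0.097,
    "total_fat": 0.298,
    "saturated_fat": 0.429,
    "mufa": -0.009,
    "pufa": -0.337,
    "omega3": -0.436,
    "omega6": -0.159,
    "trans_fat": 0.229,
    "cholesterol": 0.110,
    "fiber": -0.663,
    "alcohol": -0.278,
    "vitamin_a": -0.401,
    "beta_carotene": -0.584,
    "thiamin": -0.098,
    "riboflavin": -0.068,
    "niacin": -0.246,
    "vitamin_b6": -0.365,
    "folate": -0.190,
    "vitamin_b12": 0.106,
    "vitamin_c": -0.424,
    "vitamin_d": -0.446,
    "vitamin_e": -0.419,
    "iron": 0.032,
    "magnesium": -0.484,
    "selenium": -0.191,
    "zinc": -0.313,
    "caffeine": -0.110,
    "green_black_tea": -0.536,
    "flavan3ol": -0.415,
    "flavones": -0.616,
    "flavonols": -0.467,
    "flavanones": -0.250,
    "anthocyanidins": -0.131,
    "isoflavones": -0.593,
    "pepper": -0.131,
    "onion": -0.301,
}

assert len(DEFAULT_DII_SCORES) == 38

# component -> typical adult daily intake (component-specific units/day),
# used only as gamma-distribution means by the synthetic generator
TYPICAL_DAILY_INTAKE: dict[str, float] = {
    "energy": 2000.0,       # kcal
    "protein": 70.0,        # g
    "carbohydrate": 300.0,  # g
    "total_fat": 50.0,      # g
    "saturated_fat": 15.0,
    "mufa": 18.0,
    "pufa": 12.0,
    "omega3": 1.5,
    "omega6": 10.0,
    "trans_fat": 1.0,
    "cholesterol": 250.0,   # mg
    "fiber": 20.0,          # g
    "alcohol": 8.0,         # g
    "vitamin_a": 700.0,     # ug RE
    "beta_carotene": 3000.0,  # ug
    "thiamin": 1.2,         # mg
    "riboflavin": 1.3,
    "niacin": 15.0,
    "vitamin_b6": 1.5,
    "folate": 350.0,        # ug
    "vitamin_b12": 4.0,     # ug
    "vitamin_c": 90.0,      # mg
    "vitamin_d": 5.0,       # ug
    "vitamin_e": 8.0,       # mg
    "iron": 12.0,           # mg
    "magnesium": 300.0,     # mg
    "selenium": 55.0,       # ug
    "zinc": 10.0,           # mg
    "caffeine": 120.0,      # mg
    "green_black_tea": 200.0,  # g brewed
    "flavan3ol": 100.0,     # mg
    "flavones": 2.0,
    "flavonols": 20.0,
    "flavanones": 25.0,
    "anthocyanidins": 15.0,
    "isoflavones": 20.0,
    "pepper": 2.0,          # g
    "onion": 30.0,          # g
}
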