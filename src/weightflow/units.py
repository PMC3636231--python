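"""Unit constants and body-size formulas.

All weights are stored in pounds internally; kilograms appear only in
derived outcomes and reports.
"""

KG_PER_LB = 0.45359237
LB_PER_KG = 1.0 / KG_PER_LB

#: Factor in the imperial BMI formula: BMI = 703 * weight(lb) / height(in)^2
BMI_IMPERIAL_FACTOR = 703.0


def lb_to_kg(lb):
    return lb * KG_PER_LB


def kg_to_lb(kg):
    return kg * LB_PER_KG


def bmi_imperial(weight_lb, height_in):
    """Body-mass index from pounds and inches."""
    return BMI_IMPERIAL_FACTOR * weight_lb / (height_in ** 2)
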