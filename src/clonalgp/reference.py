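"""Published estimates from a large Australian sugarcane breeding-program study.

These are the printed second-stage results of a genomic analysis of ~2,900
genotyped elite cane clones (traits: tonnes cane per hectare TCH, commercial
cane sugar CCS, and Fibre content) under two forward-prediction training
populations: scenario "1" (2013-2015 series, 1,825 clones) and scenario "2"
(2013-2016 series, 2,397 clones).  The raw breeding data are proprietary, so
the package uses these printed variance components, log-likelihoods and
accuracies as inputs for worked examples: derived quantities (variance
shares, heritabilities, likelihood-ratio statistics, relative accuracy
improvements) are recomputed from them with the package's own functions.

Keys are (scenario, trait, model); values are printed point estimates.
``None`` marks components the model does not fit; 0.0 marks components the
original analysis pinned at the boundary ("~0").
"""

from __future__ import annotations

MODELS = ("A", "AH", "AD", "ADH", "ADE", "ADEH")

#: (scenario, trait, model) -> {var_a, var_d, var_aa, var_resid, het, loglik}
VARIANCE_COMPONENTS: dict[tuple[str, str, str], dict[str, float | None]] = {
    # scenario 1 (training 2013-2015)
    ("1", "TCH", "A"):    dict(var_a=98.13, var_d=None, var_aa=None, var_resid=36.09, het=None,   loglik=-45439.59),
    ("1", "TCH", "AH"):   dict(var_a=95.78, var_d=None, var_aa=None, var_resid=36.09, het=125.72, loglik=-45416.81),
    ("1", "TCH", "AD"):   dict(var_a=49.91, var_d=35.84, var_aa=None, var_resid=36.08, het=None,   loglik=-45403.70),
    ("1", "TCH", "ADH"):  dict(var_a=53.41, var_d=31.70, var_aa=None, var_resid=36.08, het=133.89, loglik=-45390.63),
    ("1", "TCH", "ADE"):  dict(var_a=21.91, var_d=9.71, var_aa=44.33, var_resid=36.06, het=None,   loglik=-45373.39),
    ("1", "TCH", "ADEH"): dict(var_a=23.00, var_d=3.13, var_aa=48.45, var_resid=36.06, het=118.83, loglik=-45355.42),
    ("1", "CCS", "A"):    dict(var_a=0.41, var_d=None, var_aa=None, var_resid=0.134, het=None,  loglik=6586.014),
    ("1", "CCS", "AH"):   dict(var_a=0.41, var_d=None, var_aa=None, var_resid=0.134, het=0.093, loglik=6586.277),
    ("1", "CCS", "AD"):   dict(var_a=0.40, var_d=0.006, var_aa=None, var_resid=0.134, het=None,  loglik=6586.060),
    ("1", "CCS", "ADH"):  dict(var_a=0.40, var_d=0.008, var_aa=None, var_resid=0.134, het=0.142, loglik=6586.363),
    ("1", "CCS", "ADE"):  dict(var_a=0.256, var_d=0.0, var_aa=0.110, var_resid=0.134, het=None,  loglik=6596.317),
    ("1", "CCS", "ADEH"): dict(var_a=0.256, var_d=0.0, var_aa=0.11, var_resid=0.134, het=0.204, loglik=6596.591),
    ("1", "Fibre", "A"):    dict(var_a=1.54, var_d=None, var_aa=None, var_resid=0.16, het=None,  loglik=4118.252),
    ("1", "Fibre", "AH"):   dict(var_a=1.54, var_d=None, var_aa=None, var_resid=0.16, het=1.29,  loglik=4119.29),
    ("1", "Fibre", "AD"):   dict(var_a=1.43, var_d=0.08, var_aa=None, var_resid=0.16, het=None,  loglik=4119.76),
    ("1", "Fibre", "ADH"):  dict(var_a=1.43, var_d=0.08, var_aa=None, var_resid=0.16, het=0.921, loglik=4120.84),
    ("1", "Fibre", "ADE"):  dict(var_a=1.14, var_d=0.01, var_aa=0.28, var_resid=0.16, het=None,  loglik=4123.30),
    ("1", "Fibre", "ADEH"): dict(var_a=1.14, var_d=0.01, var_aa=0.27, var_resid=0.16, het=0.841, loglik=4124.28),
    # scenario 2 (training 2013-2016)
    ("2", "TCH", "A"):    dict(var_a=85.99, var_d=None, var_aa=None, var_resid=37.39, het=None,   loglik=-66907.76),
    ("2", "TCH", "AH"):   dict(var_a=83.26, var_d=None, var_aa=None, var_resid=37.39, het=139.70, loglik=-66870.77),
    ("2", "TCH", "AD"):   dict(var_a=48.84, var_d=29.59, var_aa=None, var_resid=37.38, het=None,   loglik=-66872.13),
    ("2", "TCH", "ADH"):  dict(var_a=53.52, var_d=23.87, var_aa=None, var_resid=37.38, het=157.38, loglik=-66850.68),
    ("2", "TCH", "ADE"):  dict(var_a=22.82, var_d=11.09, var_aa=38.89, var_resid=37.37, het=None,   loglik=-66845.05),
    ("2", "TCH", "ADEH"): dict(var_a=23.30, var_d=1.24, var_aa=46.47, var_resid=37.37, het=140.57, loglik=-66813.82),
    ("2", "CCS", "A"):    dict(var_a=0.367, var_d=None, var_aa=None, var_resid=0.125, het=None,   loglik=10890.366),
    ("2", "CCS", "AH"):   dict(var_a=0.367, var_d=None, var_aa=None, var_resid=0.125, het=-0.801, loglik=10890.728),
    ("2", "CCS", "AD"):   dict(var_a=0.338, var_d=0.021, var_aa=None, var_resid=0.125, het=None,   loglik=10891.675),
    ("2", "CCS", "ADH"):  dict(var_a=0.338, var_d=0.022, var_aa=None, var_resid=0.125, het=-0.764, loglik=10892.093),
    ("2", "CCS", "ADE"):  dict(var_a=0.228, var_d=0.0, var_aa=0.110, var_resid=0.125, het=None,   loglik=10903.98),
    ("2", "CCS", "ADEH"): dict(var_a=0.228, var_d=0.0, var_aa=0.109, var_resid=0.125, het=-0.811, loglik=10904.35),
    ("2", "Fibre", "A"):    dict(var_a=1.38, var_d=None, var_aa=None, var_resid=0.16, het=None,  loglik=6449.904),
    ("2", "Fibre", "AH"):   dict(var_a=1.38, var_d=None, var_aa=None, var_resid=0.16, het=0.562, loglik=6450.688),
    ("2", "Fibre", "AD"):   dict(var_a=1.31, var_d=0.05, var_aa=None, var_resid=0.16, het=None,  loglik=6450.904),
    ("2", "Fibre", "ADH"):  dict(var_a=1.31, var_d=0.06, var_aa=None, var_resid=0.16, het=0.445, loglik=6451.769),
    ("2", "Fibre", "ADE"):  dict(var_a=1.13, var_d=0.02, var_aa=0.18, var_resid=0.16, het=None,  loglik=6452.861),
    ("2", "Fibre", "ADEH"): dict(var_a=1.13, var_d=0.02, var_aa=0.18, var_resid=0.16, het=0.263, loglik=6453.659),
}

#: (scenario, trait) -> model -> region-averaged prediction accuracy
#: scenarios: "1a" predict 2016, "1b" predict 2017 (both trained 2013-2015),
#: "2" predict 2017 trained 2013-2016
ACCURACIES: dict[tuple[str, str], dict[str, float]] = {
    ("1a", "TCH"):   dict(A=0.248, AH=0.291, AD=0.264, ADH=0.287, ADE=0.283, ADEH=0.325, RKHS=0.272),
    ("1a", "CCS"):   dict(A=0.405, AH=0.404, AD=0.406, ADH=0.406, ADE=0.409, ADEH=0.408, RKHS=0.390),
    ("1a", "Fibre"): dict(A=0.445, AH=0.446, AD=0.442, ADH=0.442, ADE=0.443, ADEH=0.444, RKHS=0.407),
    ("1b", "TCH"):   dict(A=0.218, AH=0.255, AD=0.235, ADH=0.258, ADE=0.257, ADEH=0.286, RKHS=0.246),
    ("1b", "CCS"):   dict(A=0.297, AH=0.297, AD=0.304, ADH=0.305, ADE=0.315, ADEH=0.315, RKHS=0.318),
    ("1b", "Fibre"): dict(A=0.396, AH=0.395, AD=0.390, ADH=0.390, ADE=0.394, ADEH=0.393, RKHS=0.389),
    ("2", "TCH"):    dict(A=0.247, AH=0.280, AD=0.262, ADH=0.280, ADE=0.270, ADEH=0.290, RKHS=0.247),
    ("2", "CCS"):    dict(A=0.348, AH=0.347, AD=0.353, ADH=0.352, ADE=0.354, ADEH=0.354, RKHS=0.348),
    ("2", "Fibre"):  dict(A=0.431, AH=0.431, AD=0.429, ADH=0.429, ADE=0.429, ADEH=0.428, RKHS=0.431),
}


def components(scenario: str, trait: str, model: str) -> dict[str, float]:
    """Fitted variance components of one published model, absent terms as 0."""
    row = VARIANCE_COMPONENTS[(scenario, trait, model)]
    return {
        "var_a": row["var_a"] or 0.0,
        "var_d": row["var_d"] or 0.0,
        "var_aa": row["var_aa"] or 0.0,
        "var_resid": row["var_resid"] or 0.0,
    }


def genetic_share(scenario: str, trait: str, model: str, component: str) -> float:
    """A component's share of the total genetic variance (fraction)."""
    c = components(scenario, trait, model)
    genetic = c["var_a"] + c["var_d"] + c["var_aa"]
    return c[component] / genetic


def phenotypic_share(scenario: str, trait: str, model: str, component: str) -> float:
    """A component's share of the phenotypic variance (fraction)."""
    c = components(scenario, trait, model)
    total = sum(c.values())
    return c[component] / total
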