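"""Printed study counts for the GST / CML case-control study.

These are the published marginal tables of the 104-case / 104-control
Iranian CML cohort (GSTM1 and GSTT1 whole-gene deletions, GSTP1
Ile105Val rs1695, smoking status, ELN treatment-response categories).
They drive the fixture generator and the built-in replication report.

Level coding used by the fixture solver: for each binary factor, level 1
is the "risk" level (GSTM1 null, GSTT1 null, GSTP1 variant carrier
AG/GG, smoker) and level 0 its complement.
"""

from __future__ import annotations

GROUPS = ("case", "control")

# Demographics.
DEMOGRAPHICS = {
    "n": {"case": 104, "control": 104},
    "sex": {
        "case": {"male": 55, "female": 49},
        "control": {"male": 57, "female": 47},
    },
    "age_mean_sd": {"case": (43.8, 15.1), "control": (44.99, 15.57)},
    "smoking": {
        "case": {"smoker": 57, "nonsmoker": 47},
        "control": {"smoker": 31, "nonsmoker": 73},
    },
}

# Single-locus genotype counts.
GENOTYPES = {
    "gstm1": {
        "case": {"present": 34, "null": 70},
        "control": {"present": 53, "null": 51},
    },
    "gstt1": {
        "case": {"present": 101, "null": 3},
        "control": {"present": 103, "null": 1},
    },
    "gstp1": {
        "case": {"AA": 54, "AG": 38, "GG": 12},
        "control": {"AA": 66, "AG": 33, "GG": 5},
    },
}

# Gene-gene joint counts, cells keyed (factor1_level, factor2_level) with
# level 1 = risk level (null / variant carrier).  factor order in the key
# name matches the pair name.
GENE_GENE = {
    "gstm1_gstt1": {
        "case": {(1, 1): 1, (1, 0): 69, (0, 1): 2, (0, 0): 32},
        "control": {(1, 1): 1, (1, 0): 50, (0, 1): 0, (0, 0): 53},
    },
    "gstm1_gstp1": {
        "case": {(1, 1): 43, (1, 0): 27, (0, 1): 7, (0, 0): 27},
        "control": {(1, 1): 19, (1, 0): 32, (0, 1): 19, (0, 0): 34},
    },
    "gstt1_gstp1": {
        "case": {(1, 1): 0, (1, 0): 3, (0, 1): 50, (0, 0): 51},
        "control": {(1, 1): 1, (1, 0): 0, (0, 1): 37, (0, 0): 66},
    },
}

# Gene-environment joint counts, (genotype_level, smoking_level).
GENE_SMOKING = {
    "gstm1_smoking": {
        "case": {(1, 1): 38, (1, 0): 32, (0, 1): 19, (0, 0): 15},
        "control": {(1, 1): 14, (1, 0): 37, (0, 1): 17, (0, 0): 36},
    },
    "gstt1_smoking": {
        "case": {(1, 1): 2, (1, 0): 1, (0, 1): 55, (0, 0): 46},
        "control": {(1, 1): 1, (1, 0): 0, (0, 1): 30, (0, 0): 73},
    },
    "gstp1_smoking": {
        "case": {(1, 1): 27, (1, 0): 23, (0, 1): 30, (0, 0): 24},
        "control": {(1, 1): 12, (1, 0): 26, (0, 1): 19, (0, 0): 47},
    },
}

# Treatment response among the 104 cases, (responders, non_responders)
# per genotype grouping.  The two blocks are NOT mutually consistent
# (their responder totals differ), so they cannot share one record set.
RESPONSE = {
    "table5_gstm1": {
        "grouping": ("gstm1", {"null": 70, "present": 34}),
        "mcyr_3m": {"null": (10, 60), "present": (14, 20)},
        "ccyr_6m": {"null": (17, 53), "present": (23, 11)},
        "bcrabl_3m": {"null": (2, 68), "present": (10, 24)},
        "bcrabl_6m": {"null": (6, 64), "present": (18, 16)},
    },
    "table5_gstp1": {
        "grouping": ("gstp1", {"AA": 54, "variant": 50}),
        "mcyr_3m": {"AA": (15, 39), "variant": (7, 43)},
        "ccyr_6m": {"AA": (25, 29), "variant": (13, 37)},
        "bcrabl_3m": {"AA": (20, 34), "variant": (10, 40)},
        "bcrabl_6m": {"AA": (25, 29), "variant": (11, 39)},
    },
}

# Published point estimates used by the side-by-side replication report.
PRINTED = {
    "gstm1_recessive_or": 0.46,
    "gstm1_recessive_ci": (0.26, 0.82),
    "gstm1_recessive_p": 0.008,
    "gstt1_recessive_or": 0.32,
    "gstt1_recessive_ci": (0.03, 3.19),
    "gstp1_recessive_or": 0.38,
    "gstp1_dominant_or": 0.62,
    "gstp1_additive_or": 1.569,
    "gstp1_additive_ci": (1.016, 2.423),
    "gstp1_allele_or": 0.61,
    "hwe_p": {"case": 0.19, "control": 0.73},
    "age_t_p": 0.57,
    "gene_gene": {
        "gstm1_gstt1": {"or11": 1.65, "or10": 2.28, "or01": None, "reri": 0.37},
        "gstm1_gstp1": {"or11": 2.85, "or10": 1.06, "or01": 0.46, "reri": 2.32},
        "gstt1_gstp1": {"or11": None, "or10": None, "or01": 1.75, "reri": -0.749},
    },
    "gene_smoking": {
        "gstm1_smoking": {
            "or11": 6.51, "or10": 2.07, "or01": 2.68,
            "reri": 2.756, "ap": 0.423, "si": 1.99,
        },
        "gstt1_smoking": {
            "or11": 3.17, "or10": None, "or01": 2.91,
            "reri": 1.26, "ap": 0.39, "si": 2.39,
        },
        "gstp1_smoking": {
            "or11": 4.40, "or10": 1.73, "or01": 3.09,
            "reri": 0.58, "ap": 0.13, "si": 1.20,
        },
    },
}
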