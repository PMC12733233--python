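"""Published summary data for the MMP / ACL-injury case-control study.

The underlying individual-level data (160 injured footballers, 136 uninjured
controls, three biallelic MMP polymorphisms) are not public; what is public
are the summary tables: genotype counts per phenotype stratum, unadjusted and
FDR-adjusted p-values, case-group genotype frequencies, and group demographics.
Those printed numbers are inputs to this package -- they seed the synthetic
cohort generator, drive the power analysis, and let the within-case odds
ratios and FDR columns be recomputed from scratch.

Genotype codes follow the 1/2/3 convention: 1 = homozygous major (reference)
allele, 2 = heterozygous, 3 = homozygous minor allele.  The minor allele is
the declared risk allele: I for rs1799750 (MMP1 promoter ins/del), T for
rs486055 (MMP10 coding), G for rs2276109 (MMP12 promoter).
"""

from __future__ import annotations

from .io import SNPDef

#: The three-SNP panel, major/minor per the study's coding (reference genotype
#: rows in the association tables are D/D, C/C and A/A respectively).
SNPS = (
    SNPDef("rs1799750", major_allele="D", minor_allele="I"),
    SNPDef("rs486055", major_allele="C", minor_allele="T"),
    SNPDef("rs2276109", major_allele="A", minor_allele="G"),
)

N_CASES = 160
N_CONTROLS = 136

#: Group demographics: mean (SD) of age [years] and body mass [kg].
DEMOGRAPHICS = {
    "age": {"controls": (27.0, 4.0), "cases": (36.0, 7.0)},
    "body_mass": {"controls": (73.0, 16.0), "cases": (78.0, 10.0)},
}

#: Case-group genotype counts (code 1, 2, 3) implied by the published
#: case-group genotype percentages; all three sit comfortably in HWE.
CASE_GENOTYPE_COUNTS = {
    "rs1799750": (48, 81, 30),
    "rs486055": (104, 50, 6),
    "rs2276109": (128, 28, 4),
}

#: Published case-group exact HWE p-values for the counts above.
CASE_HWE_P = {"rs1799750": 0.749, "rs486055": 1.00, "rs2276109": 0.115}

# ---------------------------------------------------------------------------
# Case-control genotype counts (code 1, 2, 3 per column).
#
# The published case-control tables carry a column-label inconsistency: the
# column headed "Cases" sums to 136 (the stated control-group size) and the
# column headed "Controls" sums to 158-159.  Group membership is therefore
# resolved by the column sums, not the headers; both interpretations are kept
# and the 136-sum column is treated as the control group by default.
# ---------------------------------------------------------------------------
CASE_CONTROL_COUNTS = {
    # column summing to 136 / column summing to ~158
    "rs1799750": {"sum136": (34, 57, 45), "sum158": (48, 80, 30)},
    "rs486055": {"sum136": (98, 35, 3), "sum158": (103, 50, 6)},
    "rs2276109": {"sum136": (106, 30, 0), "sum158": (128, 27, 4)},
}


def control_minor_allele_freq(snp_id: str, column: str = "sum136") -> float:
    """Frequency of the declared minor allele in the control-group column."""
    n1, n2, n3 = CASE_CONTROL_COUNTS[snp_id][column]
    n = n1 + n2 + n3
    return (2 * n3 + n2) / (2 * n)


def control_maf(snp_id: str, column: str = "sum136") -> float:
    """Folded control minor-allele frequency (always <= 0.5), for power work."""
    f = control_minor_allele_freq(snp_id, column)
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# Within-case association tables: genotype counts by sub-phenotype level.
#
# Keyed by SNP then outcome; each value is a pair of (code1, code2, code3)
# count triples for outcome level 0 and level 1.  ACLF level 1 = multiple
# injuries; ACLS/ACLRP/ACLRC level 1 = phenotype present.
# ---------------------------------------------------------------------------
WITHIN_CASE_COUNTS = {
    "rs1799750": {
        "ACLF": ((33, 58, 10), (15, 23, 20)),
        "ACLS": ((12, 13, 6), (36, 68, 24)),
        "ACLRP": ((28, 69, 23), (20, 12, 7)),
        "ACLRC": ((37, 73, 30), (11, 8, 0)),
    },
    "rs486055": {
        "ACLF": ((62, 35, 4), (42, 15, 2)),
        "ACLS": ((19, 11, 1), (85, 39, 5)),
        "ACLRP": ((86, 29, 5), (18, 21, 1)),
        "ACLRC": ((94, 42, 5), (10, 8, 1)),
    },
    "rs2276109": {
        "ACLF": ((89, 11, 1), (39, 17, 3)),
        "ACLS": ((27, 4, 0), (101, 24, 4)),
        "ACLRP": ((94, 23, 3), (34, 5, 1)),
        "ACLRC": ((111, 26, 4), (17, 2, 0)),
    },
}

#: Published within-case OR (95% CI) rows, for the non-reference contrast(s)
#: of each model, keyed (snp, outcome, model).  Codominant lists the
#: heterozygote then homozygote-minor contrast.  None = CI omitted (zero cell).
WITHIN_CASE_OR = {
    ("rs1799750", "ACLF", "codominant"): [(0.87, 0.40, 1.90), (4.40, 1.66, 11.65)],
    ("rs1799750", "ACLF", "dominant"): [(1.39, 0.68, 2.86)],
    ("rs1799750", "ACLF", "recessive"): [(4.79, 2.05, 11.19)],
    ("rs1799750", "ACLF", "overdominant"): [(0.49, 0.25, 0.94)],
    ("rs1799750", "ACLRP", "dominant"): [(0.29, 0.14, 0.62)],
    ("rs1799750", "ACLRP", "overdominant"): [(0.33, 0.15, 0.71)],
    ("rs1799750", "ACLRC", "dominant"): [(0.26, 0.10, 0.70)],
    ("rs1799750", "ACLRC", "recessive"): [(0.00, None, None)],
    ("rs486055", "ACLRP", "codominant"): [(3.46, 1.62, 7.38), (0.96, 0.11, 8.68)],
    ("rs486055", "ACLRP", "dominant"): [(3.09, 1.48, 6.47)],
    ("rs486055", "ACLRP", "overdominant"): [(3.47, 1.64, 7.33)],
    ("rs2276109", "ACLF", "codominant"): [(3.53, 1.51, 8.22), (6.85, 0.69, 67.89)],
    ("rs2276109", "ACLF", "dominant"): [(3.80, 1.69, 8.54)],
    ("rs2276109", "ACLF", "recessive"): [(5.36, 0.54, 52.73)],
    ("rs2276109", "ACLF", "overdominant"): [(3.31, 1.43, 7.69)],
}

_OUTCOMES = ("ACLF", "ACLS", "ACLRP", "ACLRC")
_MODELS = ("codominant", "dominant", "recessive", "overdominant")

#: Published unadjusted / FDR-adjusted p-value pairs, one per model block,
#: within-case family (m = 3 SNPs x 4 outcomes x 4 models = 48).
WITHIN_CASE_P = {
    "rs1799750": {
        "ACLF": [(0.001, 0.0096), (0.365, 0.631), (0.0002, 0.0096), (0.031, 0.099)],
        "ACLS": [(0.468, 0.702), (0.257, 0.549), (0.939, 1.0), (0.263, 0.549)],
        "ACLRP": [(0.003, 0.018), (0.001, 0.0096), (0.865, 0.944), (0.003, 0.018)],
        "ACLRC": [(0.006, 0.024), (0.007, 0.026), (0.025, 0.086), (0.411, 0.680)],
    },
    "rs486055": {
        "ACLF": [(0.444, 0.687), (0.207, 0.549), (0.854, 0.944), (0.220, 0.549)],
        "ACLS": [(0.850, 0.944), (0.632, 0.798), (0.862, 0.944), (0.574, 0.798)],
        "ACLRP": [(0.005, 0.022), (0.003, 0.018), (0.616, 0.798), (0.001, 0.0096)],
        "ACLRC": [(0.496, 0.721), (0.237, 0.549), (0.725, 0.870), (0.287, 0.574)],
    },
    "rs2276109": {
        "ACLF": [(0.004, 0.021), (0.0009, 0.0096), (0.116, 0.348), (0.005, 0.022)],
        "ACLS": [(0.598, 0.798), (0.252, 0.549), (1.0, 1.0), (0.440, 0.687)],
        "ACLRP": [(0.611, 0.798), (0.340, 0.628), (1.0, 1.0), (0.322, 0.618)],
        "ACLRC": [(0.718, 0.870), (0.240, 0.549), (1.0, 1.0), (0.368, 0.631)],
    },
}

#: Case-control family (m = 3 SNPs x 4 models = 12): (p, FDR p) per model.
CASE_CONTROL_P = {
    "rs1799750": {
        "codominant": (0.018, 0.072),
        "dominant": (0.728, 0.728),
        "recessive": (0.014, 0.072),
        "overdominant": (0.011, 0.072),
    },
    "rs486055": {
        "codominant": (0.674, 0.728),
        "dominant": (0.718, 0.728),
        "recessive": (0.486, 0.716),
        "overdominant": (0.537, 0.716),
    },
    "rs2276109": {
        "codominant": (0.209, 0.418),
        "dominant": (0.206, 0.418),
        "recessive": (0.152, 0.418),
        "overdominant": (0.324, 0.555),
    },
}


def within_case_p_family() -> list[float]:
    """The 48 unadjusted within-case p-values in table order."""
    return [
        WITHIN_CASE_P[snp.id][outcome][i][0]
        for snp in SNPS
        for outcome in _OUTCOMES
        for i in range(len(_MODELS))
    ]


def within_case_fdr_family() -> list[float]:
    """The 48 published FDR-adjusted within-case p-values, same order."""
    return [
        WITHIN_CASE_P[snp.id][outcome][i][1]
        for snp in SNPS
        for outcome in _OUTCOMES
        for i in range(len(_MODELS))
    ]


def case_control_p_family() -> list[float]:
    """The 12 unadjusted case-control p-values in table order."""
    return [CASE_CONTROL_P[snp.id][m][0] for snp in SNPS for m in _MODELS]


def case_control_fdr_family() -> list[float]:
    """The 12 published FDR-adjusted case-control p-values, same order."""
    return [CASE_CONTROL_P[snp.id][m][1] for snp in SNPS for m in _MODELS]


#: Sub-phenotype prevalences among cases, from the within-case table margins.
SUBTYPE_PREVALENCE = {
    "ACLF": 58 / 159,  # fraction with multiple injuries
    "ACLS": 128 / 159,
    "ACLRP": 40 / 160,
    "ACLRC": 19 / 159,
}
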