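"""Published summary data from the retrospective HD vancomycin cohort.

These are printed summary counts from the multicentre retrospective study
of AUC-guided vancomycin in thrice-weekly haemodialysis that this package
models: per-factor 2x2 early-response counts in the MRSA-infected subgroup,
response proportions by exposure category, and the dose means per regimen
class.  They are inputs for recomputing the study's contingency statistics;
no individual-level data are included (none are published).
"""

from __future__ import annotations

from .stats import ContingencyTable

# Early clinical response in MRSA-infected patients, per factor:
# (a, b) responders/non-responders with the factor, (c, d) without it.
# `printed_or` is the crude OR as printed, for cross-checking.
EARLY_RESPONSE_FACTORS: dict[str, dict] = {
    "male_sex": {"table": ContingencyTable(13, 8, 5, 5), "printed_or": 1.63},
    "icu_stay": {"table": ContingencyTable(2, 2, 16, 11), "printed_or": 0.69},
    "age_ge_65": {"table": ContingencyTable(16, 9, 2, 4), "printed_or": 3.56},
    "bmi_lt_18_5": {"table": ContingencyTable(3, 4, 15, 9), "printed_or": 0.45},
    "bmi_ge_25": {"table": ContingencyTable(5, 4, 13, 9), "printed_or": 0.87},
    "surgery_within_30d": {"table": ContingencyTable(4, 2, 14, 11), "printed_or": 1.57},
    "sofa_gt_5": {"table": ContingencyTable(7, 6, 11, 7), "printed_or": 0.74},
    "mechanical_ventilation": {"table": ContingencyTable(1, 1, 17, 12), "printed_or": 0.71},
    "complicated_mrsa_infection": {"table": ContingencyTable(8, 9, 10, 4), "printed_or": 0.36},
    "bloodstream_infection": {"table": ContingencyTable(3, 3, 15, 10), "printed_or": 0.67},
    "bone_and_joint_infection": {"table": ContingencyTable(7, 5, 11, 8), "printed_or": 1.02},
    "skin_soft_tissue_infection": {"table": ContingencyTable(6, 3, 12, 10), "printed_or": 1.67},
    "respiratory_tract_infection": {"table": ContingencyTable(5, 3, 13, 10), "printed_or": 1.28},
    "gram_negative_coinfection": {"table": ContingencyTable(10, 6, 8, 7), "printed_or": 1.46},
    "auc2_mic_ge_400": {"table": ContingencyTable(15, 4, 3, 9), "printed_or": 11.25},
    "source_control": {"table": ContingencyTable(12, 5, 6, 8), "printed_or": 3.20},
    "charlson_gt_11": {"table": ContingencyTable(6, 5, 12, 8), "printed_or": 0.80},
    "mi_chf": {"table": ContingencyTable(14, 9, 4, 4), "printed_or": 1.56},
    "diabetes": {"table": ContingencyTable(11, 8, 7, 5), "printed_or": 0.98},
    "liver_disease": {"table": ContingencyTable(1, 2, 17, 11), "printed_or": 0.32},
    "cerebrovascular_disease": {"table": ContingencyTable(2, 3, 16, 10), "printed_or": 0.42},
    "chronic_pulmonary_disease": {"table": ContingencyTable(3, 2, 15, 11), "printed_or": 1.10},
    "malignancy_within_5y": {"table": ContingencyTable(5, 5, 13, 8), "printed_or": 0.62},
}

# Early-response counts by exposure category: (responders, total).
RESPONSE_COUNTS = {
    "mrsa_auc_mic_ge_400": (15, 19),
    "mrsa_auc_mic_lt_400": (3, 12),
    "resistant_gp_auc_mic_ge_400": (32, 38),
    "resistant_gp_auc_mic_lt_400": (3, 12),
}

# Observed dose means per regimen class (mg/kg): loading, maintenance.
REGIMEN_DOSE_MEANS = {
    "low": (20.5, 8.0),
    "standard": (26.7, 9.0),
    "high": (30.7, 9.9),
}

# MIC distribution among MRSA isolates (ug/mL -> number of strains).
MIC_FREQUENCIES = {0.5: 2, 1.0: 28, 2.0: 1}
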