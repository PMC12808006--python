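"""Published per-cluster summary tables used as generator presets and worked-example inputs.

These are the printed cluster summaries of a nationwide Danish multimorbidity
cohort (1,184,334 people with >= 2 of 33 chronic conditions, index year 2019)
segmented into four groups by weighted k-means.  The registry microdata are not
publicly available, so these marginal tables are the closest available
description of the cohort's per-cluster structure; the synthetic generator
uses them as its "paper-like" preset and the worked O/E examples recompute
ratios from them.

Prevalences and O/E ratios are stored exactly as printed (percent, two
decimals; O/E to two decimals except one three-decimal cell).
"""

# Cluster sizes (persons) and total cohort size as printed.
CLUSTER_SIZES = (24_017, 5_035, 918_901, 236_381)
TOTAL_N = 1_184_334

# condition -> (prevalence % in clusters 1-4 and overall, printed O/E in clusters 1-4)
CONDITION_TABLE: dict[str, tuple[tuple[float, float, float, float, float],
                                 tuple[float, float, float, float]]] = {
    "ischemic_heart_disease": ((24.60, 10.54, 15.21, 21.94, 16.72), (1.47, 0.63, 0.91, 1.31)),
    "atrial_fibrillation": ((22.78, 5.14, 9.87, 17.65, 11.66), (1.95, 0.44, 0.85, 1.51)),
    "heart_failure": ((14.79, 2.56, 4.51, 7.83, 5.37), (2.75, 0.48, 0.84, 1.46)),
    "peripheral_artery_occlusive_disease": ((14.03, 3.08, 5.89, 8.98, 6.66), (2.11, 0.46, 0.88, 1.35)),
    "hypertension": ((70.70, 46.07, 68.11, 78.56, 70.15), (1.01, 0.66, 0.97, 1.12)),
    "stroke": ((17.90, 5.72, 8.49, 10.36, 9.04), (1.98, 0.63, 0.94, 1.15)),
    "high_cholesterol": ((37.71, 25.10, 43.88, 51.78, 45.25), (0.83, 0.55, 0.97, 1.14)),
    "diabetes_type1": ((9.18, 3.81, 4.04, 5.07, 4.35), (2.11, 0.88, 0.93, 1.17)),
    "diabetes_type2": ((21.10, 10.74, 16.53, 24.99, 18.29), (1.15, 0.59, 0.90, 1.37)),
    "obesity": ((12.64, 19.62, 10.37, 11.16, 10.61), (1.19, 1.85, 0.98, 1.051)),
    "copd": ((22.09, 19.18, 17.06, 22.80, 18.31), (1.21, 1.05, 0.93, 1.25)),
    "allergies": ((9.08, 20.35, 12.39, 14.76, 12.83), (0.71, 1.59, 0.97, 1.15)),
    "joint_disease": ((2.98, 2.30, 2.57, 3.12, 2.69), (1.11, 0.86, 0.96, 1.16)),
    "osteoporosis": ((17.15, 11.64, 14.19, 18.12, 15.02), (1.14, 0.77, 0.94, 1.21)),
    "osteoarthritis": ((21.65, 17.97, 22.08, 27.29, 23.10), (0.94, 0.78, 0.96, 1.18)),
    "cancer_digestive": ((8.39, 1.53, 1.86, 2.25, 2.07), (4.06, 0.74, 0.90, 1.09)),
    "cancer_respiratory": ((5.03, 0.66, 0.79, 1.25, 0.96), (5.21, 0.68, 0.81, 1.30)),
    "cancer_skin": ((0.99, 0.87, 0.80, 0.89, 0.84), (1.20, 1.06, 0.98, 1.07)),
    "cancer_breast": ((4.07, 4.31, 2.83, 2.82, 2.86), (1.42, 1.50, 0.99, 0.99)),
    "cancer_genital": ((5.86, 1.59, 2.61, 3.18, 2.79), (2.10, 0.57, 0.94, 1.14)),
    "cancer_other": ((11.52, 2.20, 2.57, 3.11, 2.85), (4.04, 0.77, 0.90, 1.09)),
    "epilepsy": ((13.54, 10.15, 5.81, 5.98, 6.02), (2.25, 1.69, 0.97, 0.99)),
    "parkinsons_disease": ((1.82, 0.36, 0.66, 1.06, 0.77), (2.38, 0.47, 0.87, 1.39)),
    "multiple_sclerosis": ((1.13, 1.45, 0.85, 0.68, 0.82), (1.37, 1.76, 1.03, 0.82)),
    "dementia": ((3.56, 0.62, 2.78, 2.98, 2.83), (1.26, 0.22, 0.98, 1.05)),
    "schizophrenia": ((4.35, 0.54, 0.50, 0.53, 0.59), (7.41, 0.91, 0.86, 0.90)),
    "depression": ((33.14, 53.69, 19.34, 23.26, 20.55), (1.61, 2.61, 0.94, 1.13)),
    "anxiety": ((4.54, 5.10, 0.94, 1.01, 1.05), (4.34, 4.88, 0.90, 0.96)),
    "addictive_disorder": ((7.15, 1.05, 1.03, 0.98, 1.14), (6.27, 0.92, 0.90, 0.86)),
    "personality_disorder": ((2.00, 0.75, 0.28, 0.27, 0.32), (6.30, 2.37, 0.89, 0.87)),
    "kidney_disease": ((11.07, 1.65, 2.63, 3.74, 3.02), (3.67, 0.55, 0.87, 1.24)),
    "liver_disease": ((6.00, 1.33, 1.72, 1.63, 1.79), (3.35, 0.74, 0.96, 0.91)),
    "bowel_disease": ((8.35, 6.61, 4.50, 4.92, 4.67), (1.79, 1.42, 0.96, 1.05)),
}

# utilization variable -> yearly mean in clusters 1-4 and overall
UTILIZATION_MEANS: dict[str, tuple[float, float, float, float, float]] = {
    "hospitalizations": (4.15, 0.40, 0.048, 0.52, 0.23),
    "bed_days": (29.49, 1.67, 0.14, 1.61, 1.03),
    "medication_usage": (9.30, 5.97, 5.57, 8.09, 6.15),
    "outpatient_visits": (16.13, 3.55, 0.47, 3.64, 1.43),
    "gp_visits": (21.74, 16.59, 3.19, 23.10, 7.59),
    "specialist_visits": (2.46, 4.33, 0.46, 6.08, 1.64),
    "psychologist_visits": (0.039, 8.84, 0.0062, 0.024, 0.048),
}

# sociodemographic variable -> category -> percent in clusters 1-4 and overall
SOCIODEMO_DISTRIBUTIONS: dict[str, dict[str, tuple[float, ...]]] = {
    "age_band": {
        "<16": (0.87, 0.26, 0.92, 0.32, 0.80),
        "17-24": (1.92, 3.08, 1.07, 0.61, 1.0),
        "25-44": (9.74, 26.77, 7.70, 4.73, 7.22),
        "45-64": (26.2, 47.58, 32.13, 22.24, 30.1),
        "65-84": (50.39, 21.83, 49.78, 59.39, 51.58),
        ">85": (10.88, 0.5, 8.41, 12.72, 9.29),
    },
    "sex": {
        "male": (52.85, 24.44, 45.84, 43.84, 45.48),
        "female": (47.15, 75.56, 54.16, 56.16, 54.52),
    },
    "family_type": {
        "registered_partnership": (0.1, 0.2, 0.14, 0.11, 0.13),
        "cohabiting_couple": (2.47, 4.86, 2.75, 1.92, 2.6),
        "co_residing_couple": (4.18, 8.76, 5.41, 4.71, 5.26),
        "married_couple": (40.07, 43.08, 52.09, 50.67, 51.52),
        "single": (53.22, 43.1, 39.62, 42.59, 40.49),
    },
    "region": {
        "north_denmark": (8.68, 12.69, 11.37, 11.53, 11.35),
        "central_denmark": (18.95, 23.65, 23.09, 22.79, 22.95),
        "southern_denmark": (23.49, 24.56, 23.91, 24.91, 24.10),
        "capital": (32.19, 23.85, 25.72, 25.72, 25.84),
        "zealand": (16.7, 15.25, 15.9, 15.05, 15.74),
    },
    "employment": {
        "self_employed": (1.4, 2.74, 2.39, 1.56, 2.21),
        "employee": (12.66, 42.36, 27.7, 15.19, 24.96),
        "unemployed": (1.93, 5.69, 1.2, 1.05, 1.20),
        "in_education": (1.12, 4.4, 1.24, 0.64, 1.13),
        "early_retirement": (15.4, 10.46, 7.7, 8.24, 7.99),
        "retired": (57.41, 35.42, 53.2, 67.77, 56.13),
        "social_assistance": (8.2, 13.05, 4.67, 4.57, 4.75),
        "unknown": (1.88, 1.97, 1.91, 0.95, 1.72),
    },
    "education": {
        "none": (29.65, 9.05, 24.81, 30.38, 25.95),
        "short": (36.39, 44.52, 38.39, 36.56, 38.0),
        "medium": (18.95, 16.64, 19.45, 18.47, 19.22),
        "long": (11.65, 28.57, 14.65, 12.33, 14.27),
        "unknown": (3.36, 1.21, 2.7, 2.27, 2.62),
    },
    "income_quartile": {
        "Q1": (25.29, 21.03, 22.66, 25.08, 23.17),
        "Q2": (53.01, 44.88, 46.77, 50.54, 47.65),
        "Q3": (8.81, 14.44, 11.58, 10.32, 11.29),
        "Q4": (12.87, 19.64, 18.99, 14.06, 17.89),
    },
}

MEAN_AGE = (64.81, 51.52, 64.43, 69.16, 65.33)
MEAN_CONDITIONS = (4.51, 2.98, 3.08, 3.85, 3.26)


def cluster_share_percent(cluster: int) -> float:
    """Share of the total cohort in cluster 1..4, in percent (unrounded)."""
    return 100.0 * CLUSTER_SIZES[cluster - 1] / TOTAL_N
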