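"""Cohort schema and delimited-text I/O.

The analysis input is a person-level table: one row per person with 33 binary
chronic-condition indicators, 7 non-negative healthcare-utilization counts
(accumulated over one year), and categorical sociodemographics.  Everyone in a
multimorbidity cohort has at least two of the 33 conditions; three of the
conditions (hypertension, high cholesterol, obesity) double as lifestyle risk
factors and can be excluded from the condition-portfolio analyses.

Files are comma-separated UTF-8 with a mandatory header.  Condition columns may
appear in any order in an input file as long as the names match; they are
reordered internally to the canonical catalog order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

# Canonical condition catalog: (snake_case name, body-system category).
_CONDITIONS: list[tuple[str, str]] = [
    ("ischemic_heart_disease", "circulatory"),
    ("atrial_fibrillation", "circulatory"),
    ("heart_failure", "circulatory"),
    ("peripheral_artery_occlusive_disease", "circulatory"),
    ("hypertension", "circulatory"),
    ("stroke", "circulatory"),
    ("high_cholesterol", "circulatory"),
    ("diabetes_type1", "endocrine"),
    ("diabetes_type2", "endocrine"),
    ("obesity", "endocrine"),
    ("copd", "pulmonary"),
    ("allergies", "pulmonary"),
    ("joint_disease", "musculoskeletal"),
    ("osteoporosis", "musculoskeletal"),
    ("osteoarthritis", "musculoskeletal"),
    ("cancer_digestive", "cancers"),
    ("cancer_respiratory", "cancers"),
    ("cancer_skin", "cancers"),
    ("cancer_breast", "cancers"),
    ("cancer_genital", "cancers"),
    ("cancer_other", "cancers"),
    ("epilepsy", "neurological"),
    ("parkinsons_disease", "neurological"),
    ("multiple_sclerosis", "neurological"),
    ("dementia", "mental_health"),
    ("schizophrenia", "mental_health"),
    ("depression", "mental_health"),
    ("anxiety", "mental_health"),
    ("addictive_disorder", "mental_health"),
    ("personality_disorder", "mental_health"),
    ("kidney_disease", "urogenital"),
    ("liver_disease", "gastrointestinal"),
    ("bowel_disease", "gastrointestinal"),
]

RISK_FACTORS = ("hypertension", "high_cholesterol", "obesity")

UTILIZATION_VARIABLES = (
    "hospitalizations",
    "bed_days",
    "medication_usage",
    "outpatient_visits",
    "gp_visits",
    "specialist_visits",
    "psychologist_visits",
)

SOCIODEMO_VARIABLES = (
    "age_band",
    "sex",
    "family_type",
    "region",
    "employment",
    "education",
    "income_quartile",
)

AGE_BANDS = ("<16", "17-24", "25-44", "45-64", "65-84", ">85")


@dataclass(frozen=True)
class ConditionCatalog:
    """Ordered catalog of the chronic conditions used for clustering.

    ``is_risk_factor`` is true exactly for hypertension, high cholesterol and
    obesity — conditions that stand in for lifestyle risk factors and are
    dropped in the secondary portfolio analyses.
    """

    names: tuple[str, ...]
    categories: tuple[str, ...]
    is_risk_factor: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise SchemaError("condition names must be unique")
        if not (len(self.names) == len(self.categories) == len(self.is_risk_factor)):
            raise SchemaError("catalog fields must have equal length")

    @classmethod
    def default(cls) -> "ConditionCatalog":
        names = tuple(name for name, _ in _CONDITIONS)
        cats = tuple(cat for _, cat in _CONDITIONS)
        return cls(names, cats, tuple(n in RISK_FACTORS for n in names))

    @property
    def n_conditions(self) -> int:
        return len(self.names)

    @property
    def risk_factor_names(self) -> tuple[str, ...]:
        return tuple(n for n, rf in zip(self.names, self.is_risk_factor) if rf)


@dataclass(frozen=True)
class UtilizationSchema:
    """Ordered list of the yearly healthcare-utilization count variables."""

    names: tuple[str, ...] = UTILIZATION_VARIABLES

    @property
    def n_variables(self) -> int:
        return len(self.names)


@dataclass
class CohortMatrix:
    """Validated person-level cohort: conditions, utilization, sociodemographics.

    ``conditions`` and ``utilization`` are DataFrames aligned row-for-row with
    ``person_id``; ``sociodemo`` holds the categorical descriptors that are
    never used for clustering, only for profiling.
    """

    person_id: pd.Series
    conditions: pd.DataFrame
    utilization: pd.DataFrame
    sociodemo: pd.DataFrame
    catalog: ConditionCatalog = field(default_factory=ConditionCatalog.default)
    util_schema: UtilizationSchema = field(default_factory=UtilizationSchema)

    @property
    def n(self) -> int:
        return len(self.person_id)

    def validate(self, enforce_multimorbidity: bool = True) -> "CohortMatrix":
        """Check all invariants; raise CohortValidationError on the first breach."""
        if self.person_id.duplicated().any():
            dupes = self.person_id[self.person_id.duplicated()].tolist()
            raise CohortValidationError(f"duplicate person_id values: {dupes[:5]}")
        cond = self.conditions.to_numpy()
        bad = ~np.isin(cond, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"non-binary condition value {cond[r, c]!r} at row {r}, "
                f"column {self.conditions.columns[c]!r}"
            )
        util = self.utilization.to_numpy()
        if not np.issubdtype(util.dtype, np.number):
            raise CohortValidationError("utilization columns must be numeric")
        if np.isnan(util.astype(float)).any():
            raise CohortValidationError("missing utilization values are not allowed")
        if (util < 0).any():
            r, c = np.argwhere(util < 0)[0]
            raise CohortValidationError(
                f"negative utilization value at row {r}, "
                f"column {self.utilization.columns[c]!r}"
            )
        if enforce_multimorbidity:
            sums = cond.sum(axis=1)
            low = sums < 2
            if low.any():
                ids = self.person_id[low].tolist()
                raise CohortValidationError(
                    f"{low.sum()} person(s) with fewer than 2 conditions: {ids[:10]}"
                )
        return self

    def condition_counts(self) -> np.ndarray:
        return self.conditions.to_numpy().sum(axis=1)

    def subset(self, mask: np.ndarray) -> "CohortMatrix":
        return replace(
            self,
            person_id=self.person_id[mask].reset_index(drop=True),
            conditions=self.conditions[mask].reset_index(drop=True),
            utilization=self.utilization[mask].reset_index(drop=True),
            sociodemo=self.sociodemo[mask].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.person_id.rename("person_id"), self.conditions,
             self.utilization, self.sociodemo],
            axis=1,
        )


def cohort_columns(
    catalog: ConditionCatalog | None = None,
    util_schema: UtilizationSchema | None = None,
) -> list[str]:
    """Canonical cohort CSV column order."""
    catalog = catalog or ConditionCatalog.default()
    util_schema = util_schema or UtilizationSchema()
    return ["person_id", *catalog.names, *util_schema.names, *SOCIODEMO_VARIABLES]


def schema_manifest(
    catalog: ConditionCatalog | None = None,
    util_schema: UtilizationSchema | None = None,
) -> dict:
    """Machine-readable description of the cohort CSV schema."""
    catalog = catalog or ConditionCatalog.default()
    util_schema = util_schema or UtilizationSchema()
    return {
        "format": "comma-separated UTF-8, header row mandatory, one row per person",
        "id_column": "person_id",
        "condition_columns": [
            {"name": n, "category": c, "risk_factor": bool(rf), "values": [0, 1]}
            for n, c, rf in zip(catalog.names, catalog.categories, catalog.is_risk_factor)
        ],
        "utilization_columns": [
            {"name": n, "values": "non-negative count"} for n in util_schema.names
        ],
        "sociodemographic_columns": [
            {"name": n, "values": "category label; missing maps to 'unknown'"}
            for n in SOCIODEMO_VARIABLES
        ],
        "multimorbidity_constraint": "row sum over condition columns >= 2",
    }


def read_cohort(
    path,
    catalog: ConditionCatalog | None = None,
    util_schema: UtilizationSchema | None = None,
    enforce_multimorbidity: bool = True,
) -> CohortMatrix:
    """Read and validate a cohort CSV.

    Condition/utilization columns are matched by name (case-sensitive) and
    reordered to the canonical order; missing sociodemographic cells map to
    the "unknown" category, missing condition or utilization cells are errors.
    """
    catalog = catalog or ConditionCatalog.default()
    util_schema = util_schema or UtilizationSchema()
    df = pd.read_csv(path)
    expected = set(cohort_columns(catalog, util_schema))
    have = set(df.columns)
    missing = sorted(expected - have)
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    extra = sorted(have - expected)
    if extra:
        raise SchemaError(f"unexpected column(s): {extra}")

    cond = df[list(catalog.names)]
    if cond.isna().any().any():
        col = cond.columns[cond.isna().any()][0]
        raise CohortValidationError(f"missing condition values in column {col!r}")
    util = df[list(util_schema.names)].apply(pd.to_numeric)
    util_np = util.to_numpy()
    if np.all(util_np == np.floor(util_np)):
        util = util.astype(np.int64)
    socio = df[list(SOCIODEMO_VARIABLES)].astype("string").fillna("unknown").astype(object)

    cohort = CohortMatrix(
        person_id=df["person_id"],
        conditions=cond,
        utilization=util,
        sociodemo=socio,
        catalog=catalog,
        util_schema=util_schema,
    )
    return cohort.validate(enforce_multimorbidity=enforce_multimorbidity)


def write_cohort(cohort: CohortMatrix, path) -> str:
    """Write the cohort as CSV in canonical column order; round-trips exactly."""
    frame = cohort.to_frame()[cohort_columns(cohort.catalog, cohort.util_schema)]
    frame.to_csv(path, index=False)
    return str(path)
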