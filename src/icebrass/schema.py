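"""Column schema, category labels and grouping rules shared across modules.

A "female record table" is a pandas DataFrame with one row per surveyed
female. Raw columns come from the survey file; derived columns are added by
:func:`icebrass.survey.derive_fields`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

# ---------------------------------------------------------------------------
# Columns

#: Columns a raw survey table must carry.
RAW_COLUMNS = [
    "wave_year",
    "cluster_id",
    "weight",
    "age_years",
    "residence",
    "region",
    "district",
    "education",
    "wealth_quintile",
    "pregnant",
    "bmi",
    "ceb",
    "sons_dead",
    "daughters_dead",
]

#: Columns added by derive_fields.
DERIVED_COLUMNS = ["children_dead", "age_group3", "age_group5", "bmi_category"]

# ---------------------------------------------------------------------------
# Category labels (orderings matter for gradients and presentation)

RESIDENCE = ["urban", "rural"]
REGIONS = ["North", "Central", "South"]
EDUCATION = ["none", "primary", "secondary", "tertiary"]
WEALTH_QUINTILES = ["poorest", "poorer", "middle", "richer", "richest"]
BMI_CATEGORIES = ["underweight", "normal", "overweight", "obese"]

AGE3_LABELS = ["15-24", "25-34", "35-49"]
AGE5_LABELS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]

#: WHO adult BMI cutoffs (kg/m^2), half-open intervals [lower, upper).
BMI_CUTOFFS = {"underweight": 18.5, "normal": 25.0, "overweight": 30.0}

#: The 28 districts of Malawi by administrative region; used for validation
#: warnings and as the synthetic generator's sampling frame.
MALAWI_DISTRICTS = {
    "North": ["Chitipa", "Karonga", "Likoma", "Mzimba", "Nkhata Bay", "Rumphi"],
    "Central": [
        "Dedza", "Dowa", "Kasungu", "Lilongwe", "Mchinji",
        "Nkhotakota", "Ntcheu", "Ntchisi", "Salima",
    ],
    "South": [
        "Balaka", "Blantyre", "Chikwawa", "Chiradzulu", "Machinga",
        "Mangochi", "Mulanje", "Mwanza", "Neno", "Nsanje",
        "Phalombe", "Thyolo", "Zomba",
    ],
}

DISTRICT_TO_REGION = {
    d: region for region, ds in MALAWI_DISTRICTS.items() for d in ds
}

# ---------------------------------------------------------------------------
# Grouping rules


def age_group3(age_years: int) -> str:
    """Three broad reproductive-age stages: 15-24, 25-34, 35-49."""
    if age_years < 15 or age_years > 49:
        raise ValueError(f"age {age_years} outside 15-49")
    if age_years <= 24:
        return AGE3_LABELS[0]
    if age_years <= 34:
        return AGE3_LABELS[1]
    return AGE3_LABELS[2]


def age_group5(age_years: int) -> str:
    """Abridged five-year maternal cohorts 15-19 ... 45-49."""
    if age_years < 15 or age_years > 49:
        raise ValueError(f"age {age_years} outside 15-49")
    return AGE5_LABELS[(age_years - 15) // 5]


def age_group5_index(label: str) -> int:
    """1-based index i of a five-year cohort (15-19 -> 1, ..., 45-49 -> 7)."""
    return AGE5_LABELS.index(label) + 1


def vector_age_group3(ages: pd.Series) -> pd.Series:
    bins = [14, 24, 34, 49]
    return pd.cut(ages, bins=bins, labels=AGE3_LABELS).astype(str)


def vector_age_group5(ages: pd.Series) -> pd.Series:
    bins = [14, 19, 24, 29, 34, 39, 44, 49]
    return pd.cut(ages, bins=bins, labels=AGE5_LABELS).astype(str)


def require_columns(table: pd.DataFrame, columns: list[str], context: str = "") -> None:
    """Raise :class:`SchemaError` naming every missing column."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        where = f" in {context}" if context else ""
        raise SchemaError(f"missing required column(s){where}: {', '.join(missing)}")


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return 0.0
    return float(w.sum() ** 2 / (w**2).sum())
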