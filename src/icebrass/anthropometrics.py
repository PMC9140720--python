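"""WHO BMI categorization, survey descriptives and between-wave tests.

Category counts are reported unweighted by default (sample composition)
with survey-weighted percents available by flag; percentages are always
computed on the unrounded values and rounded only for presentation,
half-away-from-zero to one decimal.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .schema import (
    AGE3_LABELS,
    BMI_CATEGORIES,
    BMI_CUTOFFS,
    EDUCATION,
    REGIONS,
    RESIDENCE,
    WEALTH_QUINTILES,
    effective_sample_size,
    require_columns,
)

#: Categorical blocks of the descriptive surface, with their display order.
CATEGORICAL_BLOCKS = {
    "age_group3": AGE3_LABELS,
    "residence": RESIDENCE,
    "education": EDUCATION,
    "wealth_quintile": WEALTH_QUINTILES,
    "region": REGIONS,
    "bmi_category": BMI_CATEGORIES,
}

NUMERIC_INDICATORS = ["ceb", "children_dead"]


def categorize_bmi(bmi):
    """WHO adult BMI category for a value or array of values (kg/m^2).

    Half-open intervals: underweight (0, 18.5), normal [18.5, 25),
    overweight [25, 30), obese [30, inf).
    """
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DataError("BMI must be positive and finite")
    cats = np.select(
        [arr < BMI_CUTOFFS["underweight"], arr < BMI_CUTOFFS["normal"],
         arr < BMI_CUTOFFS["overweight"]],
        BMI_CATEGORIES[:3],
        default=BMI_CATEGORIES[3],
    )
    if np.isscalar(bmi) or arr.ndim == 0:
        return str(cats)
    return pd.Series(cats, index=getattr(bmi, "index", None), name="bmi_category")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matches printed-table convention;
    Python's round() would round half to even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _one_wave_descriptives(sub: pd.DataFrame, label, weighted: bool) -> list[dict]:
    rows = []
    w = sub["weight"].to_numpy(float) if weighted else np.ones(len(sub))
    wtot = w.sum()
    for block, order in CATEGORICAL_BLOCKS.items():
        if block not in sub.columns:
            continue
        for cat in order:
            mask = (sub[block] == cat).to_numpy()
            rows.append(
                {
                    "wave_year": label,
                    "indicator": block,
                    "category": cat,
                    "count": int(mask.sum()),
                    "percent": 100.0 * w[mask].sum() / wtot if wtot else np.nan,
                }
            )
    for num in NUMERIC_INDICATORS:
        if num not in sub.columns:
            continue
        v = sub[num].to_numpy(float)
        mean = np.average(v, weights=w)
        sd = np.sqrt(np.average((v - mean) ** 2, weights=w))
        rows.append(
            {
                "wave_year": label,
                "indicator": num,
                "category": "mean",
                "count": len(sub),
                "mean": mean,
                "sd": sd,
                "min": float(v.min()) if len(v) else np.nan,
                "max": float(v.max()) if len(v) else np.nan,
            }
        )
    return rows


def descriptive_table(table: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Tidy descriptive surface: counts and percents per categorical block,
    mean/SD/range per numeric indicator, per wave and overall.

    Counts are always raw row counts; ``weighted=True`` switches percents
    and numeric moments to survey-weighted versions.
    """
    if table.empty:
        warnings.warn("descriptive_table called on an empty table")
        return pd.DataFrame(
            columns=["wave_year", "indicator", "category", "count", "percent"]
        )
    require_columns(table, ["wave_year", "weight"], "descriptive_table")
    rows = []
    for wave, sub in table.groupby("wave_year"):
        rows += _one_wave_descriptives(sub, wave, weighted)
    rows += _one_wave_descriptives(table, "total", weighted)
    return pd.DataFrame(rows)


def mean_bmi_by(table: pd.DataFrame, stratifier: str, weighted: bool = True) -> pd.DataFrame:
    """Survey-weighted mean BMI per stratum per wave (trend surface)."""
    if stratifier not in CATEGORICAL_BLOCKS or stratifier == "bmi_category":
        raise DataError(f"unknown stratifier {stratifier!r}")
    require_columns(table, ["wave_year", "bmi", "weight", stratifier], "mean_bmi_by")
    w = table["weight"] if weighted else pd.Series(1.0, index=table.index)
    df = table.assign(_w=w, _wb=w * table["bmi"])
    g = df.groupby(["wave_year", stratifier], observed=True)[["_w", "_wb"]].sum()
    out = g.reset_index()
    out["mean_bmi"] = out["_wb"] / out["_w"]
    out["n"] = df.groupby(["wave_year", stratifier], observed=True).size().to_numpy()
    return out.drop(columns=["_w", "_wb"])


class VariationTest(NamedTuple):
    statistic: float
    df: float
    pvalue: float
    kind: str  # "anova" or "chi2"


def variation_test(table: pd.DataFrame, indicator: str, weighted: bool = True) -> VariationTest:
    """Test whether an indicator's distribution differs across survey waves.

    Numeric indicators: one-way ANOVA on wave means (two waves reduce to a
    t test, F = t^2). Categorical indicators: Pearson chi-square test of
    homogeneity of the wave-by-category table. With ``weighted=True`` both
    use survey weights through Kish effective sample sizes -- an
    approximation to a design-based test, adequate for tables whose only
    design feature is an individual relative weight.
    """
    require_columns(table, ["wave_year", indicator], "variation_test")
    waves = [sub for _, sub in table.groupby("wave_year")]
    if len(waves) < 2:
        raise DataError("variation_test needs at least two survey waves")

    if indicator in CATEGORICAL_BLOCKS:
        cats = [c for c in CATEGORICAL_BLOCKS[indicator]
                if (table[indicator] == c).any()]
        counts = np.zeros((len(waves), len(cats)))
        for r, sub in enumerate(waves):
            w = sub["weight"].to_numpy(float) if weighted else np.ones(len(sub))
            neff = effective_sample_size(w)
            for c, cat in enumerate(cats):
                share = w[(sub[indicator] == cat).to_numpy()].sum() / w.sum()
                counts[r, c] = share * neff
        stat, p, dof, _ = stats.chi2_contingency(counts)
        return VariationTest(float(stat), float(dof), float(p), "chi2")

    # numeric: weighted one-way ANOVA via group moments and effective n
    stats_per = []
    for sub in waves:
        v = sub[indicator].to_numpy(float)
        w = sub["weight"].to_numpy(float) if weighted else np.ones(len(sub))
        mean = np.average(v, weights=w)
        var = np.average((v - mean) ** 2, weights=w)
        stats_per.append((mean, var, effective_sample_size(w)))
    means = np.array([s[0] for s in stats_per])
    variances = np.array([s[1] for s in stats_per])
    ns = np.array([s[2] for s in stats_per])
    grand = np.average(means, weights=ns)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float((ns * variances).sum())
    df_b = len(waves) - 1
    df_w = float(ns.sum() - len(waves))
    if ss_within == 0:
        return VariationTest(0.0 if ss_between == 0 else np.inf, df_b, 1.0 if ss_between == 0 else 0.0, "anova")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return VariationTest(float(F), float(df_b), p, "anova")


def wide_descriptives(tidy: pd.DataFrame) -> pd.DataFrame:
    """Wide presentation view: one row per (indicator, category), one
    column pair (count, rounded percent) per wave."""
    cat = tidy[tidy["percent"].notna()] if "percent" in tidy.columns else tidy
    wide = cat.pivot_table(
        index=["indicator", "category"], columns="wave_year",
        values=["count", "percent"], aggfunc="first", sort=False,
    )
    if ("percent",) in [c[:1] for c in wide.columns]:
        wide = wide.copy()
        for col in wide.columns:
            if col[0] == "percent":
                wide[col] = wide[col].map(
                    lambda v: round_half_away(v, 1) if pd.notna(v) else v
                )
    return wide
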