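"""Brass-type indirect estimation of child mortality.

The chain implemented here is the classic children-ever-born /
children-dead method with Trussell's West-family multipliers:

1. aggregate women by five-year age group i: number of women W_i, children
   ever born B_i, children dead D_i; hence the proportion dead
   d_i = D_i / B_i and mean parity P_i = B_i / W_i;
2. convert d_i into a probability of dying by exact child age x,
   q(x) = k_i * d_i, where the multiplier
   k_i = a_i + b_i * (P1/P2) + c_i * (P2/P3) corrects for the age pattern
   of childbearing, and x follows the standard correspondence
   15-19 -> q(1), 20-24 -> q(2), 25-29 -> q(3), 30-34 -> q(5),
   35-39 -> q(10), 40-44 -> q(15), 45-49 -> q(20);
3. place the survival probability l(x) = 1 - q(x) on a common mortality
   scale by interpolating the level whose tabulated l(x) matches it
   (higher level = higher survival).

The 15-19 row is computed because reporting surfaces print it, but it is
flagged unreliable: women who bear children that young are a selected,
higher-risk group.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .lifetables import (
    CHILD_AGE_FOR_GROUP,
    ModelLifeTable,
    TrussellCoefficients,
    load_model_lifetable,
    load_trussell_coefficients,
)
from .schema import AGE5_LABELS, BMI_CATEGORIES, require_columns

#: Strata reported on the printed mortality-level surface: total population,
#: underweight, normal, and overweight pooled with obese.
TABLE_STRATA = ["total", "underweight", "normal", "overweight_obese"]


def aggregate_by_age(
    table: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Per five-year maternal age group: W_i, B_i, D_i, d_i, P_i.

    Weights scale women, births and deaths alike, so d_i and P_i are
    weight-invariant under uniform rescaling. Groups absent from the data
    appear with W_i = 0; d_i is NaN where B_i = 0.
    """
    require_columns(table, ["age_group5", "ceb", "children_dead"], "aggregate_by_age")
    w = table["weight"].to_numpy(dtype=float) if weighted else np.ones(len(table))
    df = pd.DataFrame(
        {
            "age_group5": table["age_group5"].to_numpy(),
            "W": w,
            "B": w * table["ceb"].to_numpy(dtype=float),
            "D": w * table["children_dead"].to_numpy(dtype=float),
        }
    )
    agg = df.groupby("age_group5")[["W", "B", "D"]].sum()
    agg = agg.reindex(AGE5_LABELS, fill_value=0.0).reset_index()
    agg.insert(0, "i", np.arange(1, 8))
    agg["d"] = np.where(agg["B"] > 0, agg["D"] / agg["B"].replace(0, np.nan), np.nan)
    agg["P"] = np.where(agg["W"] > 0, agg["B"] / agg["W"].replace(0, np.nan), np.nan)
    return agg


def aggregates_from_counts(
    women: Sequence[float],
    children_born: Sequence[float],
    children_dead: Sequence[float],
) -> pd.DataFrame:
    """Build the age-group aggregate frame directly from W/B/D tallies
    (one value per five-year group, 15-19 first)."""
    if not (len(women) == len(children_born) == len(children_dead) == 7):
        raise DataError("need exactly 7 values per series (age groups 15-19..45-49)")
    W = np.asarray(women, dtype=float)
    B = np.asarray(children_born, dtype=float)
    D = np.asarray(children_dead, dtype=float)
    if (D > B).any():
        raise DataError("children dead exceed children ever born in an age group")
    return pd.DataFrame(
        {
            "i": np.arange(1, 8),
            "age_group5": AGE5_LABELS,
            "W": W,
            "B": B,
            "D": D,
            "d": np.where(B > 0, D / np.where(B > 0, B, np.nan), np.nan),
            "P": np.where(W > 0, B / np.where(W > 0, W, np.nan), np.nan),
        }
    )


def multipliers(
    P1: float, P2: float, P3: float, coeffs: TrussellCoefficients | None = None
) -> pd.Series:
    """Trussell multipliers k_i = a_i + b_i*(P1/P2) + c_i*(P2/P3), i=1..7."""
    if coeffs is None:
        coeffs = load_trussell_coefficients()
    if not (P2 > 0):
        raise DataError("P2 (mean parity of women 20-24) must be positive")
    if not (P3 > 0):
        raise DataError("P3 (mean parity of women 25-29) must be positive")
    f = coeffs.frame
    k = f["a"] + f["b"] * (P1 / P2) + f["c"] * (P2 / P3)
    return pd.Series(k.to_numpy(), index=f["i"].to_numpy(), name="k")


def child_mortality(
    agg: pd.DataFrame, coeffs: TrussellCoefficients | None = None
) -> pd.DataFrame:
    """Apply multipliers to an age-group aggregate: adds k, x, q, l.

    q = k * d is clamped into [0, 1] with a ``clamped`` flag rather than
    erroring; l = 1 - q exactly. Rows with undefined d (no reported
    births) keep NaN estimates and are flagged ``undefined``.
    """
    P = agg.set_index("i")["P"]
    k = multipliers(P.loc[1], P.loc[2], P.loc[3], coeffs)
    out = agg.copy()
    out["k"] = k.to_numpy()
    out["x"] = out["age_group5"].map(CHILD_AGE_FOR_GROUP)
    raw_q = out["k"] * out["d"]
    out["q"] = raw_q.clip(0.0, 1.0)
    out["clamped"] = (raw_q < 0) | (raw_q > 1)
    out["l"] = 1.0 - out["q"]
    out["undefined"] = out["d"].isna()
    out["unreliable"] = out["age_group5"] == "15-19"
    return out


def mortality_levels(
    estimates: pd.DataFrame, lifetable: ModelLifeTable | None = None
) -> pd.DataFrame:
    """Interpolated mortality level per row of a child_mortality frame."""
    if lifetable is None:
        lifetable = load_model_lifetable()
    out = estimates.copy()
    levels, clamped = [], []
    for _, row in out.iterrows():
        if pd.isna(row["l"]) or row["l"] <= 0:
            levels.append(np.nan)
            clamped.append(False)
            continue
        lev, cl = lifetable.mortality_level(float(row["l"]), int(row["x"]))
        levels.append(lev)
        clamped.append(cl)
    out["level"] = levels
    out["level_clamped"] = clamped
    return out


def brass_chain(
    table: pd.DataFrame,
    weighted: bool = True,
    coeffs: TrussellCoefficients | None = None,
    lifetable: ModelLifeTable | None = None,
) -> pd.DataFrame:
    """Full chain on a harmonized female table: aggregate -> multipliers ->
    q(x)/l(x) -> interpolated mortality level."""
    agg = aggregate_by_age(table, weighted=weighted)
    return mortality_levels(child_mortality(agg, coeffs), lifetable)


def _stratum_mask(table: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "total":
        return pd.Series(True, index=table.index)
    if stratum == "overweight_obese":
        return table["bmi_category"].isin(["overweight", "obese"])
    if stratum in BMI_CATEGORIES:
        return table["bmi_category"] == stratum
    raise DataError(f"unknown BMI stratum {stratum!r}")


def mortality_by_bmi_group(
    table: pd.DataFrame,
    weighted: bool = True,
    strata: Sequence[str] = tuple(TABLE_STRATA),
    coeffs: TrussellCoefficients | None = None,
    lifetable: ModelLifeTable | None = None,
) -> pd.DataFrame:
    """Mortality-level grid: age group x BMI stratum x survey wave.

    The printed surface this mirrors pools overweight with obese; the
    ``total`` stratum is the unstratified chain on the whole wave. Cells
    whose stratum-age group reports no births stay NaN.
    """
    require_columns(
        table, ["wave_year", "bmi_category", "age_group5"], "mortality_by_bmi_group"
    )
    if coeffs is None:
        coeffs = load_trussell_coefficients()
    if lifetable is None:
        lifetable = load_model_lifetable()
    frames = []
    for wave, wave_table in table.groupby("wave_year"):
        for stratum in strata:
            sub = wave_table[_stratum_mask(wave_table, stratum)]
            if sub.empty:
                continue
            try:
                est = brass_chain(sub, weighted=weighted, coeffs=coeffs,
                                  lifetable=lifetable)
            except DataError as exc:
                # degenerate stratum (e.g. no women 20-24 or 25-29, so the
                # parity ratios are undefined): blank cells, not a failure
                warnings.warn(
                    f"stratum {stratum!r} in wave {wave}: {exc}; levels left blank"
                )
                est = aggregate_by_age(sub, weighted=weighted)
                est["k"] = np.nan
                est["x"] = est["age_group5"].map(CHILD_AGE_FOR_GROUP)
                est["q"] = np.nan
                est["clamped"] = False
                est["l"] = np.nan
                est["undefined"] = True
                est["unreliable"] = est["age_group5"] == "15-19"
                est["level"] = np.nan
                est["level_clamped"] = False
            est.insert(0, "stratum", stratum)
            est.insert(0, "wave_year", wave)
            frames.append(est)
    return pd.concat(frames, ignore_index=True)


def mortality_grid_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy stratified output into the printed wide layout:
    rows = mother's age group, columns = (stratum, wave_year), values =
    interpolated level."""
    return tidy.pivot_table(
        index="age_group5", columns=["stratum", "wave_year"], values="level",
        sort=False,
    ).reindex(AGE5_LABELS)
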