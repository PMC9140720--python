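"""Index of Concentration at the Extremes (ICE) for BMI.

For a group (a sociodemographic stratum, a district, or a region) with
H obese members, L underweight members and total size T (all possibly
survey-weighted), ICE = (H - L) / T in [-1, 1]: -1 means the group is
entirely underweight, +1 entirely obese, 0 a balance of the extremes.
Normal and overweight members count toward T only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .schema import require_columns

#: Stratifiers the stratum-level surface supports.
STRATIFIERS = ["age_group3", "age_group5", "residence", "education",
               "wealth_quintile", "region"]


def ice(H: float, L: float, T: float) -> float:
    """ICE = (H - L) / T for one group.

    H, L are counts (weighted or not) at the high and low extreme; T is
    the group total. Requires T > 0 and H + L <= T.
    """
    if not T > 0:
        raise DataError("ICE undefined for an empty group (T must be > 0)")
    if H < 0 or L < 0:
        raise DataError("extreme counts must be non-negative")
    if H + L > T * (1 + 1e-12):
        raise DataError(f"H + L = {H + L} exceeds group total T = {T}")
    return (H - L) / T


def _accumulate(
    table: pd.DataFrame,
    keys: list[str],
    weighted: bool,
    include_overweight_high: bool,
) -> pd.DataFrame:
    w = table["weight"].to_numpy(float) if weighted else np.ones(len(table))
    high = ["obese", "overweight"] if include_overweight_high else ["obese"]
    df = pd.DataFrame(
        {
            **{k: table[k].to_numpy() for k in keys},
            "H": np.where(table["bmi_category"].isin(high), w, 0.0),
            "L": np.where(table["bmi_category"] == "underweight", w, 0.0),
            "T": w,
        }
    )
    out = df.groupby(keys, observed=True)[["H", "L", "T"]].sum().reset_index()
    out = out[out["T"] > 0]
    out["ice"] = (out["H"] - out["L"]) / out["T"]
    return out


def ice_by(
    table: pd.DataFrame,
    stratifier: str,
    weighted: bool = True,
    include_overweight_high: bool = False,
) -> pd.DataFrame:
    """ICE per stratum per survey wave.

    ``include_overweight_high`` pools overweight with obese at the high
    extreme (sensitivity variant); the default follows the standard
    definition of obese-vs-underweight.
    """
    if stratifier not in STRATIFIERS:
        raise DataError(f"unknown stratifier {stratifier!r}; one of {STRATIFIERS}")
    require_columns(table, ["wave_year", "bmi_category", "weight", stratifier], "ice_by")
    return _accumulate(table, ["wave_year", stratifier], weighted,
                       include_overweight_high)


def ice_by_area(
    table: pd.DataFrame,
    area_level: str = "district",
    subgroup: str | None = None,
    weighted: bool = True,
    include_overweight_high: bool = False,
) -> pd.DataFrame:
    """ICE per district or region per wave, optionally cross-classified by
    a sociodemographic subgroup; carries mean GPS coordinates per area
    when the table has them (for external mapping)."""
    if area_level not in ("district", "region"):
        raise DataError("area_level must be 'district' or 'region'")
    keys = ["wave_year", area_level]
    if subgroup is not None:
        if subgroup not in STRATIFIERS:
            raise DataError(f"unknown subgroup {subgroup!r}")
        keys.append(subgroup)
    require_columns(table, keys + ["bmi_category", "weight"], "ice_by_area")
    out = _accumulate(table, keys, weighted, include_overweight_high)
    if {"longitude", "latitude"} <= set(table.columns):
        cent = table.groupby(keys[:2], observed=True)[["longitude", "latitude"]].mean()
        out = out.merge(cent.reset_index(), on=keys[:2], how="left")
    return out


def bootstrap_ci(
    table: pd.DataFrame,
    stratifier: str,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Percentile bootstrap CI for stratum ICE, resampling survey clusters.

    Engineering extension: the point surface reports no uncertainty; this
    resamples whole clusters within each wave to respect the survey's
    clustered design.
    """
    rng = np.random.default_rng(seed)
    point = ice_by(table, stratifier, weighted=weighted)
    reps = []
    for b in range(n_boot):
        parts = []
        for wave, sub in table.groupby("wave_year"):
            clusters = sub["cluster_id"].unique()
            take = rng.choice(clusters, size=len(clusters), replace=True)
            grp = sub.groupby("cluster_id")
            parts.append(pd.concat([grp.get_group(c) for c in take]))
        rep = ice_by(pd.concat(parts, ignore_index=True), stratifier,
                     weighted=weighted)
        rep["rep"] = b
        reps.append(rep)
    allreps = pd.concat(reps, ignore_index=True)
    qs = (
        allreps.groupby(["wave_year", stratifier], observed=True)["ice"]
        .quantile([alpha / 2, 1 - alpha / 2])
        .unstack()
        .rename(columns={alpha / 2: "ice_lo", 1 - alpha / 2: "ice_hi"})
        .reset_index()
    )
    return point.merge(qs, on=["wave_year", stratifier], how="left")


def to_geojson(area_ice: pd.DataFrame, area_level: str = "district") -> dict:
    """Point-feature GeoJSON (area centroid) with ICE as a property, for
    external choropleth/mapping tools."""
    feats = []
    for _, row in area_ice.iterrows():
        geom = None
        if "longitude" in area_ice.columns and pd.notna(row.get("longitude")):
            geom = {"type": "Point",
                    "coordinates": [float(row["longitude"]), float(row["latitude"])]}
        feats.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "area": row[area_level],
                    "wave_year": int(row["wave_year"]),
                    "H": float(row["H"]),
                    "L": float(row["L"]),
                    "T": float(row["T"]),
                    "ice": float(row["ice"]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
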