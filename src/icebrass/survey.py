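"""Read, harmonize, filter and merge multi-wave female survey tables.

The canonical on-disk format is plain CSV (UTF-8, one header row) in the
units the analysis uses; a :class:`Dialect` maps foreign column names,
categorical codes and storage scale factors (DHS recodes store BMI as
kg/m^2 x 100 and weights x 1,000,000) onto that canonical form.

The fixed per-wave pipeline order is read -> join_gps -> impute ->
derive_fields -> exclude_pregnant, then waves are merged; imputation runs
before the pregnancy exclusion so a missing pregnancy flag is itself
imputed rather than silently treated as "not pregnant". ``harmonize``
logs row counts at every stage (the selection flowchart as data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .anthropometrics import categorize_bmi
from .errors import DataError, SchemaError
from .impute import impute_cart
from .schema import (
    BMI_CATEGORIES,
    EDUCATION,
    RAW_COLUMNS,
    REGIONS,
    RESIDENCE,
    WEALTH_QUINTILES,
    MALAWI_DISTRICTS,
    require_columns,
    vector_age_group3,
    vector_age_group5,
)

GPS_COLUMNS = ["cluster_id", "wave_year", "longitude", "latitude"]

_KNOWN_LABELS = {
    "residence": set(RESIDENCE),
    "region": set(REGIONS),
    "education": set(EDUCATION),
    "wealth_quintile": set(WEALTH_QUINTILES),
}

_ALL_DISTRICTS = {d for ds in MALAWI_DISTRICTS.values() for d in ds}


@dataclass
class Dialect:
    """How a survey CSV's columns map onto the canonical schema."""

    column_map: dict[str, str] = field(default_factory=dict)  # file -> canonical
    bmi_scale: float = 1.0      # stored value = bmi * bmi_scale
    weight_scale: float = 1.0   # stored value = weight * weight_scale
    category_maps: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        raw = yaml.safe_load(open(path)) or {}
        return cls(
            column_map=raw.get("column_map", {}),
            bmi_scale=float(raw.get("bmi_scale", 1.0)),
            weight_scale=float(raw.get("weight_scale", 1.0)),
            category_maps=raw.get("category_maps", {}),
        )


#: DHS recode storage conventions.
DHS_DIALECT = Dialect(bmi_scale=100.0, weight_scale=1_000_000.0)

_INT_COLUMNS = ["wave_year", "cluster_id", "age_years", "ceb", "sons_dead",
                "daughters_dead"]
_FLOAT_COLUMNS = ["weight", "bmi"]
_TRUTHY = {"true": True, "1": True, "yes": True, "false": False, "0": False,
           "no": False, "1.0": True, "0.0": False}


def _coerce_numeric(table: pd.DataFrame, col: str, kind: str) -> pd.Series:
    raw = table[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +1 header, +1 1-based
        raise DataError(
            f"unparseable {kind} value(s) in column {col!r} at file line(s) "
            f"{lines[:10]}{'...' if len(lines) > 10 else ''}"
        )
    return out


def _coerce_pregnant(s: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        key = str(v).strip().lower()
        if key in _TRUTHY:
            return _TRUTHY[key]
        raise DataError(f"unparseable pregnancy flag {v!r}")

    return s.map(conv)


def read_survey(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read one wave's female table as a typed canonical DataFrame."""
    dialect = dialect or Dialect()
    table = pd.read_csv(path)
    table = table.rename(columns=dialect.column_map)
    require_columns(table, RAW_COLUMNS, str(path))
    table = table[RAW_COLUMNS].copy()
    for col, codes in dialect.category_maps.items():
        table[col] = table[col].map(lambda v: codes.get(v, v))
    for col in _INT_COLUMNS:
        table[col] = _coerce_numeric(table, col, "integer")
    for col in _FLOAT_COLUMNS:
        table[col] = _coerce_numeric(table, col, "numeric")
    table["bmi"] = table["bmi"] / dialect.bmi_scale
    table["weight"] = table["weight"] / dialect.weight_scale
    table["pregnant"] = _coerce_pregnant(table["pregnant"])
    for col, known in _KNOWN_LABELS.items():
        odd = set(table[col].dropna().unique()) - known
        if odd:
            warnings.warn(f"unknown {col} code(s) {sorted(map(str, odd))} left as-is")
    odd_districts = set(table["district"].dropna().unique()) - _ALL_DISTRICTS
    if odd_districts:
        warnings.warn(
            f"district label(s) not in the packaged 28-district list: "
            f"{sorted(map(str, odd_districts))[:5]}"
        )
    return table


def write_survey(table: pd.DataFrame, path) -> None:
    """Write a table in the canonical plain-unit CSV dialect."""
    table.to_csv(path, index=False)


def read_gps(path) -> pd.DataFrame:
    gps = pd.read_csv(path)
    require_columns(gps, GPS_COLUMNS, str(path))
    return gps


def join_gps(table: pd.DataFrame, gps: pd.DataFrame) -> pd.DataFrame:
    """Left-join cluster coordinates on (cluster_id, wave_year); females in
    clusters without GPS are retained with missing coordinates."""
    require_columns(gps, GPS_COLUMNS, "gps table")
    if gps.duplicated(["cluster_id", "wave_year"]).any():
        raise DataError("gps table has duplicate (cluster_id, wave_year) keys")
    out = table.merge(
        gps[["cluster_id", "wave_year", "longitude", "latitude"]],
        on=["cluster_id", "wave_year"],
        how="left",
    )
    unmatched = int(out["longitude"].isna().sum())
    if unmatched:
        warnings.warn(f"{unmatched} female record(s) have no matching GPS cluster")
    return out


def exclude_pregnant(table: pd.DataFrame) -> pd.DataFrame:
    """Drop females pregnant at interview (their BMI reflects gestation,
    not habitual body mass). Missing flags are retained with a warning."""
    require_columns(table, ["pregnant"], "exclude_pregnant")
    flag = table["pregnant"]
    if flag.isna().any():
        warnings.warn(
            f"{int(flag.isna().sum())} missing pregnancy flag(s); "
            "those rows are retained (impute first to resolve them)"
        )
    keep = ~flag.fillna(False).astype(bool)
    return table[keep].reset_index(drop=True)


def derive_fields(table: pd.DataFrame) -> pd.DataFrame:
    """Populate children_dead, both age groupings and the BMI category.

    Rows with age outside 15-49 or with children dead exceeding children
    ever born are rejected (dropped with a warning), never silently fixed.
    """
    require_columns(table, ["age_years", "sons_dead", "daughters_dead", "ceb", "bmi"],
                    "derive_fields")
    out = table.copy()
    bad_age = (out["age_years"] < 15) | (out["age_years"] > 49)
    if bad_age.any():
        warnings.warn(f"rejected {int(bad_age.sum())} row(s) with age outside 15-49")
        out = out[~bad_age]
    out = out.copy()
    out["children_dead"] = out["sons_dead"] + out["daughters_dead"]
    bad_tally = out["children_dead"] > out["ceb"]
    if bad_tally.any():
        warnings.warn(
            f"rejected {int(bad_tally.sum())} row(s) with children dead "
            "exceeding children ever born"
        )
        out = out[~bad_tally].copy()
    out["age_group3"] = vector_age_group3(out["age_years"])
    out["age_group5"] = vector_age_group5(out["age_years"])
    cat = pd.Series(pd.NA, index=out.index, dtype=object)
    ok = out["bmi"].notna()
    if ok.any():
        cat.loc[ok] = np.asarray(categorize_bmi(out.loc[ok, "bmi"]))
    out["bmi_category"] = cat
    return out.reset_index(drop=True)


def merge_surveys(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate harmonized waves after checking schema equality."""
    if not tables:
        raise SchemaError("no survey tables to merge")
    ref = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != ref:
            diff = set(ref).symmetric_difference(t.columns)
            raise SchemaError(f"wave schemas differ on column(s): {sorted(diff)}")
    return pd.concat(tables, ignore_index=True)


DEFAULT_IMPUTE_VARS = ["bmi", "education", "wealth_quintile", "residence", "pregnant"]


def harmonize(
    waves: list[pd.DataFrame],
    gps: pd.DataFrame | None = None,
    impute_vars: list[str] | None = None,
    seed: int = 0,
    sweeps: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Run the fixed per-wave pipeline and merge; returns (table, log).

    The log maps each wave to its row count after every stage -- the data
    equivalent of a sample-selection flowchart.
    """
    log: dict = {"stage_order": ["read", "join_gps", "impute", "derive",
                                 "exclude_pregnant"], "waves": {}}
    processed = []
    for wave_table in waves:
        year = int(wave_table["wave_year"].iloc[0])
        counts = {"read": len(wave_table)}
        t = wave_table
        if gps is not None:
            t = join_gps(t, gps)
        counts["join_gps"] = len(t)
        vars_present = [
            v for v in (impute_vars if impute_vars is not None else DEFAULT_IMPUTE_VARS)
            if v in t.columns and t[v].isna().any()
        ]
        if vars_present:
            t = impute_cart(t, vars_present, seed=seed, sweeps=sweeps)
        counts["impute"] = len(t)
        counts["imputed_variables"] = vars_present
        t = derive_fields(t)
        counts["derive"] = len(t)
        t = exclude_pregnant(t)
        counts["exclude_pregnant"] = len(t)
        processed.append(t)
        log["waves"][year] = counts
    merged = merge_surveys(processed)
    log["merged_rows"] = len(merged)
    return merged, log
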