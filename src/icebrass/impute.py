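"""Chained single imputation with classification and regression trees.

Each incomplete variable is filled by fitting a decision tree (classifier
for categorical, regressor for numeric) on the currently-complete
predictors, then drawing each missing cell uniformly (seeded) from the
*donor* values of observed rows falling in the same leaf. Leaf-donor
sampling keeps every imputed value inside the observed support and
preserves within-leaf variability, unlike mean/mode prediction. Variables
are visited in increasing order of missingness, over a small number of
sweeps, so later variables are imputed conditional on earlier fills.

Point estimates only: a single completed table is returned, with no
between-imputation variance (the analyses downstream report point
surfaces).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .errors import DataError

#: Default predictor pool (intersected with available columns).
DEFAULT_PREDICTORS = [
    "age_years", "wave_year", "residence", "region", "district",
    "education", "wealth_quintile", "bmi", "pregnant", "ceb",
]

_NUMERIC_VARS = {"bmi", "age_years", "ceb"}


def _is_numeric(table: pd.DataFrame, var: str) -> bool:
    if var in _NUMERIC_VARS:
        return True
    return pd.api.types.is_numeric_dtype(table[var]) and not (
        pd.api.types.is_bool_dtype(table[var])
        or set(table[var].dropna().unique()) <= {0, 1, True, False}
    )


def _encode(frame: pd.DataFrame) -> np.ndarray:
    cols = []
    for c in frame.columns:
        s = frame[c]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            cols.append(s.to_numpy(dtype=float))
        else:
            cols.append(pd.Categorical(s.astype(object)).codes.astype(float))
    return np.column_stack(cols)


def impute_cart(
    table: pd.DataFrame,
    variables: list[str],
    seed: int = 0,
    sweeps: int = 3,
    min_leaf: int = 5,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Return a copy of ``table`` with the listed variables completed.

    Observed values are never altered; every imputed value is a donor
    value observed somewhere in the same variable.
    """
    for var in variables:
        if var not in table.columns:
            raise DataError(f"cannot impute unknown variable {var!r}")
        if table[var].notna().sum() == 0:
            raise DataError(f"variable {var!r} is entirely missing; nothing to learn from")

    out = table.copy()
    miss = {v: out[v].isna().to_numpy() for v in variables}
    if not any(m.any() for m in miss.values()):
        return out

    rng = np.random.default_rng(seed)
    order = sorted((v for v in variables if miss[v].any()),
                   key=lambda v: miss[v].sum())
    pool = predictors or DEFAULT_PREDICTORS
    pred_cols = [c for c in pool if c in out.columns]
    pred_cols += [v for v in variables if v not in pred_cols]

    # initialize missing cells with marginal draws so chained trees always
    # see complete predictors
    for v in order:
        donors = out.loc[~miss[v], v].to_numpy()
        idx = rng.integers(0, len(donors), size=int(miss[v].sum()))
        out.loc[miss[v], v] = donors[idx]

    for _ in range(sweeps):
        for v in order:
            m = miss[v]
            feats = [c for c in pred_cols if c != v]
            X = _encode(out[feats])
            y = out[v].to_numpy()
            if _is_numeric(table, v):
                tree = DecisionTreeRegressor(
                    min_samples_leaf=min_leaf,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                tree.fit(X[~m], y[~m].astype(float))
            else:
                tree = DecisionTreeClassifier(
                    min_samples_leaf=min_leaf,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                tree.fit(X[~m], y[~m].astype(str))
            leaves = tree.apply(X)
            # donor pools: observed row positions per leaf of the fitted tree
            obs_pos = np.flatnonzero(~m)
            pools: dict[int, np.ndarray] = {}
            for leaf in np.unique(leaves[obs_pos]):
                pools[leaf] = obs_pos[leaves[obs_pos] == leaf]
            fill_pos = np.flatnonzero(m)
            draws = np.empty(len(fill_pos), dtype=object)
            for j, pos in enumerate(fill_pos):
                pool_pos = pools[leaves[pos]]
                draws[j] = y[pool_pos[rng.integers(len(pool_pos))]]
            col = out[v].copy()
            col.iloc[fill_pos] = (
                draws.astype(float) if _is_numeric(table, v) else draws
            )
            out[v] = col

    # restore clean dtypes where the masking had upcast to object
    for v in variables:
        if _is_numeric(table, v):
            out[v] = pd.to_numeric(out[v])
        elif set(out[v].dropna().unique()) <= {True, False}:
            out[v] = out[v].astype(bool)
    return out
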