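"""Packaged reference constants for Brass-type indirect estimation.

Two assets live under ``icebrass/reference/``:

``trussell_west_coefficients.csv``
    The Trussell regression coefficients (a_i, b_i, c_i) for converting the
    proportion of children dead d(i) among mothers in five-year age group i
    into a probability of dying q(x), Coale-Demeny *West* family, as
    published in the UN's Manual X (1983), Table 47. These are real
    published constants, transcribed verbatim.

``west_lx_levels_synthetic.csv``
    A *synthetic* West-style family of child-survival levels: l(x) for
    x in {1,2,3,5,10,15,20} at integer levels 1..24, for female and
    both-sexes schedules. The true Coale-Demeny West l(x)-by-level pages
    are not redistributable here, so this table is generated by
    :func:`build_synthetic_west_lx` -- a documented construction that
    reproduces the *structure* the method relies on (l(x) strictly
    decreasing in x within a level, strictly increasing in level at fixed
    x, higher level = higher survival) with demographically plausible
    magnitudes. Level numbers from this table are internally consistent
    but not comparable digit-for-digit with published West levels.

Both files are integrity-checked against SHA-256 checksums recorded in
``reference/_checksums.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ReferenceDataError
from .schema import AGE5_LABELS

#: Child ages x (exact years) tabulated per maternal five-year age group,
#: standard Brass correspondence: mothers 15-19 inform q(1), 20-24 -> q(2),
#: 25-29 -> q(3), 30-34 -> q(5), 35-39 -> q(10), 40-44 -> q(15),
#: 45-49 -> q(20).
CHILD_AGES = [1, 2, 3, 5, 10, 15, 20]
CHILD_AGE_FOR_GROUP = dict(zip(AGE5_LABELS, CHILD_AGES))

TRUSSELL_FILE = "trussell_west_coefficients.csv"
LX_FILE = "west_lx_levels_synthetic.csv"
CHECKSUM_FILE = "_checksums.json"

MIN_LEVEL, MAX_LEVEL = 1, 24


def _reference_path(name: str):
    return resources.files("icebrass") / "reference" / name


def _read_checked(name: str, verify: bool = True) -> pd.DataFrame:
    path = _reference_path(name)
    try:
        raw = path.read_bytes()
    except FileNotFoundError as exc:
        raise ReferenceDataError(f"reference file {name} is missing") from exc
    if verify:
        recorded = json.loads(_reference_path(CHECKSUM_FILE).read_text())
        digest = hashlib.sha256(raw).hexdigest()
        if recorded.get(name) != digest:
            raise ReferenceDataError(
                f"reference file {name} failed its checksum "
                f"(expected {recorded.get(name)}, got {digest})"
            )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def verify_reference_data() -> dict[str, bool]:
    """Checksum every packaged reference file; return {file: ok}."""
    recorded = json.loads(_reference_path(CHECKSUM_FILE).read_text())
    out = {}
    for name, expected in recorded.items():
        try:
            digest = hashlib.sha256(_reference_path(name).read_bytes()).hexdigest()
            out[name] = digest == expected
        except FileNotFoundError:
            out[name] = False
    return out


# ---------------------------------------------------------------------------
# Trussell multiplier coefficients


@dataclass(frozen=True)
class TrussellCoefficients:
    """West-family Trussell coefficients, one (a, b, c) row per maternal
    age group i = 1..7, for k_i = a_i + b_i * (P1/P2) + c_i * (P2/P3)."""

    frame: pd.DataFrame  # columns: i, age_group, a, b, c
    model_family: str = "West"
    variant: str = "Trussell"

    def row(self, i: int) -> pd.Series:
        return self.frame.set_index("i").loc[i]


def load_trussell_coefficients(verify: bool = True) -> TrussellCoefficients:
    frame = _read_checked(TRUSSELL_FILE, verify=verify)
    expected = {"i", "age_group", "a", "b", "c"}
    if set(frame.columns) != expected or len(frame) != 7:
        raise ReferenceDataError(
            f"{TRUSSELL_FILE} must have 7 rows with columns {sorted(expected)}"
        )
    return TrussellCoefficients(frame=frame)


# ---------------------------------------------------------------------------
# Model life table (levels of child survival)


class ModelLifeTable:
    """Child survival l(x) tabulated by mortality level.

    Levels follow the Coale-Demeny convention: a *higher* level means
    *higher* survival (lower mortality). ``l(x)`` is the proportion of
    children surviving to exact age x, with l(0) = 1.
    """

    def __init__(self, frame: pd.DataFrame, sex: str):
        sub = frame[frame["sex"] == sex]
        if sub.empty:
            raise ReferenceDataError(f"no l(x) rows for sex={sex!r}")
        self.sex = sex
        # grid[level, x]
        self.grid = sub.pivot(index="level", columns="x", values="lx").sort_index()
        self.levels = self.grid.index.to_numpy()
        self.ages = np.array(sorted(self.grid.columns))
        self._validate()

    def _validate(self) -> None:
        g = self.grid[self.ages].to_numpy()
        if not (np.diff(g, axis=1) < 0).all():
            raise ReferenceDataError("l(x) must strictly decrease in x within a level")
        if not (np.diff(g, axis=0) > 0).all():
            raise ReferenceDataError("l(x) must strictly increase in level at fixed x")

    def lx(self, level: float, x: int) -> float:
        """l(x) at a possibly fractional level (linear between levels)."""
        if x not in self.grid.columns:
            raise ValueError(f"child age x={x} not tabulated (have {list(self.ages)})")
        if not MIN_LEVEL <= level <= MAX_LEVEL:
            raise ValueError(f"level {level} outside [{MIN_LEVEL}, {MAX_LEVEL}]")
        lo = int(np.floor(level))
        hi = min(lo + 1, MAX_LEVEL)
        frac = level - lo
        col = self.grid[x]
        return float(col.loc[lo] + frac * (col.loc[hi] - col.loc[lo]))

    # alias used in the indirect-estimation chain
    level_to_lx = lx

    def mortality_level(self, lx: float, x: int) -> tuple[float, bool]:
        """Interpolated mortality level matching an observed l(x).

        Returns ``(level, clamped)``: the fractional level a + (lx - l_a) /
        (l_b - l_a) between the bracketing integer levels a < b, or the
        nearest bound (1 or 24) with ``clamped=True`` if lx falls outside
        the tabulated range.
        """
        if x not in self.grid.columns:
            raise ValueError(f"child age x={x} not tabulated (have {list(self.ages)})")
        if not 0.0 < lx <= 1.0:
            raise ValueError(f"l(x) must be in (0, 1], got {lx}")
        col = self.grid[x].to_numpy()
        if lx <= col[0]:
            return float(MIN_LEVEL), lx < col[0]
        if lx >= col[-1]:
            return float(MAX_LEVEL), lx > col[-1]
        # first index with tabulated value >= lx; bracket is [a, a+1]
        j = int(np.searchsorted(col, lx))
        a = self.levels[j - 1]
        frac = (lx - col[j - 1]) / (col[j] - col[j - 1])
        return float(a + frac), False


def load_model_lifetable(sex: str = "both", verify: bool = True) -> ModelLifeTable:
    """Load the packaged West-style level table ('both' or 'female')."""
    frame = _read_checked(LX_FILE, verify=verify)
    return ModelLifeTable(frame, sex=sex)


# ---------------------------------------------------------------------------
# Synthetic West-style table construction

#: q(5) anchors for the female schedule: (level, probability of dying by
#: age five). Level 1 ~ severe historical mortality, level 24 ~ low modern
#: mortality; the mid anchor keeps mid-table levels in the range typical of
#: high-mortality survey settings. Between anchors ln q(5) is linear in
#: level, so survival is strictly increasing in level.
_Q5_ANCHORS = [(1, 0.45), (13, 0.17), (24, 0.005)]

#: Cumulative-hazard ratios r(x) = H(x)/H(5): child mortality is
#: front-loaded ((x/5)^0.55 below age five) and accumulates slowly after
#: age five ((x/5)^0.30).
_HAZARD_EXPONENT_YOUNG = 0.55
_HAZARD_EXPONENT_OLD = 0.30

#: Both-sexes schedules carry a modestly higher hazard than female-only
#: (male excess child mortality).
_BOTH_SEXES_HAZARD_RATIO = 1.075


def _q5_female(level: np.ndarray) -> np.ndarray:
    pts = np.array(_Q5_ANCHORS, dtype=float)
    return np.exp(np.interp(level, pts[:, 0], np.log(pts[:, 1])))


def _hazard_ratio(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    young = (x / 5.0) ** _HAZARD_EXPONENT_YOUNG
    old = (x / 5.0) ** _HAZARD_EXPONENT_OLD
    return np.where(x <= 5, young, old)


def build_synthetic_west_lx() -> pd.DataFrame:
    """Construct the synthetic West-style l(x) level table.

    The packaged CSV is exactly the output of this function; a test pins
    that equality so the asset can always be audited against its
    generator.
    """
    levels = np.arange(MIN_LEVEL, MAX_LEVEL + 1)
    rows = []
    r = _hazard_ratio(np.array(CHILD_AGES))
    q5_f = _q5_female(levels)
    for sex, ratio in [("female", 1.0), ("both", _BOTH_SEXES_HAZARD_RATIO)]:
        h5 = -np.log1p(-q5_f) * ratio
        for lev, h in zip(levels, h5):
            lx = np.exp(-h * r)
            for x, v in zip(CHILD_AGES, lx):
                rows.append({"sex": sex, "level": int(lev), "x": int(x),
                             "lx": round(float(v), 5)})
    return pd.DataFrame(rows, columns=["sex", "level", "x", "lx"])
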