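"""DHS-like synthetic survey generator with known ground truth.

Emulates the structure of a multi-wave female recode: four unequal survey
waves, women aged 15-49 sampled in clusters nested in districts, BMI
shifting upward with wealth, urban residence, education and later waves,
parity rising with maternal age, and children-dead counts thinned from
parity at a child-mortality probability implied by a configurable
"true" mortality level of the packaged model life table. Because the
generating level is known exactly, the whole indirect-estimation chain
can be tested for parameter recovery without any external microdata.

What this deliberately does not emulate: DHS multistage selection
probabilities and design effects (weights here are i.i.d. lognormal noise
normalized to mean one), birth-timing within a mother's reproductive
span, and any missing-not-at-random mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .lifetables import CHILD_AGE_FOR_GROUP, load_model_lifetable
from .schema import (
    AGE5_LABELS,
    BMI_CATEGORIES,
    EDUCATION,
    MALAWI_DISTRICTS,
    DISTRICT_TO_REGION,
    WEALTH_QUINTILES,
    vector_age_group5,
)

#: Latitude bands (degrees N) per region, inside a Malawi-like bounding box.
_REGION_LAT = {"North": (-11.5, -9.2), "Central": (-14.5, -11.5),
               "South": (-17.8, -14.5)}
_LON_RANGE = (32.8, 35.8)

_ALL_DISTRICTS = [d for r in ("North", "Central", "South") for d in MALAWI_DISTRICTS[r]]


def _default_n_per_wave() -> dict[int, int]:
    # analysed wave sizes of the study design this emulates
    return {2000: 11663, 2004: 10249, 2010: 20858, 2015: 22729}


def _default_bmi_means() -> dict[str, float]:
    return {
        "base": 21.9,          # rural, poorest, no education, 15-24, first wave
        "wave_step": 0.55,     # secular upward drift per wave
        "urban": 1.3,
        "wealth_step": 0.35,   # per quintile step poorest -> richest
        "education_step": 0.25,
        "age_25_34": 0.5,
        "age_35_49": 0.9,
        "region_North": -0.5,  # lower BMI in the north, higher central/south
        "region_Central": 0.2,
        "region_South": 0.25,
    }


def _default_fertility() -> dict[str, float]:
    return {"15-19": 0.3, "20-24": 1.5, "25-29": 2.9, "30-34": 4.2,
            "35-39": 5.3, "40-44": 6.1, "45-49": 6.5}


def _default_urban_share() -> dict[int, float]:
    return {2000: 0.095, 2004: 0.143, 2010: 0.138, 2015: 0.217}


def _default_education_probs() -> dict[int, list[float]]:
    return {
        2000: [0.782, 0.173, 0.043, 0.002],
        2004: [0.753, 0.193, 0.048, 0.006],
        2010: [0.714, 0.218, 0.053, 0.015],
        2015: [0.639, 0.262, 0.071, 0.028],
    }


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic survey.

    ``bmi_means`` is a mapping of additive effects (kg/m^2) on the mean of
    the truncated-normal BMI draw rather than a flat stratum->mean table,
    because the emulated gradients (wealth, residence, education, age,
    wave, region) are crossed. ``true_mortality_level`` indexes the
    packaged West-style life-table family (1..24, higher = higher child
    survival); children dead are Binomial(parity, q_true) with q_true the
    level's probability of dying by the child age x mapped to the
    mother's five-year age group. ``bmi_mortality_rr`` multiplies q_true
    per maternal BMI category (all 1.0 by default, i.e. no BMI effect on
    child mortality).
    """

    n_per_wave: dict[int, int] = field(default_factory=_default_n_per_wave)
    n_districts: int = 28
    n_clusters: int = 250
    bmi_means: dict[str, float] = field(default_factory=_default_bmi_means)
    bmi_sd: float = 3.2
    pregnancy_rate: float = 0.07
    fertility_schedule: dict[str, float] = field(default_factory=_default_fertility)
    true_mortality_level: float = 13.0
    bmi_mortality_rr: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in BMI_CATEGORIES}
    )
    missing_rates: dict[str, float] = field(default_factory=dict)
    urban_share: dict[int, float] = field(default_factory=_default_urban_share)
    education_probs: dict[int, list[float]] = field(
        default_factory=_default_education_probs
    )
    wealth_probs: list[float] = field(default_factory=lambda: [0.2] * 5)
    weight_sigma: float = 0.3
    lifetable_sex: str = "both"
    max_parity: int = 17
    seed: int = 0

    @property
    def wave_years(self) -> list[int]:
        return sorted(self.n_per_wave)

    def validate(self) -> None:
        for year, n in self.n_per_wave.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ConfigurationError(f"n_per_wave[{year}] must be a positive integer")
        if not 1 <= self.n_districts <= len(_ALL_DISTRICTS):
            raise ConfigurationError(
                f"n_districts must be in [1, {len(_ALL_DISTRICTS)}]"
            )
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if not 0 <= self.pregnancy_rate <= 1:
            raise ConfigurationError("pregnancy_rate must be in [0, 1]")
        if not 1 <= self.true_mortality_level <= 24:
            raise ConfigurationError("true_mortality_level must be in [1, 24]")
        if self.bmi_sd <= 0:
            raise ConfigurationError("bmi_sd must be positive")
        sched = [self.fertility_schedule.get(g) for g in AGE5_LABELS]
        if any(s is None or s < 0 for s in sched):
            raise ConfigurationError(
                "fertility_schedule must cover all seven age groups with >= 0 values"
            )
        if any(b > a for a, b in zip(sched[1:], sched)):
            raise ConfigurationError("fertility_schedule must be non-decreasing in age")
        for var, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"missing_rates[{var}] must be in [0, 1]")
        for cat, rr in self.bmi_mortality_rr.items():
            if rr <= 0:
                raise ConfigurationError(f"bmi_mortality_rr[{cat}] must be positive")
        for year in self.wave_years:
            share = self.urban_share.get(year)
            if share is None or not 0 <= share <= 1:
                raise ConfigurationError(f"urban_share[{year}] must be in [0, 1]")
            probs = self.education_probs.get(year)
            if probs is None or len(probs) != len(EDUCATION) or min(probs) < 0:
                raise ConfigurationError(
                    f"education_probs[{year}] must give {len(EDUCATION)} non-negative values"
                )

    def districts(self) -> list[str]:
        return _ALL_DISTRICTS[: self.n_districts]

    def to_dict(self) -> dict:
        return asdict(self)


def _wave_rng(config: SyntheticConfig, wave_year: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, wave_year, stream]))


def _cluster_districts(config: SyntheticConfig, wave_year: int) -> np.ndarray:
    """District label per cluster id 1..n_clusters, shared by the
    population and GPS generators so their join is closed."""
    rng = _wave_rng(config, wave_year, 101)
    return rng.choice(config.districts(), size=config.n_clusters)


def ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """The exact child-mortality probabilities used in generation, per
    maternal age group (before any BMI relative risk): the recovery
    target downstream estimates are compared against."""
    lt = load_model_lifetable(config.lifetable_sex)
    rows = []
    for g in AGE5_LABELS:
        x = CHILD_AGE_FOR_GROUP[g]
        l_true = lt.lx(config.true_mortality_level, x)
        rows.append({"age_group5": g, "x": x, "l_true": l_true,
                     "q_true": 1.0 - l_true, "level": config.true_mortality_level})
    return pd.DataFrame(rows)


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """One raw survey row per female across all waves (see module docstring
    for the generative model). Deterministic given config (incl. seed)."""
    config.validate()
    lt = load_model_lifetable(config.lifetable_sex)
    q_by_group = {
        g: 1.0 - lt.lx(config.true_mortality_level, CHILD_AGE_FOR_GROUP[g])
        for g in AGE5_LABELS
    }
    eff = config.bmi_means
    frames = []
    for wave in config.wave_years:
        n = config.n_per_wave[wave]
        widx = config.wave_years.index(wave)
        rng = _wave_rng(config, wave, 1)
        cluster_district = _cluster_districts(config, wave)

        age = rng.integers(15, 50, size=n)
        age5 = vector_age_group5(pd.Series(age))
        cluster = rng.integers(1, config.n_clusters + 1, size=n)
        district = cluster_district[cluster - 1]
        region = pd.Series(district).map(DISTRICT_TO_REGION).to_numpy()

        # residence decided at cluster level (DHS clusters are urban or rural)
        urban_cluster = rng.random(config.n_clusters) < config.urban_share[wave]
        residence = np.where(urban_cluster[cluster - 1], "urban", "rural")

        eprobs = np.asarray(config.education_probs[wave], float)
        education = rng.choice(EDUCATION, size=n, p=eprobs / eprobs.sum())
        wprobs = np.asarray(config.wealth_probs, float)
        wealth = rng.choice(WEALTH_QUINTILES, size=n, p=wprobs / wprobs.sum())

        mean_bmi = (
            eff["base"]
            + eff["wave_step"] * widx
            + eff["urban"] * (residence == "urban")
            + eff["wealth_step"] * pd.Series(wealth).map(
                {q: i for i, q in enumerate(WEALTH_QUINTILES)}
            ).to_numpy()
            + eff["education_step"] * pd.Series(education).map(
                {e: i for i, e in enumerate(EDUCATION)}
            ).to_numpy()
            + eff["age_25_34"] * ((age >= 25) & (age <= 34))
            + eff["age_35_49"] * (age >= 35)
            + pd.Series(region).map(
                {r: eff.get(f"region_{r}", 0.0) for r in _REGION_LAT}
            ).to_numpy()
        )
        bmi = np.clip(rng.normal(mean_bmi, config.bmi_sd), 12.0, 60.0)
        pregnant = rng.random(n) < config.pregnancy_rate

        parity_mean = age5.map(config.fertility_schedule).to_numpy(float)
        ceb = np.minimum(rng.poisson(parity_mean), config.max_parity)

        bmi_cat = np.select(
            [bmi < 18.5, bmi < 25.0, bmi < 30.0],
            BMI_CATEGORIES[:3], default=BMI_CATEGORIES[3],
        )
        q = age5.map(q_by_group).to_numpy(float) * pd.Series(bmi_cat).map(
            config.bmi_mortality_rr
        ).to_numpy(float)
        q = np.clip(q, 0.0, 0.99)
        children_dead = rng.binomial(ceb, q)
        sons_dead = rng.binomial(children_dead, 0.51)

        weight = rng.lognormal(0.0, config.weight_sigma, size=n)
        weight = weight / weight.mean()

        frames.append(
            pd.DataFrame(
                {
                    "wave_year": wave,
                    "cluster_id": cluster,
                    "weight": weight,
                    "age_years": age,
                    "residence": residence,
                    "region": region,
                    "district": district,
                    "education": education,
                    "wealth_quintile": wealth,
                    "pregnant": pregnant,
                    "bmi": np.round(bmi, 2),
                    "ceb": ceb,
                    "sons_dead": sons_dead,
                    "daughters_dead": children_dead - sons_dead,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["ground_truth"] = ground_truth(config).to_dict("records")
    return out


def inject_missingness(
    table: pd.DataFrame, missing_rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Mask listed variables completely at random at the given rates.

    Fertility/mortality tallies, survey weights and design keys are never
    masked (the indirect method consumes them raw).
    """
    protected = {"ceb", "sons_dead", "daughters_dead", "children_dead",
                 "weight", "wave_year", "cluster_id"}
    out = table.copy()
    rng = np.random.default_rng(seed)
    for var, rate in missing_rates.items():
        if var not in table.columns:
            raise ConfigurationError(f"missing rate given for unknown variable {var!r}")
        if var in protected:
            raise ConfigurationError(f"variable {var!r} may not be masked")
        if not 0 <= rate <= 1:
            raise ConfigurationError(f"missing_rates[{var}] must be in [0, 1]")
        mask = rng.random(len(out)) < rate
        if out[var].dtype != object and not pd.api.types.is_float_dtype(out[var]):
            out[var] = out[var].astype(object)
        out.loc[mask, var] = np.nan
    return out


def generate_gps(config: SyntheticConfig) -> pd.DataFrame:
    """One GPS row per (cluster, wave): coordinates inside a Malawi-like
    bounding box, latitude banded by the cluster's district's region so
    maps look geographically coherent; district labels match the
    population table exactly."""
    config.validate()
    frames = []
    for wave in config.wave_years:
        rng = _wave_rng(config, wave, 202)
        district = _cluster_districts(config, wave)
        region = pd.Series(district).map(DISTRICT_TO_REGION)
        lat_lo = region.map({r: b[0] for r, b in _REGION_LAT.items()}).to_numpy()
        lat_hi = region.map({r: b[1] for r, b in _REGION_LAT.items()}).to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "cluster_id": np.arange(1, config.n_clusters + 1),
                    "wave_year": wave,
                    "longitude": rng.uniform(*_LON_RANGE, size=config.n_clusters),
                    "latitude": rng.uniform(lat_lo, lat_hi),
                    "district": district,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
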