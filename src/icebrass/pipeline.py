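"""Configuration-driven end-to-end runner.

``run`` takes a :class:`RunConfig` pointing either at user CSVs or at a
synthetic-data configuration, executes the fixed pipeline (harmonize ->
descriptives -> BMI trends -> ICE by stratum and by area -> indirect
mortality grid) and writes a bundle of tidy CSVs plus a JSON manifest
recording the seed, a hash of the configuration and the row count at every
selection stage. Runs with equal config hashes produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import anthropometrics, lifetables, mortality, survey
from .errors import ConfigurationError
from .ice import ice_by, ice_by_area, to_geojson
from .synthetic import SyntheticConfig, generate_gps, generate_population, inject_missingness

ARTIFACTS = [
    "harmonized.csv",
    "descriptives.csv",
    "mean_bmi_trends.csv",
    "ice_strata.csv",
    "ice_areas.csv",
    "mortality_levels.csv",
]


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of ``survey_paths`` or
    ``synthetic`` must be given."""

    survey_paths: list[str] | None = None
    gps_path: str | None = None
    dialect_path: str | None = None
    synthetic: SyntheticConfig | None = None
    weighted: bool = True
    ice_include_overweight_high: bool = False
    ice_bootstrap: bool = False
    ice_area_level: str = "district"
    lifetable_sex: str = "both"
    impute_vars: list[str] | None = None
    mean_bmi_stratifiers: list[str] = field(
        default_factory=lambda: ["age_group3", "residence", "education",
                                 "wealth_quintile", "region"]
    )
    ice_stratifiers: list[str] = field(
        default_factory=lambda: ["age_group3", "residence", "education",
                                 "wealth_quintile"]
    )
    seed: int = 0
    out_dir: str = "icebrass_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.survey_paths is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of survey_paths / synthetic must be configured"
            )
        if self.ice_area_level not in ("district", "region"):
            raise ConfigurationError("ice_area_level must be 'district' or 'region'")
        if self.lifetable_sex not in ("both", "female"):
            raise ConfigurationError("lifetable_sex must be 'both' or 'female'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            syn = {**syn}
            for key in ("n_per_wave", "urban_share", "education_probs"):
                if key in syn:
                    syn[key] = {int(k): v for k, v in syn[key].items()}
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def config_hash(self) -> str:
        payload = dict(self.__dict__)
        if self.synthetic is not None:
            payload["synthetic"] = self.synthetic.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate(config: RunConfig) -> list[str]:
    """Dry-run checks without computing; returns a list of failures."""
    failures: list[str] = []
    try:
        config.validate()
    except ConfigurationError as exc:
        failures.append(str(exc))
    for name, ok in lifetables.verify_reference_data().items():
        if not ok:
            failures.append(f"reference data {name} failed its checksum")
    if config.synthetic is not None:
        try:
            config.synthetic.validate()
        except ConfigurationError as exc:
            failures.append(str(exc))
    if config.dialect_path is not None:
        try:
            survey.Dialect.from_yaml(config.dialect_path)
        except Exception as exc:  # bad YAML or bad field
            failures.append(f"dialect file {config.dialect_path}: {exc}")
    for p in config.survey_paths or []:
        if not Path(p).exists():
            failures.append(f"survey file not found: {p}")
    if config.gps_path and not Path(config.gps_path).exists():
        failures.append(f"gps file not found: {config.gps_path}")
    return failures


def _load_inputs(config: RunConfig) -> tuple[list[pd.DataFrame], pd.DataFrame | None]:
    if config.synthetic is not None:
        syn = config.synthetic
        pop = generate_population(syn)
        if syn.missing_rates:
            pop = inject_missingness(pop, syn.missing_rates, seed=syn.seed + 1)
        gps = generate_gps(syn)
        waves = [g.reset_index(drop=True) for _, g in pop.groupby("wave_year")]
        return waves, gps
    dialect = (survey.Dialect.from_yaml(config.dialect_path)
               if config.dialect_path else None)
    waves = [survey.read_survey(p, dialect) for p in config.survey_paths]
    gps = survey.read_gps(config.gps_path) if config.gps_path else None
    return waves, gps


def _write_csv(frame: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, index=False)


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage failure removes partially-written outputs and re-raises.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()} seed={config.seed}"
    written: list[Path] = []
    try:
        waves, gps = _load_inputs(config)
        table, stage_log = survey.harmonize(
            waves, gps=gps, impute_vars=config.impute_vars, seed=config.seed
        )

        def emit(frame: pd.DataFrame, name: str) -> None:
            path = out / name
            _write_csv(frame, path, stamp)
            written.append(path)

        emit(table, "harmonized.csv")
        emit(anthropometrics.descriptive_table(table, weighted=config.weighted),
             "descriptives.csv")
        trends = pd.concat(
            [
                anthropometrics.mean_bmi_by(table, s, weighted=config.weighted)
                .rename(columns={s: "category"})
                .assign(stratifier=s)
                for s in config.mean_bmi_stratifiers
            ],
            ignore_index=True,
        )
        emit(trends, "mean_bmi_trends.csv")
        strata_ice = pd.concat(
            [
                ice_by(
                    table, s, weighted=config.weighted,
                    include_overweight_high=config.ice_include_overweight_high,
                ).rename(columns={s: "category"}).assign(stratifier=s)
                for s in config.ice_stratifiers
            ],
            ignore_index=True,
        )
        emit(strata_ice, "ice_strata.csv")
        area_ice = ice_by_area(
            table, area_level=config.ice_area_level, weighted=config.weighted,
            include_overweight_high=config.ice_include_overweight_high,
        )
        emit(area_ice, "ice_areas.csv")
        geo = to_geojson(area_ice, area_level=config.ice_area_level)
        geo["config_hash"], geo["seed"] = config.config_hash(), config.seed
        geo_path = out / "ice_areas.geojson"
        geo_path.write_text(json.dumps(geo))
        written.append(geo_path)

        lifetable = lifetables.load_model_lifetable(config.lifetable_sex)
        grid = mortality.mortality_by_bmi_group(
            table, weighted=config.weighted, lifetable=lifetable
        )
        emit(grid, "mortality_levels.csv")

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_log": stage_log,
            "artifacts": [p.name for p in written] + ["manifest.json"],
            "rows": {"harmonized": len(table)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (out / "manifest.json").unlink(missing_ok=True)
        raise
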