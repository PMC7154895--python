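"""YAML configuration: packaged defaults, override merging, validation.

The packaged defaults carry the published demographic and control parameter
tables for the susceptible and glyphosate-resistant populations, the
emergence-model constants, the default cohort schedule, and the synthetic
climatology. A user config (YAML, nested keys) overrides any subset;
unknown keys are rejected by name. CLI flags override the config, which
overrides the defaults.
"""

from __future__ import annotations

import copy

import yaml

from .climate import ClimatologyConfig, ScenarioConfig
from .demography import EXTINCTION_FLOOR, PopulationParams
from .emergence import CohortSchedule, EmergenceModel
from .management import M4_VARIANTS, ControlRates, get_strategy
from .stochastics import FecundityParam, RateParam

__all__ = ["DEFAULTS", "load_config", "build_simulation_config"]


def _rate_entry(p: RateParam) -> dict:
    return {"mean": p.mean, "sd": p.sd, "stochastic": p.stochastic}


def _population_entry(pop: PopulationParams) -> dict:
    return {
        "sm": _rate_entry(pop.sm),
        "e": _rate_entry(pop.e),
        "sdls1": _rate_entry(pop.sdls[0]),
        "sdls2": _rate_entry(pop.sdls[1]),
        "sdls3": _rate_entry(pop.sdls[2]),
        "fr1": _rate_entry(pop.fr[0]),
        "fr2": _rate_entry(pop.fr[1]),
        "fr3": _rate_entry(pop.fr[2]),
        "f": {"mean": pop.f.mean, "sd": pop.f.sd},
        "b": _rate_entry(pop.b),
        "lp": _rate_entry(pop.lp),
        "sl": _rate_entry(pop.sl),
    }


def _defaults() -> dict:
    ctrl = ControlRates()
    return {
        "gompertz": {"k": 0.0151, "tt0": 444.20},
        "tbase": 1.9,
        "soil": {"slope": 0.84, "intercept": 3.81},
        "count_start": "03-10",
        "cohorts": {"boundaries": ["03-31", "04-30", "06-30"], "normalize": True},
        "climate": {
            "annual_mean": 13.5,
            "annual_amplitude": 5.5,
            "warmest_day_of_year": 15,
            "daily_noise_sd": 2.0,
        },
        "scenario": {"delta_T": {"1": 0.0, "2": 2.5}},
        "population": {
            "susceptible": _population_entry(PopulationParams.susceptible()),
            "resistant": _population_entry(PopulationParams.resistant()),
        },
        "control": {
            "rc_post_early": _rate_entry(ctrl.rc_post_early),
            "rc_post_late": _rate_entry(ctrl.rc_post_late),
            "cr": {key: _rate_entry(p) for key, p in ctrl.cr.items()},
        },
        "sim": {
            "years": 10,
            "replicates": 100,
            "initial_seed_bank": 2000.0,
            "start_year": 2001,
        },
        "model": {
            "rc_applies": "both",
            "m4_variant": "table2",
            "extinction_floor": EXTINCTION_FLOOR,
        },
    }


DEFAULTS = _defaults()


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ValueError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a full configuration: defaults <- YAML file <- overrides."""
    cfg = _defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"configuration file {path} must be a YAML mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    bounds = cfg["cohorts"]["boundaries"]
    if len(bounds) != 3:
        raise ValueError("cohorts.boundaries must list exactly three dates")
    if cfg["model"]["rc_applies"] not in ("both", "survival_only", "fecundity_only"):
        raise ValueError(f"model.rc_applies invalid: {cfg['model']['rc_applies']!r}")
    if cfg["model"]["m4_variant"] not in M4_VARIANTS:
        raise ValueError(f"model.m4_variant invalid: {cfg['model']['m4_variant']!r}")
    # constructing the domain objects enforces the remaining invariants
    build_emergence_model(cfg)
    build_schedule(cfg)
    build_climatology(cfg)
    build_population(cfg, "susceptible")
    build_population(cfg, "resistant")
    build_control(cfg)


def _rate(entry: dict, name: str) -> RateParam:
    try:
        return RateParam(
            float(entry["mean"]),
            float(entry.get("sd", 0.0)),
            bool(entry.get("stochastic", True)),
            name,
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed rate entry for {name!r}: {entry!r}") from exc


def build_emergence_model(cfg: dict) -> EmergenceModel:
    return EmergenceModel(
        gompertz_rate=float(cfg["gompertz"]["k"]),
        gompertz_location=float(cfg["gompertz"]["tt0"]),
        t_base=float(cfg["tbase"]),
        soil_slope=float(cfg["soil"]["slope"]),
        soil_intercept=float(cfg["soil"]["intercept"]),
        count_start=cfg["count_start"],
    )


def build_schedule(cfg: dict) -> CohortSchedule:
    return CohortSchedule(
        boundary_dates=tuple(cfg["cohorts"]["boundaries"]),
        normalize_fractions=bool(cfg["cohorts"]["normalize"]),
    )


def build_climatology(cfg: dict, rng_seed: int = 0, force_no_noise: bool = False) -> ClimatologyConfig:
    c = cfg["climate"]
    return ClimatologyConfig(
        annual_mean=float(c["annual_mean"]),
        annual_amplitude=float(c["annual_amplitude"]),
        warmest_day_of_year=int(c["warmest_day_of_year"]),
        daily_noise_sd=0.0 if force_no_noise else float(c["daily_noise_sd"]),
        rng_seed=rng_seed,
    )


def build_population(cfg: dict, label: str) -> PopulationParams:
    try:
        p = cfg["population"][label]
    except KeyError:
        raise ValueError(f"unknown population {label!r}") from None
    return PopulationParams(
        sm=_rate(p["sm"], "sm"),
        e=_rate(p["e"], "e"),
        sdls=tuple(_rate(p[f"sdls{i}"], f"sdls{i}") for i in (1, 2, 3)),
        fr=tuple(_rate(p[f"fr{i}"], f"fr{i}") for i in (1, 2, 3)),
        f=FecundityParam(float(p["f"]["mean"]), float(p["f"].get("sd", 0.0))),
        b=_rate(p["b"], "b"),
        lp=_rate(p["lp"], "lp"),
        sl=_rate(p["sl"], "sl"),
        label=label,
    )


def build_control(cfg: dict) -> ControlRates:
    c = cfg["control"]
    return ControlRates(
        rc_post_early=_rate(c["rc_post_early"], "rc_post_early"),
        rc_post_late=_rate(c["rc_post_late"], "rc_post_late"),
        cr={key: _rate(entry, f"cr_{key}") for key, entry in c["cr"].items()},
    )


def build_scenario(cfg: dict, scenario: str) -> ScenarioConfig:
    deltas = cfg["scenario"]["delta_T"]
    key = str(scenario)
    if key not in deltas:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(deltas)}")
    return ScenarioConfig(name=f"scenario{key}", delta_T=float(deltas[key]))


def build_simulation_config(
    cfg: dict,
    strategy: str,
    scenario: str,
    population: str,
    master_seed: int,
    *,
    years: int | None = None,
    replicates: int | None = None,
    deterministic: bool = False,
) -> "SimulationConfig":
    """Assemble an engine SimulationConfig from a resolved configuration."""
    from .engine import SimulationConfig

    return SimulationConfig(
        population=build_population(cfg, population),
        strategy=get_strategy(strategy, cfg["model"]["m4_variant"]),
        control=build_control(cfg),
        scenario=build_scenario(cfg, scenario),
        climatology=build_climatology(cfg),
        emergence_model=build_emergence_model(cfg),
        schedule=build_schedule(cfg),
        years=int(years if years is not None else cfg["sim"]["years"]),
        replicates=int(replicates if replicates is not None else cfg["sim"]["replicates"]),
        initial_seed_bank=float(cfg["sim"]["initial_seed_bank"]),
        master_seed=int(master_seed),
        start_year=int(cfg["sim"]["start_year"]),
        deterministic=deterministic,
        rc_applies=cfg["model"]["rc_applies"],
        extinction_floor=float(cfg["model"]["extinction_floor"]),
    )
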