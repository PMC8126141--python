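"""Run configuration: one YAML file describes a reproducible run.

A config with no overrides reproduces every shipped default (rate and
diffusion constants, the four treatment regimes, the reference phenotype,
the three-phase time grid, solver tolerances and the sweep grid).  All
quantities are SI with concentrations in molar; no unit conversion is
performed anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .model_core import (
    SCENARIOS,
    CellPhenotype,
    InvalidParameterError,
    ModelConstants,
    TreatmentScenario,
)
from .simulator import DEFAULT_ATOL, DEFAULT_RTOL, TimeGrid
from .sweep import GridSpec

__all__ = [
    "ConfigError",
    "SolverSettings",
    "RunConfig",
    "load_config",
    "serialize_config",
    "save_config",
    "default_config_path",
]


class ConfigError(ValueError):
    """Configuration file is missing, unparseable, or invalid."""


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    method: str = "BDF"

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0):
            raise InvalidParameterError("rtol and atol must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a single run or a sweep bit-for-bit."""

    constants: ModelConstants = field(default_factory=ModelConstants)
    phenotype: CellPhenotype = field(default_factory=CellPhenotype)
    scenario: TreatmentScenario = field(
        default_factory=lambda: SCENARIOS["selective_non_synergistic"])
    time_grid: TimeGrid = field(default_factory=TimeGrid)
    solver: SolverSettings = field(default_factory=SolverSettings)
    sweep: GridSpec = field(default_factory=GridSpec)
    tau_tolerance: float = 0.10
    tau_convention: str = "increase"
    output_dir: str = "ptlkin_runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        scenario: object
        if self.scenario == SCENARIOS.get(self.scenario.regime_label):
            scenario = self.scenario.regime_label
        else:
            scenario = dataclasses.asdict(self.scenario)
        return {
            "constants": self.constants.to_dict(),
            "phenotype": dataclasses.asdict(self.phenotype),
            "scenario": scenario,
            "time_grid": dataclasses.asdict(self.time_grid),
            "solver": dataclasses.asdict(self.solver),
            "sweep": self.sweep.to_dict(),
            "tau_tolerance": self.tau_tolerance,
            "tau_convention": self.tau_convention,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }


def _build_section(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    if name == "constants":
        allowed.discard("k4")  # derived, never settable
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}"
        )
    # tolerate YAML 1.1 floats written without an exponent sign ("1.7e7")
    coerced = {}
    for k, v in section.items():
        if isinstance(v, str):
            try:
                v = float(v)
            except ValueError:
                pass
        coerced[k] = v
    try:
        return cls(**coerced)
    except (InvalidParameterError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def _build_scenario(raw) -> TreatmentScenario:
    if isinstance(raw, str):
        try:
            return TreatmentScenario.from_label(raw)
        except InvalidParameterError as exc:
            raise ConfigError(str(exc)) from exc
    if isinstance(raw, dict):
        return _build_section(TreatmentScenario, raw, "scenario")
    raise ConfigError("section 'scenario' must be a regime label or a mapping")


_SECTION_BUILDERS = {
    "constants": lambda raw: _build_section(ModelConstants, raw, "constants"),
    "phenotype": lambda raw: _build_section(CellPhenotype, raw, "phenotype"),
    "scenario": _build_scenario,
    "time_grid": lambda raw: _build_section(TimeGrid, raw, "time_grid"),
    "solver": lambda raw: _build_section(SolverSettings, raw, "solver"),
    "sweep": lambda raw: _build_section(GridSpec, raw, "sweep"),
}

_SCALAR_KEYS = ("tau_tolerance", "tau_convention", "output_dir", "log_level")


def config_from_dict(raw: dict | None) -> RunConfig:
    """Validated RunConfig from a parsed mapping; unknown keys rejected."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTION_BUILDERS) - set(_SCALAR_KEYS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, builder in _SECTION_BUILDERS.items():
        if key in raw:
            kwargs[key] = builder(raw[key])
    for key in _SCALAR_KEYS:
        if key in raw:
            kwargs[key] = raw[key]
    cfg = RunConfig(**kwargs)
    if cfg.tau_convention not in ("increase", "literal"):
        raise ConfigError(
            f"tau_convention must be 'increase' or 'literal', got {cfg.tau_convention!r}"
        )
    if not (cfg.tau_tolerance > 0):
        raise ConfigError("tau_tolerance must be positive")
    return cfg


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw)


def serialize_config(config: RunConfig) -> str:
    """YAML text such that ``load`` of it reproduces ``config`` exactly."""
    return yaml.safe_dump(config.to_dict(), sort_keys=False)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(serialize_config(config))


def default_config_path() -> Path:
    """Path of the shipped all-defaults configuration file."""
    return Path(str(resources.files("ptlkin").joinpath("data/default_config.yaml")))
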