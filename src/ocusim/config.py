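"""Run configuration: structured-text (YAML) parsing and validation.

A run config names a drug (fixture name or explicit parameter block), a
physiology source, a dosing regimen, solver settings, the horizon and a
seed. Unknown keys are rejected; validation errors name the offending key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dosing import DeviceSpec, IVRegimen, InjectionEvent, build_iv_soc_schedule, build_ivt_schedule
from .params import DrugParameters, OcularPhysiology, TargetParameters


class ConfigError(ValueError):
    """A configuration file failed validation."""


_TOP_KEYS = {
    "drug", "physiology", "target", "regimen", "solver",
    "horizon_weeks", "seed", "output_dir",
}
_REGIMEN_KEYS = {
    "type", "dose", "loading_multiplier", "start", "interval",
    "release_rate", "duration", "injection_times", "emptying_weeks_early",
}
_SOLVER_KEYS = {"rtol", "atol", "method", "fine_step_h", "coarse_step_h"}
_DRUG_KEYS = {"name", "MW", "Kd_TNF", "koff_TNF", "radius"}
_TARGET_KEYS = {"baseline_conc", "kdeg_TNF", "SF", "kdeg_complex"}


def _reject_unknown(mapping: Mapping, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def _require(mapping: Mapping, key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required key {key!r} in {context}")
    return mapping[key]


def _positive_number(value: Any, key: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool) or value <= 0:
        raise ConfigError(f"key {key!r} must be a number > 0, got {value!r}")
    return float(value)


def _nonneg_number(value: Any, key: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool) or value < 0:
        raise ConfigError(f"key {key!r} must be a number >= 0, got {value!r}")
    return float(value)


@dataclass
class RunConfig:
    """A fully validated, runnable configuration."""

    drug: DrugParameters
    physiology: OcularPhysiology
    target: TargetParameters
    regimen_type: str  # "iv_soc" | "ivt" | "none"
    schedule: list[InjectionEvent]
    horizon_weeks: float = 52.0
    solver: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str | None = None
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        """Stable hash of the raw configuration mapping."""
        text = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def config_from_dict(cfg: Mapping) -> RunConfig:
    """Validate a config mapping and resolve it into model objects."""
    from . import synthetic

    if not isinstance(cfg, Mapping):
        raise ConfigError("top-level config must be a mapping")
    _reject_unknown(cfg, _TOP_KEYS, "top level")

    # drug
    drug_cfg = _require(cfg, "drug", "top level")
    if isinstance(drug_cfg, str):
        try:
            drug = synthetic.default_drug_params(drug_cfg)
        except KeyError as exc:
            raise ConfigError(str(exc)) from None
    elif isinstance(drug_cfg, Mapping):
        _reject_unknown(drug_cfg, _DRUG_KEYS, "drug")
        try:
            drug = DrugParameters(
                name=str(_require(drug_cfg, "name", "drug")),
                MW=_positive_number(_require(drug_cfg, "MW", "drug"), "drug.MW"),
                Kd_TNF=_positive_number(_require(drug_cfg, "Kd_TNF", "drug"), "drug.Kd_TNF"),
                koff_TNF=_positive_number(
                    _require(drug_cfg, "koff_TNF", "drug"), "drug.koff_TNF"
                ),
                radius=drug_cfg.get("radius"),
            )
        except ValueError as exc:
            raise ConfigError(f"drug: {exc}") from None
    else:
        raise ConfigError("key 'drug' must be a name or a parameter mapping")

    # target
    target_cfg = cfg.get("target", {})
    if not isinstance(target_cfg, Mapping):
        raise ConfigError("key 'target' must be a mapping")
    _reject_unknown(target_cfg, _TARGET_KEYS, "target")
    try:
        target = TargetParameters(**{k: float(v) for k, v in target_cfg.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"target: {exc}") from None

    # physiology
    phys_cfg = cfg.get("physiology", "default")
    if phys_cfg == "default":
        physiology = synthetic.default_physiology()
    elif isinstance(phys_cfg, Mapping) and set(phys_cfg) <= {"seed", "jitter_cv"}:
        physiology = synthetic.sample_physiology(
            seed=int(phys_cfg.get("seed", cfg.get("seed", 0))),
            jitter_cv=_nonneg_number(phys_cfg.get("jitter_cv", 0.2), "physiology.jitter_cv"),
        )
    elif isinstance(phys_cfg, Mapping) and set(phys_cfg) == {"file"}:
        path = Path(phys_cfg["file"])
        if not path.exists():
            raise ConfigError(f"physiology.file {path} does not exist")
        physiology = synthetic.physiology_from_dict(yaml.safe_load(path.read_text()))
    elif isinstance(phys_cfg, Mapping):
        try:
            physiology = synthetic.physiology_from_dict(phys_cfg)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"physiology: {exc}") from None
    else:
        raise ConfigError(
            "key 'physiology' must be 'default', {file: ...}, "
            "{seed/jitter_cv: ...} or an inline physiology mapping"
        )

    horizon = _positive_number(cfg.get("horizon_weeks", 52.0), "horizon_weeks")

    # regimen -> schedule
    regimen_cfg = cfg.get("regimen")
    if regimen_cfg is None:
        regimen_type, schedule = "none", []
    else:
        if not isinstance(regimen_cfg, Mapping):
            raise ConfigError("key 'regimen' must be a mapping")
        _reject_unknown(regimen_cfg, _REGIMEN_KEYS, "regimen")
        regimen_type = _require(regimen_cfg, "type", "regimen")
        try:
            if regimen_type == "iv_soc":
                regimen = IVRegimen(
                    maintenance_dose=_nonneg_number(
                        _require(regimen_cfg, "dose", "regimen"), "regimen.dose"
                    ),
                    loading_multiplier=_nonneg_number(
                        regimen_cfg.get("loading_multiplier", 2.0),
                        "regimen.loading_multiplier",
                    ),
                    start=_nonneg_number(regimen_cfg.get("start", 1.0), "regimen.start"),
                    interval=_positive_number(
                        regimen_cfg.get("interval", 2.0), "regimen.interval"
                    ),
                    horizon=horizon,
                )
                schedule = build_iv_soc_schedule(regimen)
            elif regimen_type == "ivt":
                device = DeviceSpec(
                    release_rate=_nonneg_number(
                        _require(regimen_cfg, "release_rate", "regimen"),
                        "regimen.release_rate",
                    ),
                    duration=_positive_number(
                        regimen_cfg.get("duration", 24.0), "regimen.duration"
                    ),
                    injection_times=tuple(
                        float(t) for t in regimen_cfg.get("injection_times", (1.0, 25.0))
                    ),
                    emptying_weeks_early=_nonneg_number(
                        regimen_cfg.get("emptying_weeks_early", 0.0),
                        "regimen.emptying_weeks_early",
                    ),
                )
                schedule = build_ivt_schedule(device)
            else:
                raise ConfigError(
                    f"regimen.type must be 'iv_soc' or 'ivt', got {regimen_type!r}"
                )
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(f"regimen: {exc}") from None

    solver = dict(cfg.get("solver", {}))
    _reject_unknown(solver, _SOLVER_KEYS, "solver")
    for key in ("rtol", "atol", "fine_step_h", "coarse_step_h"):
        if key in solver:
            solver[key] = _positive_number(solver[key], f"solver.{key}")

    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"key 'seed' must be an integer, got {seed!r}")

    return RunConfig(
        drug=drug,
        physiology=physiology,
        target=target,
        regimen_type=regimen_type,
        schedule=schedule,
        horizon_weeks=horizon,
        solver=solver,
        seed=seed,
        output_dir=cfg.get("output_dir"),
        raw=dict(cfg),
    )


def parse_config(path: str | Path) -> RunConfig:
    """Read, validate and resolve a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from None
    return config_from_dict(cfg or {})


def serialize_config(config: RunConfig) -> dict:
    """Round-trippable mapping: ``config_from_dict(serialize_config(c))``
    is semantically identical to ``c``."""
    return dict(config.raw)
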