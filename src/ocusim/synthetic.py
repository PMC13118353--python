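"""Fixtures and synthetic observations.

Drug/target fixtures carry the published binding and turnover constants of
the three IgG1 anti-TNF-α antibodies; the default physiology is the
package's own calibration (no measured rat ocular dataset accompanies the
model). Noisy observation sets emulate sparse PK/PD sampling with
multiplicative lognormal error, closing the loop for parameter-recovery
studies that the purely simulation-based design pipeline itself does not
need.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dosing import DeviceSpec, InjectionEvent, build_ivt_schedule
from .params import DrugParameters, ModulatedProcess, OcularPhysiology, TargetParameters
from .simulate import SimulationResult, simulate

_DRUGS = {
    "adalimumab": dict(MW=144190.0, Kd_TNF=127.0, koff_TNF=0.576, radius=5.04),
    "golimumab": dict(MW=146940.0, Kd_TNF=18.0, koff_TNF=0.335, radius=5.08),
    "infliximab": dict(MW=144190.0, Kd_TNF=44.0, koff_TNF=0.720, radius=5.04),
}

THERAPEUTIC_OBJECTIVE_PM = 0.7  # 10% of the 7 pM pathological level


def default_drug_params(name: str) -> DrugParameters:
    """Binding/physicochemical constants for one of the three antibodies."""
    key = name.lower()
    if key not in _DRUGS:
        raise KeyError(
            f"unknown drug {name!r}; options: {', '.join(sorted(_DRUGS))}"
        )
    return DrugParameters(name=key, **_DRUGS[key])


def default_target_params() -> TargetParameters:
    """TNF-α turnover constants: 1 pM baseline, kdeg 0.223/h, SF 7,
    complex kdeg 0.18/h."""
    return TargetParameters()


def physiology_from_dict(cfg: Mapping) -> OcularPhysiology:
    """Build an :class:`OcularPhysiology` from a nested config mapping."""
    procs = cfg["processes"]

    def proc(key: str, location: str, is_fraction: bool = False) -> ModulatedProcess:
        entry = procs[key]
        return ModulatedProcess(
            healthy_value=float(entry["healthy"]),
            disease_value=float(entry["disease"]),
            coupling_location=location,
            is_fraction=is_fraction,
        )

    iop = cfg.get("iop_perturbation", {})
    return OcularPhysiology(
        q_ah=proc("q_ah", "aqueous_humor"),
        q_av=proc("q_av", "icb_interstitial"),
        q_va=proc("q_va", "icb_interstitial"),
        f_schlemm=proc("f_schlemm", "aqueous_humor", is_fraction=True),
        sigma_ah=proc("sigma_ah", "icb_plasma", is_fraction=True),
        volumes_ml={k: float(v) for k, v in cfg["volumes_ml"].items()},
        Q_ICB=float(cfg["Q_ICB"]),
        PS_ICB=float(cfg["PS_ICB"]),
        L_ICB=float(cfg["L_ICB"]),
        CL_sys=float(cfg["CL_sys"]),
        iop_perturbation_enabled=bool(iop.get("enabled", True)),
        iop_amplitude=float(iop.get("amplitude", 0.2)),
        iop_tau=float(iop.get("tau_h", 24.0)),
    )


def physiology_to_dict(phys: OcularPhysiology) -> dict:
    """Inverse of :func:`physiology_from_dict`."""
    def proc(p: ModulatedProcess) -> dict:
        return {"healthy": p.healthy_value, "disease": p.disease_value}

    return {
        "volumes_ml": dict(phys.volumes_ml),
        "processes": {
            "q_ah": proc(phys.q_ah),
            "q_av": proc(phys.q_av),
            "q_va": proc(phys.q_va),
            "f_schlemm": proc(phys.f_schlemm),
            "sigma_ah": proc(phys.sigma_ah),
        },
        "Q_ICB": phys.Q_ICB,
        "PS_ICB": phys.PS_ICB,
        "L_ICB": phys.L_ICB,
        "CL_sys": phys.CL_sys,
        "iop_perturbation": {
            "enabled": phys.iop_perturbation_enabled,
            "amplitude": phys.iop_amplitude,
            "tau_h": phys.iop_tau,
        },
    }


_DEFAULT_PHYSIOLOGY_CACHE: dict | None = None


def default_physiology() -> OcularPhysiology:
    """Calibrated default physiology shipped with the package."""
    global _DEFAULT_PHYSIOLOGY_CACHE
    if _DEFAULT_PHYSIOLOGY_CACHE is None:
        text = (
            resources.files("ocusim").joinpath("data/default_physiology.yaml").read_text()
        )
        _DEFAULT_PHYSIOLOGY_CACHE = yaml.safe_load(text)
    return physiology_from_dict(_DEFAULT_PHYSIOLOGY_CACHE)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def sample_physiology(seed: int, jitter_cv: float = 0.2) -> OcularPhysiology:
    """Calibrated defaults with independent lognormal jitter per parameter.

    Flows, volumes and clearances are jittered multiplicatively (median
    preserved); fraction-valued parameters (f_Schlemm, σ_AH) are jittered
    on the odds scale so they remain in (0, 1). ``jitter_cv = 0`` returns
    the defaults exactly.
    """
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be >= 0")
    base = default_physiology()
    if jitter_cv == 0:
        return base
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(jitter_cv)

    def jit(x: float) -> float:
        return float(x * np.exp(rng.normal(0.0, sigma)))

    def jit_fraction(p_val: float) -> float:
        odds = p_val / (1.0 - p_val)
        odds = jit(odds)
        return odds / (1.0 + odds)

    def jit_flow_process(p: ModulatedProcess) -> ModulatedProcess:
        healthy = jit(p.healthy_value)
        ratio = jit(p.healthy_value / p.disease_value)  # reduction coefficient
        return replace(p, healthy_value=healthy, disease_value=healthy / ratio)

    def jit_frac_process(p: ModulatedProcess) -> ModulatedProcess:
        return replace(
            p,
            healthy_value=jit_fraction(p.healthy_value),
            disease_value=jit_fraction(p.disease_value),
        )

    return base.with_updates(
        q_ah=jit_flow_process(base.q_ah),
        q_av=jit_flow_process(base.q_av),
        q_va=jit_flow_process(base.q_va),
        f_schlemm=jit_frac_process(base.f_schlemm),
        sigma_ah=jit_frac_process(base.sigma_ah),
        volumes_ml={k: jit(v) for k, v in base.volumes_ml.items()},
        Q_ICB=jit(base.Q_ICB),
        PS_ICB=jit(base.PS_ICB),
        L_ICB=jit(base.L_ICB),
        CL_sys=jit(base.CL_sys),
    )


@dataclass(frozen=True)
class ObservationSet:
    """Noisy observations of one simulated concentration series."""

    times: np.ndarray  # h
    location: str
    species: str
    values: np.ndarray  # pM
    cv: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "location": self.location,
                "species": self.species,
                "conc_pM": self.values,
            }
        )


def noisy_observations(
    result: SimulationResult,
    times: Sequence[float],
    location: str,
    species: str,
    cv: float,
    seed: int,
) -> ObservationSet:
    """Sample ``result`` at ``times`` (h) with multiplicative lognormal error.

    obs = model × exp(ε), ε ~ N(0, σ²) with σ² = ln(1 + cv²), so the
    observation CV equals ``cv``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    t = np.asarray(times, dtype=float)
    if t.min() < result.time[0] or t.max() > result.time[-1]:
        raise ValueError("observation times extrapolate beyond the simulated grid")
    model = np.interp(t, result.time, result.concentration(location, species))
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, _lognormal_sigma(cv), size=t.size) if cv > 0 else np.zeros(t.size)
    return ObservationSet(
        times=t, location=location, species=species,
        values=model * np.exp(eps), cv=cv, seed=seed,
    )


@dataclass
class RecoveryResult:
    """Weighted-least-squares parameter estimates with diagnostics."""

    estimates: dict
    residual_sum: float
    converged: bool
    n_simulations: int
    message: str = ""


#: documented identifiable free-parameter subsets
IDENTIFIABLE_SUBSETS = ({"SF"}, {"SF", "CL_sys"}, {"release_rate"})

_FLOOR_PM = 1e-12


def recover_parameters(
    observations: ObservationSet | Sequence[ObservationSet],
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    *,
    physiology: OcularPhysiology,
    drug: DrugParameters,
    target: TargetParameters,
    schedule: Sequence[InjectionEvent],
    horizon: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> RecoveryResult:
    """Estimate model parameters from observations by nonlinear least squares.

    Residuals are log-concentration differences (matching the lognormal
    observation model); the underlying simulator is re-run at every trial
    point. Supported free parameters: ``SF``, ``CL_sys`` (mL/h) and
    ``release_rate`` (µg/week, rescales every device in the schedule).
    Non-convergence is flagged on the result rather than raised.
    """
    from scipy.optimize import least_squares

    obs_list = [observations] if isinstance(observations, ObservationSet) else list(observations)
    free = list(free)
    unknown = set(free) - {"SF", "CL_sys", "release_rate"}
    if unknown:
        raise ValueError(f"unsupported free parameters: {sorted(unknown)}")
    if not any(set(free) <= s for s in IDENTIFIABLE_SUBSETS):
        raise ValueError(
            f"{sorted(free)} is not a documented identifiable subset"
        )
    t_max = max(o.times.max() for o in obs_list)
    if horizon is None:
        horizon = float(np.ceil(t_max / (7 * 24.0)) + 1.0)

    n_sim = 0

    def build(theta: np.ndarray):
        values = dict(zip(free, theta))
        tgt = replace(target, SF=values["SF"]) if "SF" in values else target
        phys = (
            physiology.with_updates(CL_sys=values["CL_sys"])
            if "CL_sys" in values
            else physiology
        )
        sched = schedule
        if "release_rate" in values:
            sched = []
            for ev in schedule:
                if ev.kind == "ivt_device_start":
                    dev = replace(ev.device, release_rate=values["release_rate"])
                    sched.append(replace(ev, device=dev))
                else:
                    sched.append(ev)
        return phys, tgt, sched

    def residuals(theta: np.ndarray) -> np.ndarray:
        nonlocal n_sim
        phys, tgt, sched = build(theta)
        result = simulate(
            phys, drug, tgt, sched, horizon=horizon, rtol=rtol, atol=atol
        )
        n_sim += 1
        res = []
        for o in obs_list:
            model = np.interp(
                o.times, result.time, result.concentration(o.location, o.species)
            )
            res.append(
                np.log(np.maximum(model, _FLOOR_PM))
                - np.log(np.maximum(o.values, _FLOOR_PM))
            )
        return np.concatenate(res)

    lo = np.array([bounds[p][0] for p in free], dtype=float)
    hi = np.array([bounds[p][1] for p in free], dtype=float)
    x0 = np.sqrt(lo * hi)  # geometric midpoint of the bounds
    try:
        fit = least_squares(
            residuals, x0, bounds=(lo, hi), x_scale=x0, diff_step=1e-3,
            xtol=1e-8, ftol=1e-10, gtol=1e-10,
        )
        return RecoveryResult(
            estimates=dict(zip(free, fit.x)),
            residual_sum=float(np.sum(fit.fun**2)),
            converged=bool(fit.success),
            n_simulations=n_sim,
            message=str(fit.message),
        )
    except Exception as exc:  # flagged, not raised
        return RecoveryResult(
            estimates={p: float("nan") for p in free},
            residual_sum=float("nan"),
            converged=False,
            n_simulations=n_sim,
            message=f"optimizer failure: {exc}",
        )
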