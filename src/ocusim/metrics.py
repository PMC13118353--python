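"""Evaluation endpoints: Red%, fold changes, dose totals, outcome classes.

Red% is the average percent reduction of free TNF-α from its pathological
level (SF × healthy baseline) over a steady-state window, reported with a
positive sign for reductions. Device-failure outcomes are classified from
the free TNF-α concentrations in the four monitored locations at the time
of the next administration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dosing import DeviceSpec, InjectionEvent
from .params import TNF_COMPARTMENTS
from .simulate import SimulationResult

#: ordered from best to worst outcome
OUTCOME_CATEGORIES = (
    "all_below_objective",
    "first_above_objective",
    "all_above_baseline",
    "all_pathological",
)

DEFAULT_THRESHOLDS = {"objective": 0.7, "baseline": 1.0, "pathological": 7.0}

#: tie-break order for the sentinel location (highest concentration wins;
#: ties resolved in this order)
LOCATION_PRIORITY = ("aqueous_humor", "icb_interstitial", "icb_plasma", "venous_plasma")


@dataclass(frozen=True)
class OutcomeClassification:
    """Device-failure endpoint at the next-administration time point."""

    category: str
    triggering_location: str | None = None
    evaluation_time: float | None = None  # weeks

    def __post_init__(self) -> None:
        if self.category not in OUTCOME_CATEGORIES:
            raise ValueError(f"unknown outcome category {self.category!r}")
        if self.category == "first_above_objective" and self.triggering_location is None:
            raise ValueError("first_above_objective requires a triggering location")

    @property
    def severity(self) -> int:
        """Rank of the category, 0 (best) to 3 (worst)."""
        return OUTCOME_CATEGORIES.index(self.category)


def red_percent(C_avg: float, SF: float, C_healthy: float) -> float:
    """Percent reduction of free TNF-α from the pathological level.

    ``(1 − C_avg / (SF · C_healthy)) × 100``; 100 at complete suppression,
    0 at the pathological level, negative if TNF-α exceeds it.
    """
    if SF * C_healthy <= 0:
        raise ValueError("pathological concentration must be > 0")
    if C_avg < 0:
        raise ValueError("C_avg must be >= 0")
    return (1.0 - C_avg / (SF * C_healthy)) * 100.0


def fold_change(C_ss_ivt: float, C_avg_ss_iv: float) -> float:
    """IVT-over-IV steady-state concentration ratio, rounded to 2 decimals."""
    if C_avg_ss_iv <= 0:
        raise ValueError("IV average concentration must be > 0")
    return round(C_ss_ivt / C_avg_ss_iv, 2)


def total_annual_dose(schedule: Sequence[InjectionEvent]) -> float:
    """Total drug administered over the schedule, µg.

    IV boluses contribute their amounts (including loading); each device
    start contributes the device load.
    """
    total = 0.0
    for ev in schedule:
        if ev.kind == "iv_bolus":
            total += ev.amount
        elif ev.kind == "ivt_device_start":
            total += ev.device.load
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return total


def dose_reduction_percent(iv_total: float, ivt_total: float) -> float:
    """Percent reduction of the annual dose moving from IV to IVT."""
    if iv_total <= 0:
        raise ValueError("iv_total must be > 0")
    return (1.0 - ivt_total / iv_total) * 100.0


def free_ratio_series(
    result: SimulationResult, location: str, floor_pM: float = 1e-6
) -> pd.Series:
    """Free TNF-α over free drug concentration ratio at ``location``.

    Points where the free drug concentration is below ``floor_pM`` are
    emitted as missing (NaN) rather than divided through.
    """
    tnf = result.concentration(location, "tnf")
    drug = result.concentration(location, "drug")
    ratio = np.where(drug >= floor_pM, tnf / np.maximum(drug, floor_pM), np.nan)
    return pd.Series(ratio, index=pd.Index(result.time, name="time_h"), name="tnf_over_drug")


def classify_outcome(
    concentrations: Mapping[str, float],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    *,
    pathological_tol: float = 0.01,
    evaluation_time: float | None = None,
) -> OutcomeClassification:
    """Classify free TNF-α concentrations at the next-administration time.

    Categories, in increasing severity: every location below the
    therapeutic objective; at least one location at/above the objective
    (the highest-concentration location is reported as sentinel); every
    location at/above baseline; every location within ``pathological_tol``
    (relative) of the pathological level — the asymptotic rebound never
    exactly attains it.
    """
    missing = set(TNF_COMPARTMENTS) - set(concentrations)
    if missing:
        raise ValueError(f"missing locations: {sorted(missing)}")
    conc = {c: float(concentrations[c]) for c in TNF_COMPARTMENTS}
    objective = thresholds["objective"]
    baseline = thresholds["baseline"]
    pathological = thresholds["pathological"]

    values = np.array([conc[c] for c in TNF_COMPARTMENTS])
    if np.all(values >= pathological * (1.0 - pathological_tol)):
        return OutcomeClassification("all_pathological", evaluation_time=evaluation_time)
    if np.all(values >= baseline):
        return OutcomeClassification("all_above_baseline", evaluation_time=evaluation_time)
    if np.any(values >= objective):
        top = max(conc.values())
        sentinel = next(c for c in LOCATION_PRIORITY if conc[c] == top)
        return OutcomeClassification(
            "first_above_objective", triggering_location=sentinel,
            evaluation_time=evaluation_time,
        )
    return OutcomeClassification("all_below_objective", evaluation_time=evaluation_time)
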