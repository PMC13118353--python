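"""Event-driven deterministic simulation of the ocular PBPK-PD model.

Integration is restarted at every discontinuity: disease onset, each IV
bolus (an instantaneous amount jump into venous plasma), each device start
and each device-exhaustion time. Within a segment the right-hand side is
smooth and a stiff implicit method (BDF) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import kinetics
from .dosing import DeviceSpec, InjectionEvent
from .kinetics import (
    HOURS_PER_WEEK,
    IDX_COMPLEX,
    IDX_DRUG,
    IDX_TNF,
    assemble_rhs,
    healthy_initial_state,
    ug_per_week_to_pmol_per_h,
    ug_to_pmol,
)
from .params import DrugParameters, OcularPhysiology, TargetParameters

SPECIES = ("drug", "tnf", "complex")
_IDX = {"drug": IDX_DRUG, "tnf": IDX_TNF, "complex": IDX_COMPLEX}


class SimulationError(RuntimeError):
    """Solver failure; carries the last successfully reached state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass
class SimulationResult:
    """Dense simulated trajectories with event log and solver diagnostics."""

    time: np.ndarray  # h
    amounts: np.ndarray  # (n_t, 13), pmol
    physiology: OcularPhysiology
    drug: DrugParameters
    target: TargetParameters
    events: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def concentration(self, location: str, species: str) -> np.ndarray:
        """Concentration series (pM) of ``species`` at ``location``."""
        try:
            idx = _IDX[species][location]
        except KeyError:
            raise KeyError(f"no {species!r} series at {location!r}") from None
        return self.amounts[:, idx] / self.physiology.volumes_l[location]

    def concentration_at(self, t: float, location: str, species: str) -> float:
        """Linearly interpolated concentration (pM) at time ``t`` (h)."""
        series = self.concentration(location, species)
        if not (self.time[0] <= t <= self.time[-1]):
            raise ValueError(f"time {t} h outside simulated grid")
        return float(np.interp(t, self.time, series))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame with columns time_h, compartment, species, conc_pM."""
        frames = []
        for species, index in _IDX.items():
            for location in index:
                frames.append(
                    pd.DataFrame(
                        {
                            "time_h": self.time,
                            "compartment": location,
                            "species": species,
                            "conc_pM": self.concentration(location, species),
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _segment_grid(t0: float, t1: float, fine_h: float, coarse_h: float) -> np.ndarray:
    """Output grid for one segment: fine for the first week, then coarse."""
    span = t1 - t0
    fine_end = min(t0 + HOURS_PER_WEEK, t1)
    pts = [np.arange(t0, fine_end, fine_h)]
    if fine_end < t1:
        pts.append(np.arange(fine_end, t1, coarse_h))
    pts.append(np.array([t1]))
    grid = np.unique(np.concatenate(pts))
    return grid[(grid >= t0) & (grid <= t1)] if span > 0 else np.array([t0])


def detect_device_exhaustion(
    device: DeviceSpec, schedule: Iterable[InjectionEvent]
) -> list[float]:
    """Exhaustion times (h) of ``device`` within ``schedule``.

    Exhaustion occurs exactly ``load / effective_rate`` weeks after each
    start of this device; these times are integration breakpoints.
    """
    times = []
    for ev in schedule:
        if ev.kind == "ivt_device_start" and ev.device == device:
            times.append(ev.time + device.effective_duration * HOURS_PER_WEEK)
    return times


def simulate(
    physiology: OcularPhysiology,
    drug: DrugParameters,
    target: TargetParameters,
    schedule: Sequence[InjectionEvent],
    horizon: float = 52.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    start_week: float = -1.0,
    method: str = "BDF",
    fine_step_h: float = 1.0,
    coarse_step_h: float = 6.0,
) -> SimulationResult:
    """Simulate the model from ``start_week`` (healthy steady state) to
    ``horizon`` weeks.

    Disease switches on at week 0 (synthesis factor jumps to SF and the
    five modulated processes onto their disease-to-healthy recovery
    curves). Identical inputs produce identical output arrays.
    """
    t_start = start_week * HOURS_PER_WEEK
    t_end = horizon * HOURS_PER_WEEK
    events = sorted(schedule, key=lambda e: e.time)
    if events and (events[0].time < t_start or events[-1].time > t_end):
        raise ValueError("schedule events must lie within the simulated span")

    # device release windows: (start_h, stop_h, rate_pmol_h)
    windows = []
    for ev in events:
        if ev.kind == "ivt_device_start":
            dev = ev.device
            if dev is None:
                raise ValueError("ivt_device_start event lacks a device")
            stop = ev.time + dev.effective_duration * HOURS_PER_WEEK
            windows.append((ev.time, stop, ug_per_week_to_pmol_per_h(dev.effective_rate, drug.MW)))

    breakpoints = {t_start, t_end}
    if t_start < 0.0 < t_end:
        breakpoints.add(0.0)
    breakpoints.update(ev.time for ev in events)
    breakpoints.update(w[1] for w in windows if w[1] <= t_end)
    cuts = sorted(b for b in breakpoints if t_start <= b <= t_end)

    bolus_at = {}
    ivt_times = []
    event_rows = []
    for ev in events:
        if ev.kind == "iv_bolus":
            bolus_at[ev.time] = bolus_at.get(ev.time, 0.0) + ug_to_pmol(ev.amount, drug.MW)
            event_rows.append({"time_h": ev.time, "event": "iv_bolus", "value": ev.amount})
        elif ev.kind == "ivt_device_start":
            ivt_times.append(ev.time)
            event_rows.append(
                {"time_h": ev.time, "event": "ivt_device_start", "value": ev.device.effective_rate}
            )
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    for w in windows:
        if w[1] <= t_end:
            event_rows.append({"time_h": w[1], "event": "device_exhausted", "value": 0.0})

    y = healthy_initial_state(physiology, target)
    times_out = [np.array([t_start])]
    states_out = [y.copy()[None, :]]
    nfev = 0
    nsteps = 0

    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        if t0 in bolus_at:
            y = y.copy()
            y[IDX_DRUG["venous_plasma"]] += bolus_at[t0]
            times_out.append(np.array([t0]))
            states_out.append(y.copy()[None, :])
        if t1 <= t0:
            continue
        release = sum(r for (a, b, r) in windows if a <= t0 < b)
        past_ivt = [t for t in ivt_times if t <= t0]
        rhs = assemble_rhs(
            physiology,
            drug,
            target,
            disease_active=t0 >= 0.0,
            release_pmol_h=release,
            iop_reference_time=max(past_ivt) if past_ivt else None,
        )
        grid = _segment_grid(t0, t1, fine_step_h, coarse_step_h)
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=grid, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed in segment [{t0}, {t1}] h: {sol.message}",
                last_time=float(sol.t[-1]) if sol.t.size else t0,
                last_state=sol.y[:, -1] if sol.t.size else y,
            )
        nfev += sol.nfev
        nsteps += sol.t.size
        # drop the duplicated segment-start point (after a bolus the
        # post-jump state at t0 is already recorded; the pre-jump state is
        # the previous segment's endpoint)
        if sol.t.size and sol.t[0] == times_out[-1][-1]:
            times_out.append(sol.t[1:])
            states_out.append(sol.y.T[1:])
        else:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
        y = sol.y[:, -1]

    time = np.concatenate(times_out)
    amounts = np.vstack(states_out)
    events_df = pd.DataFrame(event_rows, columns=["time_h", "event", "value"]).sort_values(
        "time_h", kind="stable", ignore_index=True
    )
    return SimulationResult(
        time=time,
        amounts=amounts,
        physiology=physiology,
        drug=drug,
        target=target,
        events=events_df,
        diagnostics={"nfev": nfev, "n_grid": int(time.size), "method": method,
                     "rtol": rtol, "atol": atol},
    )


def steady_state_average(
    result: SimulationResult,
    location: str,
    species: str,
    window: tuple[float, float],
) -> float:
    """Time-weighted (trapezoidal) mean concentration (pM) over ``window`` (h).

    Window endpoints are linearly interpolated onto the grid.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    if t0 < result.time[0] or t1 > result.time[-1]:
        raise ValueError("window outside simulated grid")
    series = result.concentration(location, species)
    inside = (result.time > t0) & (result.time < t1)
    t = np.concatenate(([t0], result.time[inside], [t1]))
    c = np.concatenate(
        (
            [np.interp(t0, result.time, series)],
            series[inside],
            [np.interp(t1, result.time, series)],
        )
    )
    return float(np.trapezoid(c, t) / (t1 - t0))


def default_steady_state_window(
    route: str, horizon: float = 52.0
) -> tuple[float, float]:
    """Default averaging window (h) for steady-state summaries.

    IV: the last complete Q2W interval (weeks 50–52). IVT: the second
    device interval (weeks 25–49).
    """
    if route == "iv":
        return ((horizon - 2.0) * HOURS_PER_WEEK, horizon * HOURS_PER_WEEK)
    if route == "ivt":
        t0, t1 = 25.0, min(49.0, horizon)
        if horizon <= t0:  # horizon too short for the second device interval
            t0, t1 = horizon / 2.0, horizon
        return (t0 * HOURS_PER_WEEK, t1 * HOURS_PER_WEEK)
    raise ValueError("route must be 'iv' or 'ivt'")
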