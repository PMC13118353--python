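"""Dose schedules: IV standard-of-care regimens and intravitreal devices.

The IV standard of care (SOC) is a loading dose (double the maintenance
dose) one week after disease induction followed by the maintenance dose
every other week starting on week 2. Intravitreal (IVT) dosing uses
zero-order sustained-release devices with a finite load injected every 24
weeks; premature-emptying variants release the same load at a higher rate
over a shortened duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinetics import HOURS_PER_WEEK


@dataclass(frozen=True)
class IVRegimen:
    """IV multiple-dose regimen (amounts in µg, times in weeks)."""

    maintenance_dose: float
    loading_multiplier: float = 2.0
    start: float = 1.0
    interval: float = 2.0
    horizon: float = 52.0

    def __post_init__(self) -> None:
        if self.maintenance_dose < 0 or self.loading_multiplier < 0:
            raise ValueError("doses must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.horizon < self.start:
            raise ValueError("horizon must be >= start")


@dataclass(frozen=True)
class DeviceSpec:
    """Zero-order intravitreal sustained-release device.

    The load is fixed at construction as ``release_rate * duration``; a
    premature-emptying variant (``emptying_weeks_early > 0``) releases the
    same load at the proportionally higher effective rate and stops exactly
    when the load is exhausted.
    """

    release_rate: float  # nominal, µg/week
    duration: float = 24.0  # nominal, weeks
    injection_times: tuple[float, ...] = (1.0, 25.0)  # weeks
    emptying_weeks_early: float = 0.0

    def __post_init__(self) -> None:
        if self.release_rate < 0:
            raise ValueError("release_rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0 <= self.emptying_weeks_early < self.duration:
            raise ValueError("emptying_weeks_early must be in [0, duration)")
        if any(t < 0 for t in self.injection_times):
            raise ValueError("injection times must be >= 0")
        if list(self.injection_times) != sorted(set(self.injection_times)):
            raise ValueError("injection times must be strictly increasing")

    @property
    def load(self) -> float:
        """Drug load per device, µg."""
        return self.release_rate * self.duration

    @property
    def effective_duration(self) -> float:
        """Actual release duration, weeks."""
        return self.duration - self.emptying_weeks_early

    @property
    def effective_rate(self) -> float:
        """Actual release rate, µg/week (load-conserving)."""
        return self.load / self.effective_duration


@dataclass(frozen=True, order=True)
class InjectionEvent:
    """One administration event.

    ``kind`` is ``"iv_bolus"`` (``amount`` in µg) or ``"ivt_device_start"``
    (``device`` carries the :class:`DeviceSpec`).
    """

    time: float  # h
    kind: str = field(compare=False)
    amount: float = field(default=0.0, compare=False)  # µg, iv_bolus only
    device: DeviceSpec | None = field(default=None, compare=False)


def build_iv_soc_schedule(regimen: IVRegimen) -> list[InjectionEvent]:
    """Ordered IV bolus events for the SOC regimen.

    Loading dose ``loading_multiplier × maintenance_dose`` at ``start``,
    then maintenance doses every ``interval`` weeks from ``start + 1``,
    strictly before the horizon. The defaults with a 52-week horizon give
    26 administrations (weeks 1, 2, 4, ..., 50).
    """
    events = [
        InjectionEvent(
            time=regimen.start * HOURS_PER_WEEK,
            kind="iv_bolus",
            amount=regimen.loading_multiplier * regimen.maintenance_dose,
        )
    ]
    t = regimen.start + 1.0
    while t < regimen.horizon:
        events.append(
            InjectionEvent(
                time=t * HOURS_PER_WEEK,
                kind="iv_bolus",
                amount=regimen.maintenance_dose,
            )
        )
        t += regimen.interval
    return events


def build_ivt_schedule(device: DeviceSpec) -> list[InjectionEvent]:
    """One device-start event per injection time of ``device``."""
    return [
        InjectionEvent(time=t * HOURS_PER_WEEK, kind="ivt_device_start", device=device)
        for t in device.injection_times
    ]


def emptying_rate(optimal_rate: float, interval: float, weeks_early: float) -> float:
    """Effective release rate (µg/week) when the device empties early.

    Conserves the load: the nominal ``optimal_rate × interval`` µg are
    released over ``interval − weeks_early`` weeks.
    """
    if not 0 <= weeks_early < interval:
        raise ValueError("weeks_early must be in [0, interval)")
    if optimal_rate < 0:
        raise ValueError("optimal_rate must be >= 0")
    return optimal_rate * interval / (interval - weeks_early)


def rate_increase_percent(interval: float, weeks_early: float) -> float:
    """Relative release-rate increase (%) caused by ``weeks_early`` emptying."""
    if not 0 <= weeks_early < interval:
        raise ValueError("weeks_early must be in [0, interval)")
    return 100.0 * weeks_early / (interval - weeks_early)


def iop_perturbation_factor(
    t_since_injection: float, amplitude: float, tau: float
) -> float:
    """Transient IOP multiplier on Q_VA and Q_AH after an IVT injection."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if t_since_injection < 0:
        raise ValueError("t_since_injection must be >= 0")
    import math

    return 1.0 + amplitude * math.exp(-t_since_injection / tau)
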