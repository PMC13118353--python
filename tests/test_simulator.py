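"""Event-driven integration: closed forms, averaging, exhaustion, determinism."""

import numpy as np
import pandas as pd
import pytest

from ocusim import (
    DeviceSpec,
    IVRegimen,
    ModulatedProcess,
    TargetParameters,
    build_iv_soc_schedule,
    build_ivt_schedule,
)
from ocusim.dosing import InjectionEvent
from ocusim.kinetics import HOURS_PER_WEEK, ug_to_pmol
from ocusim.params import TNF_COMPARTMENTS
from ocusim.simulate import (
    SimulationResult,
    default_steady_state_window,
    detect_device_exhaustion,
    simulate,
    steady_state_average,
)
from conftest import FAST_SOLVER


def _make_result(time, conc, physiology, drug, target, location="aqueous_humor"):
    """Construct a SimulationResult with a prescribed drug series."""
    amounts = np.zeros((time.size, 13))
    from ocusim.kinetics import IDX_DRUG

    amounts[:, IDX_DRUG[location]] = conc * physiology.volumes_l[location]
    return SimulationResult(
        time=time, amounts=amounts, physiology=physiology, drug=drug,
        target=target, events=pd.DataFrame(columns=["time_h", "event", "value"]),
    )


class TestClosedForms:
    def test_healthy_baseline_is_flat(self, physiology, adalimumab):
        target = TargetParameters(SF=1.0)
        res = simulate(physiology, adalimumab, target, [], horizon=3.0)
        for loc in TNF_COMPARTMENTS:
            assert np.allclose(res.concentration(loc, "tnf"), 1.0, rtol=1e-9)
            assert np.allclose(res.concentration(loc, "drug"), 0.0)

    def test_disease_relaxation_follows_exponential(self, physiology, adalimumab, target):
        # with no drug each compartment follows 7 - 6 exp(-0.223 t)
        res = simulate(physiology, adalimumab, target, [], horizon=6.0)
        mask = res.time >= 0
        t = res.time[mask]
        expected = 7.0 - 6.0 * np.exp(-0.223 * t)
        for loc in TNF_COMPARTMENTS:
            c = res.concentration(loc, "tnf")[mask]
            assert np.max(np.abs(c - expected) / expected) < 1e-6

    def test_iv_bolus_monoexponential_with_transfers_zeroed(
        self, physiology, target
    ):
        # no binding (Kd huge), no ocular flows: venous plasma is a
        # one-compartment model with rate CL_sys / V
        from ocusim import DrugParameters

        inert = DrugParameters("inert", MW=144190.0, Kd_TNF=1e30, koff_TNF=1e-10)
        zero = ModulatedProcess(0.0, 0.0, "aqueous_humor")
        phys = physiology.with_updates(
            q_ah=zero,
            q_av=ModulatedProcess(0.0, 0.0, "icb_interstitial"),
            q_va=ModulatedProcess(0.0, 0.0, "icb_interstitial"),
            Q_ICB=0.0, PS_ICB=0.0, L_ICB=0.0,
            iop_perturbation_enabled=False,
        )
        dose_ug = 10.0
        schedule = [InjectionEvent(time=0.0, kind="iv_bolus", amount=dose_ug)]
        res = simulate(phys, inert, target, schedule, horizon=4.0)
        mask = res.time > 0
        t = res.time[mask]
        V = phys.volumes_l["venous_plasma"]
        k = phys.CL_sys * 1e-3 / V
        expected = ug_to_pmol(dose_ug, inert.MW) / V * np.exp(-k * t)
        c = res.concentration("venous_plasma", "drug")[mask]
        assert np.max(np.abs(c - expected) / expected) < 1e-6


class TestSteadyStateAverage:
    def test_constant_series(self, physiology, adalimumab, target):
        t = np.linspace(0.0, 100.0, 200)
        res = _make_result(t, np.full(t.size, 3.7), physiology, adalimumab, target)
        avg = steady_state_average(res, "aqueous_humor", "drug", (10.0, 90.0))
        assert avg == pytest.approx(3.7)

    def test_sinusoid_over_full_period_returns_mean(
        self, physiology, adalimumab, target
    ):
        period = 24.0
        t = np.linspace(0.0, 5 * period, 20001)
        conc = 5.0 + 2.0 * np.sin(2 * np.pi * t / period)
        res = _make_result(t, conc, physiology, adalimumab, target)
        avg = steady_state_average(
            res, "aqueous_humor", "drug", (period, 2 * period)
        )
        assert avg == pytest.approx(5.0, abs=1e-6)

    def test_bolus_decay_interval_mean_matches_closed_form(
        self, physiology, target
    ):
        # one bolus into an isolated venous compartment: the interval mean
        # over [0, T] is (D/V)(1 - e^{-kT}) / (kT)
        from ocusim import DrugParameters

        inert = DrugParameters("inert", MW=144190.0, Kd_TNF=1e30, koff_TNF=1e-10)
        zero = ModulatedProcess(0.0, 0.0, "aqueous_humor")
        phys = physiology.with_updates(
            q_ah=zero,
            q_av=ModulatedProcess(0.0, 0.0, "icb_interstitial"),
            q_va=ModulatedProcess(0.0, 0.0, "icb_interstitial"),
            Q_ICB=0.0, PS_ICB=0.0, L_ICB=0.0,
        )
        schedule = [InjectionEvent(time=0.0, kind="iv_bolus", amount=5.0)]
        t0, t1 = 24.0, 2 * HOURS_PER_WEEK
        res = simulate(phys, inert, target, schedule, horizon=2.0)
        avg = steady_state_average(res, "venous_plasma", "drug", (t0, t1))
        V = phys.volumes_l["venous_plasma"]
        k = phys.CL_sys * 1e-3 / V
        expected = (
            ug_to_pmol(5.0, inert.MW) / V
            * (np.exp(-k * t0) - np.exp(-k * t1)) / (k * (t1 - t0))
        )
        # trapezoidal quadrature on the 6-hourly output grid carries
        # O((k*h)^2) error, ~2e-5 relative here
        assert avg == pytest.approx(expected, rel=1e-4)

    def test_empty_window_rejected(self, physiology, adalimumab, target):
        t = np.linspace(0.0, 10.0, 11)
        res = _make_result(t, np.ones(11), physiology, adalimumab, target)
        with pytest.raises(ValueError):
            steady_state_average(res, "aqueous_humor", "drug", (5.0, 5.0))


class TestDeviceExhaustion:
    @pytest.mark.parametrize(
        "rate, weeks_early, expected_weeks",
        [
            (1.802, 0.0, 24.0),  # nominal device spans the interval
            (1.802, 10.0, 14.0),  # load 43.25 at 3.089 ug/week
            (0.979, 4.0, 20.0),  # golimumab load 23.5 at 1.175 ug/week
        ],
    )
    def test_exhaustion_times(self, rate, weeks_early, expected_weeks):
        dev = DeviceSpec(
            release_rate=rate, emptying_weeks_early=weeks_early,
            injection_times=(1.0,),
        )
        times = detect_device_exhaustion(dev, build_ivt_schedule(dev))
        assert times == pytest.approx([(1.0 + expected_weeks) * HOURS_PER_WEEK])

    def test_exhaustion_creates_integration_breakpoint(
        self, physiology, golimumab, target
    ):
        dev = DeviceSpec(release_rate=0.5, emptying_weeks_early=12.0,
                         injection_times=(1.0,))
        res = simulate(
            physiology, golimumab, target, build_ivt_schedule(dev),
            horizon=20.0, **FAST_SOLVER,
        )
        stop = (1.0 + 12.0) * HOURS_PER_WEEK
        assert stop in res.time
        assert (res.events.event == "device_exhausted").any()


class TestDeterminismAndGrid:
    def test_identical_runs_give_identical_csv_bytes(
        self, physiology, golimumab, target
    ):
        sched = build_iv_soc_schedule(IVRegimen(maintenance_dose=5.0, horizon=4.0))
        runs = [
            simulate(physiology, golimumab, target, sched, horizon=4.0, **FAST_SOLVER)
            for _ in range(2)
        ]
        csvs = [r.to_dataframe().to_csv(index=False).encode() for r in runs]
        assert csvs[0] == csvs[1]

    def test_grid_refinement_stability(self, physiology, golimumab, target):
        dev = DeviceSpec(release_rate=0.5, injection_times=(1.0,))
        sched = build_ivt_schedule(dev)
        coarse = simulate(
            physiology, golimumab, target, sched, horizon=10.0,
            fine_step_h=2.0, coarse_step_h=12.0, **FAST_SOLVER,
        )
        fine = simulate(
            physiology, golimumab, target, sched, horizon=10.0,
            fine_step_h=1.0, coarse_step_h=6.0, **FAST_SOLVER,
        )
        window = (6.0 * HOURS_PER_WEEK, 10.0 * HOURS_PER_WEEK)
        for loc in TNF_COMPARTMENTS:
            a = steady_state_average(coarse, loc, "tnf", window)
            b = steady_state_average(fine, loc, "tnf", window)
            assert a == pytest.approx(b, rel=1e-3)

    def test_schedule_outside_span_rejected(self, physiology, golimumab, target):
        sched = [InjectionEvent(time=60.0 * HOURS_PER_WEEK, kind="iv_bolus", amount=1.0)]
        with pytest.raises(ValueError):
            simulate(physiology, golimumab, target, sched, horizon=52.0)

    def test_default_windows(self):
        assert default_steady_state_window("iv") == (50 * 168.0, 52 * 168.0)
        assert default_steady_state_window("ivt") == (25 * 168.0, 49 * 168.0)
        with pytest.raises(ValueError):
            default_steady_state_window("topical")
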