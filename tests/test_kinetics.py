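"""Unit tests for the core kinetics: binding, turnover, recovery, RHS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ocusim.kinetics import (
    IDX_COMPLEX,
    IDX_DRUG,
    IDX_TNF,
    N_STATE,
    assemble_rhs,
    complex_fraction,
    healthy_initial_state,
    kon_from,
    recovery_value,
    tmdd_rates,
    tnf_turnover_rate,
    ug_per_week_to_pmol_per_h,
)
from ocusim.params import (
    TNF_COMPARTMENTS,
    DrugParameters,
    ModulatedProcess,
    TargetParameters,
)


class TestKonFrom:
    @pytest.mark.parametrize(
        "koff, kd, expected, tol",
        [
            (0.335, 18.0, 0.0186, 1e-3),  # golimumab, fastest binder
            (0.576, 127.0, 0.004535, 1e-3),  # adalimumab
            (1.0, 1.0, 1.0, 0.0),
        ],
    )
    def test_values(self, koff, kd, expected, tol):
        assert kon_from(koff, kd) == pytest.approx(expected, rel=max(tol, 1e-12))

    @pytest.mark.parametrize("koff, kd", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_rejected(self, koff, kd):
        with pytest.raises(ValueError):
            kon_from(koff, kd)


class TestTurnover:
    @pytest.mark.parametrize(
        "A, SF, expected",
        [
            (1.0, 1.0, 0.0),  # healthy steady state
            (7.0, 7.0, 0.0),  # pathological steady state
            (2.0, 7.0, 1.115),  # 7*0.223*1 - 0.223*2
        ],
    )
    def test_values(self, A, SF, expected):
        assert tnf_turnover_rate(A, SF, 0.223, 1.0) == pytest.approx(expected)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            tnf_turnover_rate(-1.0, 7.0, 0.223, 1.0)

    @given(
        A=st.floats(0.0, 100.0),
        SF=st.floats(1.0, 20.0),
        healthy=st.floats(0.01, 10.0),
    )
    def test_sign_drives_relaxation_to_sf_times_baseline(self, A, SF, healthy):
        # the turnover rate pushes the amount toward SF * healthy
        rate = tnf_turnover_rate(A, SF, 0.223, healthy)
        assert np.sign(rate) == np.sign(SF * healthy - A) or rate == 0.0


class TestRecoveryValue:
    @pytest.mark.parametrize(
        "frac, expected", [(0.0, 4.0), (1.0, 10.0), (0.5, 7.0)]
    )
    def test_linear_interpolation(self, frac, expected):
        proc = ModulatedProcess(10.0, 4.0, "aqueous_humor")
        assert recovery_value(proc, frac) == pytest.approx(expected)

    @pytest.mark.parametrize("frac", [-0.1, 1.1])
    def test_fraction_out_of_range_rejected(self, frac):
        with pytest.raises(ValueError):
            recovery_value(ModulatedProcess(10.0, 4.0, "aqueous_humor"), frac)

    @given(
        healthy=st.floats(-100, 100),
        disease=st.floats(-100, 100),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200)
    def test_bounded_between_disease_and_healthy(self, healthy, disease, frac):
        proc = ModulatedProcess(healthy, disease, "aqueous_humor")
        v = recovery_value(proc, frac)
        lo, hi = min(healthy, disease), max(healthy, disease)
        assert lo - 1e-12 <= v <= hi + 1e-12


class TestComplexFraction:
    def test_zero_total_defined_as_zero(self):
        assert complex_fraction(0.0, 0.0) == 0.0

    def test_basic(self):
        assert complex_fraction(3.0, 1.0) == pytest.approx(0.25)


class TestTmddRates:
    def setup_method(self):
        self.drug = DrugParameters("x", MW=150000.0, Kd_TNF=100.0, koff_TNF=0.5)
        self.target = TargetParameters()

    def test_no_drug_no_binding(self):
        binding, diss, _ = tmdd_rates(0.0, 5.0, 2.0, 1.0, self.drug, self.target)
        assert binding == 0.0
        assert diss == pytest.approx(0.5 * 2.0)

    def test_no_complex_no_dissociation_or_degradation(self):
        _, diss, deg = tmdd_rates(10.0, 5.0, 0.0, 1.0, self.drug, self.target)
        assert diss == 0.0 and deg == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            tmdd_rates(1.0, 1.0, 1.0, 0.0, self.drug, self.target)

    def test_equilibrium_matches_quadratic_root(self):
        # closed compartment, no synthesis/degradation: the free-target
        # concentration at zero net binding equals the smaller root of
        # cx^2 - (D+T+Kd) cx + D T = 0.  D = T = Kd = 100 pM.
        D = T = Kd = 100.0
        drug = DrugParameters("x", MW=150000.0, Kd_TNF=Kd, koff_TNF=0.5)

        def net_binding(free_T):
            cx = T - free_T
            binding, diss, _ = tmdd_rates(
                D - cx, free_T, cx, 1.0, drug, self.target
            )
            return binding - diss

        free = brentq(net_binding, 1e-12, T, xtol=1e-13, rtol=1e-15)
        roots = np.roots([1.0, -(D + T + Kd), D * T])
        cx_oracle = roots.min()
        assert T - free == pytest.approx(38.197, abs=5e-4)
        assert free == pytest.approx(T - cx_oracle, abs=1e-9)


class TestUnitBridge:
    @pytest.mark.parametrize(
        "rate, mw, expected",
        [
            (1.802, 144190.0, 0.07439),  # adalimumab optimal device
            (0.0, 123.0, 0.0),
            (0.979, 146940.0, 0.03966),  # golimumab optimal device
        ],
    )
    def test_values(self, rate, mw, expected):
        assert ug_per_week_to_pmol_per_h(rate, mw) == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValueError):
            ug_per_week_to_pmol_per_h(1.0, 0.0)


class TestAssembleRhs:
    def test_healthy_steady_state_is_flat(self, physiology, adalimumab, target):
        rhs = assemble_rhs(physiology, adalimumab, target, disease_active=False)
        y0 = healthy_initial_state(physiology, target)
        assert np.allclose(rhs(0.0, y0), 0.0, atol=1e-18)

    def test_pathological_steady_state_tnf_flat(self, physiology, adalimumab, target):
        rhs = assemble_rhs(physiology, adalimumab, target, disease_active=True)
        y = healthy_initial_state(physiology, target) * 0.0
        vol = physiology.volumes_l
        for c in TNF_COMPARTMENTS:
            y[IDX_TNF[c]] = target.SF * target.baseline_conc * vol[c]
        d = rhs(0.0, y)
        for c in TNF_COMPARTMENTS:
            assert d[IDX_TNF[c]] == pytest.approx(0.0, abs=1e-15)

    def test_total_drug_mass_balance_bookkeeping(self, physiology, adalimumab, target):
        # transport terms cancel pairwise: summed drug+complex derivatives
        # must equal release - CL*C_venous - sum(kdegc * A_complex)
        rng = np.random.default_rng(42)
        y = rng.uniform(0.01, 5.0, N_STATE)
        release = 0.37
        rhs = assemble_rhs(
            physiology, adalimumab, target, disease_active=True,
            release_pmol_h=release,
        )
        d = rhs(10.0, y)
        total = sum(d[IDX_DRUG[c]] for c in IDX_DRUG) + sum(
            d[IDX_COMPLEX[c]] for c in IDX_COMPLEX
        )
        C_ven = y[IDX_DRUG["venous_plasma"]] / physiology.volumes_l["venous_plasma"]
        expected = (
            release
            - physiology.CL_sys * 1e-3 * C_ven
            - target.kdeg_complex * sum(y[IDX_COMPLEX[c]] for c in IDX_COMPLEX)
        )
        assert total == pytest.approx(expected, rel=1e-10)

    def test_nan_state_raises_with_diagnostics(self, physiology, adalimumab, target):
        rhs = assemble_rhs(physiology, adalimumab, target)
        y = healthy_initial_state(physiology, target)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(0.0, y)
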