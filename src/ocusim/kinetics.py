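"""Model kinetics: TNF-α turnover, full TMDD binding, disease recovery.

The right-hand side couples, per compartment,

* zero-order TNF-α synthesis scaled by a synthesis factor SF and
  first-order degradation (indirect-response turnover),
* full 1:1 target-mediated drug disposition (TMDD): association at
  kon = koff/Kd, dissociation at koff, complex degradation at kdeg_complex,
* linear convective/diffusive drug transport over the reduced
  five-compartment topology, with the five disease-modulated processes
  recovering toward their healthy values in proportion to the local
  complexed fraction of TNF-α.

All fluxes are in pmol/h; see :mod:`ocusim.params` for unit conventions.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .params import (
    DRUG_COMPARTMENTS,
    TNF_COMPARTMENTS,
    DrugParameters,
    ModulatedProcess,
    OcularPhysiology,
    TargetParameters,
)

HOURS_PER_WEEK = 168.0

# state-vector layout: drug in the 5 compartments, then TNF and complex in
# the 4 TNF-bearing compartments
N_STATE = 13
IDX_DRUG = {c: i for i, c in enumerate(DRUG_COMPARTMENTS)}
IDX_TNF = {c: 5 + i for i, c in enumerate(TNF_COMPARTMENTS)}
IDX_COMPLEX = {c: 9 + i for i, c in enumerate(TNF_COMPARTMENTS)}


def kon_from(koff_TNF: float, Kd_TNF: float) -> float:
    """Association rate constant kon = koff/Kd, 1/(h·pM)."""
    if koff_TNF <= 0 or Kd_TNF <= 0:
        raise ValueError("koff_TNF and Kd_TNF must be > 0")
    return koff_TNF / Kd_TNF


def tnf_turnover_rate(
    A_TNF: float, SF: float, kdeg: float, A_TNF_healthy: float
) -> float:
    """Net TNF-α turnover rate, pmol/h.

    Synthesis is zero-order at ``SF * kdeg * A_TNF_healthy`` (the healthy
    steady state scaled by the synthesis factor); degradation is first
    order at ``kdeg``.
    """
    if A_TNF < 0 or A_TNF_healthy <= 0:
        raise ValueError("TNF amounts must be >= 0 (healthy amount > 0)")
    if kdeg <= 0 or SF < 1:
        raise ValueError("require kdeg > 0 and SF >= 1")
    return SF * kdeg * A_TNF_healthy - kdeg * A_TNF


def complex_fraction(A_TNF: float, A_complex: float) -> float:
    """Fraction of total TNF-α bound in complex; 0 when no TNF is present."""
    total = A_TNF + A_complex
    if total <= 0.0:
        return 0.0
    return A_complex / total


def recovery_value(process: ModulatedProcess, complex_fraction: float) -> float:
    """Operative value of a disease-modulated process.

    Linear interpolation from the disease value (no complexation) to the
    healthy value (full complexation).
    """
    if not 0.0 <= complex_fraction <= 1.0:
        raise ValueError(f"complex fraction {complex_fraction!r} outside [0, 1]")
    return process.disease_value + (
        process.healthy_value - process.disease_value
    ) * complex_fraction


def tmdd_rates(
    A_drug: float,
    A_TNF: float,
    A_complex: float,
    V: float,
    drug: DrugParameters,
    target: TargetParameters,
) -> tuple[float, float, float]:
    """Full-TMDD fluxes (binding, dissociation, complex degradation), pmol/h.

    Binding is second order in the local free drug concentration
    ``A_drug / V`` (pM) and the free TNF-α amount; each flux moves one unit
    of each species (1:1 stoichiometry).
    """
    if V <= 0:
        raise ValueError("container volume must be > 0")
    if min(A_drug, A_TNF, A_complex) < 0:
        raise ValueError("amounts must be >= 0")
    binding = drug.kon_TNF * A_TNF * (A_drug / V)
    dissociation = drug.koff_TNF * A_complex
    degradation = target.kdeg_complex * A_complex
    return binding, dissociation, degradation


def ug_per_week_to_pmol_per_h(rate: float, MW: float) -> float:
    """Convert a device release rate from µg/week to pmol/h via MW (g/mol)."""
    if MW <= 0:
        raise ValueError("MW must be > 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return rate * 1e6 / MW / HOURS_PER_WEEK


def ug_to_pmol(amount_ug: float, MW: float) -> float:
    """Convert a dose from µg to pmol via MW (g/mol)."""
    if MW <= 0:
        raise ValueError("MW must be > 0")
    return amount_ug * 1e6 / MW


def assemble_rhs(
    physiology: OcularPhysiology,
    drug: DrugParameters,
    target: TargetParameters,
    *,
    disease_active: bool = True,
    release_pmol_h: float = 0.0,
    iop_reference_time: float | None = None,
):
    """Build the ODE right-hand side ``f(t, y) -> dy/dt`` for one segment.

    Within a segment the dosing inputs are constant: ``release_pmol_h`` is
    the summed zero-order intravitreal release (pmol/h) of all active
    devices, and ``iop_reference_time`` is the time (h) of the most recent
    intravitreal injection, switching on the transient intraocular-pressure
    perturbation of Q_VA and Q_AH.

    IV boluses are instantaneous amount jumps applied between segments, not
    part of the RHS.
    """
    vol = physiology.volumes_l
    V_ven = vol["venous_plasma"]
    V_icbp = vol["icb_plasma"]
    V_icbi = vol["icb_interstitial"]
    V_ah = vol["aqueous_humor"]
    V_vit = vol["vitreous"]

    # µL/h -> L/h, mL/h -> L/h
    Q_ICB = physiology.Q_ICB * 1e-6
    PS = physiology.PS_ICB * 1e-6
    L = physiology.L_ICB * 1e-6
    CL = physiology.CL_sys * 1e-3

    SF = target.SF if disease_active else 1.0
    kdeg = target.kdeg_TNF
    kdegc = target.kdeg_complex
    kon = drug.kon_TNF
    koff = drug.koff_TNF
    base = target.baseline_conc
    A_healthy = {c: base * vol[c] for c in TNF_COMPARTMENTS}

    iop_on = physiology.iop_perturbation_enabled and iop_reference_time is not None
    iop_amp = physiology.iop_amplitude
    iop_tau = physiology.iop_tau

    i_dr = [IDX_DRUG[c] for c in DRUG_COMPARTMENTS]
    p = physiology

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        d = np.zeros(N_STATE)
        A_ven, A_icbp, A_icbi, A_ah, A_vit = y[i_dr]
        C_ven = A_ven / V_ven
        C_icbp = A_icbp / V_icbp
        C_icbi = A_icbi / V_icbi
        C_ah = A_ah / V_ah
        C_vit = A_vit / V_vit

        if disease_active:
            frac_ah = complex_fraction(
                y[IDX_TNF["aqueous_humor"]], y[IDX_COMPLEX["aqueous_humor"]]
            )
            frac_icbi = complex_fraction(
                y[IDX_TNF["icb_interstitial"]], y[IDX_COMPLEX["icb_interstitial"]]
            )
            frac_icbp = complex_fraction(
                y[IDX_TNF["icb_plasma"]], y[IDX_COMPLEX["icb_plasma"]]
            )
            # complex fractions can stray marginally outside [0,1] from
            # solver overshoot of near-zero amounts; clip for robustness
            frac_ah = min(max(frac_ah, 0.0), 1.0)
            frac_icbi = min(max(frac_icbi, 0.0), 1.0)
            frac_icbp = min(max(frac_icbp, 0.0), 1.0)
            q_ah = recovery_value(p.q_ah, frac_ah)
            f_sch = recovery_value(p.f_schlemm, frac_ah)
            q_av = recovery_value(p.q_av, frac_icbi)
            q_va = recovery_value(p.q_va, frac_icbi)
            sigma = recovery_value(p.sigma_ah, frac_icbp)
        else:
            q_ah = p.q_ah.healthy_value
            f_sch = p.f_schlemm.healthy_value
            q_av = p.q_av.healthy_value
            q_va = p.q_va.healthy_value
            sigma = p.sigma_ah.healthy_value

        q_ah *= 1e-6
        q_av *= 1e-6
        q_va *= 1e-6

        if iop_on:
            factor = 1.0 + iop_amp * np.exp(-(t - iop_reference_time) / iop_tau)
            q_ah *= factor
            q_va *= factor

        # drug transport (pmol/h)
        secretion = q_ah * (1.0 - sigma) * C_icbp  # ICB plasma -> AH
        drain = q_ah * C_ah  # AH drainage, split by f_Schlemm
        d[IDX_DRUG["venous_plasma"]] = (
            f_sch * drain
            + L * C_icbi
            + Q_ICB * (C_icbp - C_ven)
            - CL * C_ven
        )
        d[IDX_DRUG["icb_plasma"]] = (
            Q_ICB * (C_ven - C_icbp) - secretion - PS * (C_icbp - C_icbi)
        )
        d[IDX_DRUG["icb_interstitial"]] = (
            (1.0 - f_sch) * drain + PS * (C_icbp - C_icbi) - L * C_icbi
        )
        d[IDX_DRUG["aqueous_humor"]] = (
            secretion + q_va * C_vit - q_av * C_ah - drain
        )
        d[IDX_DRUG["vitreous"]] = release_pmol_h + q_av * C_ah - q_va * C_vit

        # turnover + TMDD in TNF-bearing compartments
        for c in TNF_COMPARTMENTS:
            it, ic, idg = IDX_TNF[c], IDX_COMPLEX[c], IDX_DRUG[c]
            A_T = y[it]
            A_cx = y[ic]
            C_D = y[idg] / vol[c]
            binding = kon * A_T * C_D
            dissociation = koff * A_cx
            d[it] += SF * kdeg * A_healthy[c] - kdeg * A_T - binding + dissociation
            d[ic] += binding - dissociation - kdegc * A_cx
            d[idg] += dissociation - binding

        if not np.all(np.isfinite(d)):
            raise FloatingPointError(
                f"non-finite derivative at t={t!r}; state={y.tolist()!r}"
            )
        return d

    return rhs


def healthy_initial_state(
    physiology: OcularPhysiology, target: TargetParameters
) -> np.ndarray:
    """State vector at the healthy steady state (no drug, TNF at baseline)."""
    y0 = np.zeros(N_STATE)
    vol = physiology.volumes_l
    for c in TNF_COMPARTMENTS:
        y0[IDX_TNF[c]] = target.baseline_conc * vol[c]
    return y0


def equilibrium_free_target(
    D_total: float, T_total: float, Kd: float
) -> float:
    """Free-target concentration at binding equilibrium in a closed vessel.

    Root of the 1:1 binding quadratic for total drug ``D_total``, total
    target ``T_total`` and dissociation constant ``Kd`` (all pM):
    complex = ((D+T+Kd) − sqrt((D+T+Kd)² − 4·D·T)) / 2.
    """
    if min(D_total, T_total) < 0 or Kd <= 0:
        raise ValueError("require D,T >= 0 and Kd > 0")
    s = D_total + T_total + Kd
    cx = (s - np.sqrt(s * s - 4.0 * D_total * T_total)) / 2.0
    return T_total - cx


def total_drug_amount(y: np.ndarray) -> float:
    """Total drug in the system (free + complexed), pmol."""
    return float(np.sum(y[:5]) + np.sum(y[9:13]))
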