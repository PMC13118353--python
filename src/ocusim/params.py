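"""Domain parameter types for the ocular anti-TNF-α PBPK-PD model.

Units convention throughout the package: amounts in pmol, volumes in L
(configuration files use mL), flows in µL/h internally converted to L/h,
concentrations in pM, time in h, doses in µg (converted via molecular
weight), release rates in µg/week.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

# Canonical compartment names. Drug distributes in all five; TNF-α (and hence
# drug-TNF complex) is modelled as a stationary species in the first four.
DRUG_COMPARTMENTS = (
    "venous_plasma",
    "icb_plasma",
    "icb_interstitial",
    "aqueous_humor",
    "vitreous",
)
TNF_COMPARTMENTS = DRUG_COMPARTMENTS[:4]

#: complex-fraction coupling location of each disease-modulated process
COUPLING = {
    "q_ah": "aqueous_humor",
    "f_schlemm": "aqueous_humor",
    "q_av": "icb_interstitial",
    "q_va": "icb_interstitial",
    "sigma_ah": "icb_plasma",
}


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and TNF-α binding constants of one monoclonal antibody.

    Parameters
    ----------
    name : str
        Drug identifier (e.g. ``"adalimumab"``).
    MW : float
        Molecular weight, g/mol.
    Kd_TNF : float
        Drug–TNF-α equilibrium dissociation constant, pM.
    koff_TNF : float
        First-order complex dissociation rate constant, 1/h.
    radius : float, optional
        Hydrodynamic radius, nm (documentation only; not used by the
        reduced transport topology).
    """

    name: str
    MW: float
    Kd_TNF: float
    koff_TNF: float
    radius: float | None = None

    def __post_init__(self) -> None:
        _require_positive(MW=self.MW, Kd_TNF=self.Kd_TNF, koff_TNF=self.koff_TNF)

    @property
    def kon_TNF(self) -> float:
        """Second-order association rate constant, 1/(h·pM) (koff/Kd)."""
        return self.koff_TNF / self.Kd_TNF


@dataclass(frozen=True)
class TargetParameters:
    """TNF-α turnover and complex degradation parameters.

    ``baseline_conc`` is the healthy free TNF-α concentration (pM) assumed
    identical in every TNF-bearing compartment; the pathological
    concentration is ``SF * baseline_conc``.
    """

    baseline_conc: float = 1.0  # pM
    kdeg_TNF: float = 0.223  # 1/h
    SF: float = 7.0  # dimensionless synthesis factor
    kdeg_complex: float = 0.18  # 1/h

    def __post_init__(self) -> None:
        _require_positive(
            baseline_conc=self.baseline_conc,
            kdeg_TNF=self.kdeg_TNF,
            kdeg_complex=self.kdeg_complex,
        )
        if self.SF < 1:
            raise ValueError(f"SF must be >= 1, got {self.SF!r}")

    @property
    def pathological_conc(self) -> float:
        """Free TNF-α concentration under full disease, pM."""
        return self.SF * self.baseline_conc


@dataclass(frozen=True)
class ModulatedProcess:
    """One disease-modulated physiological process.

    The operative value interpolates linearly between ``disease_value``
    (complex fraction 0) and ``healthy_value`` (complex fraction 1), the
    fraction being evaluated at ``coupling_location``.
    """

    healthy_value: float
    disease_value: float
    coupling_location: str
    is_fraction: bool = False

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.healthy_value) and math.isfinite(self.disease_value)):
            raise ValueError("process values must be finite")
        if self.coupling_location not in TNF_COMPARTMENTS:
            raise ValueError(f"unknown coupling location {self.coupling_location!r}")
        if self.is_fraction:
            for v in (self.healthy_value, self.disease_value):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"fractional process value {v!r} outside [0, 1]")


@dataclass(frozen=True)
class OcularPhysiology:
    """Reduced five-compartment ocular/systemic physiology.

    Compartments: venous plasma, ICB plasma, ICB interstitial fluid,
    aqueous humour (anterior chamber) and vitreous. The five
    disease-modulated processes (aqueous drainage Q_AH, anterior-to-posterior
    flow Q_AV, posterior-to-anterior flow Q_VA, Schlemm's-canal fraction
    f_Schlemm, blood–aqueous reflection coefficient σ_AH) are each a
    :class:`ModulatedProcess`.

    Flow units are µL/h, volumes mL, CL_sys mL/h (converted internally).
    """

    q_ah: ModulatedProcess
    q_av: ModulatedProcess
    q_va: ModulatedProcess
    f_schlemm: ModulatedProcess
    sigma_ah: ModulatedProcess
    volumes_ml: Dict[str, float]  # per compartment, mL
    Q_ICB: float  # ICB plasma perfusion, µL/h
    PS_ICB: float  # ICB plasma<->interstitial permeability-surface, µL/h
    L_ICB: float  # ICB interstitial->venous lymph flow, µL/h
    CL_sys: float  # lumped systemic clearance from venous plasma, mL/h
    iop_perturbation_enabled: bool = True
    iop_amplitude: float = 0.2  # dimensionless
    iop_tau: float = 24.0  # h

    def __post_init__(self) -> None:
        missing = set(DRUG_COMPARTMENTS) - set(self.volumes_ml)
        if missing:
            raise ValueError(f"missing compartment volumes: {sorted(missing)}")
        for name, v in self.volumes_ml.items():
            if not v > 0:
                raise ValueError(f"volume of {name} must be > 0, got {v!r}")
        for name in ("Q_ICB", "PS_ICB", "L_ICB", "CL_sys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.iop_tau <= 0:
            raise ValueError("iop_tau must be > 0")

    @property
    def volumes_l(self) -> Dict[str, float]:
        """Compartment volumes in litres."""
        return {k: v * 1e-3 for k, v in self.volumes_ml.items()}

    def with_updates(self, **kwargs) -> "OcularPhysiology":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompartmentState:
    """Amounts (pmol) of the three species in one compartment."""

    A_drug: float = 0.0
    A_TNF: float = 0.0
    A_complex: float = 0.0

    @property
    def TNF_total(self) -> float:
        return self.A_TNF + self.A_complex


@dataclass
class ModelState:
    """Full model state: one :class:`CompartmentState` per compartment."""

    compartments: Dict[str, CompartmentState] = field(default_factory=dict)
    disease_active: bool = True
    time: float = 0.0
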