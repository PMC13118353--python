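# Methods

## Model structure

`ocusim` implements a reduced physiologically based PK-PD model of an
anti-TNF-α monoclonal antibody in the anterior uveitis-diseased rat eye.
Five well-stirred compartments carry drug:

| compartment | volume (mL) | role |
|---|---|---|
| venous plasma | 10.0 | systemic circulation; IV bolus entry; lumped clearance |
| ICB plasma | 0.001 | vascular side of the blood–aqueous barrier |
| ICB interstitial | 0.005 | the biophase (site of action) |
| aqueous humour | 0.025 | anterior chamber |
| vitreous | 0.055 | intravitreal device site; drug only |

This is the smallest topology in which the five disease-modulated
processes and the four locations where TNF-α is evaluated are all
distinct. TNF-α is modelled as a stationary species: it is synthesized,
degraded and complexed locally in venous plasma, ICB plasma, ICB
interstitial fluid and aqueous humour, with no inter-compartment
transport and no TNF-α in the vitreous. Each TNF-bearing compartment has
an independent turnover at the same 1 pM healthy baseline, and disease
multiplies the synthesis rate by the synthesis factor SF (default 7), so
untreated disease relaxes every location to 7 pM with rate constant
k_deg (half-life ln 2 / 0.223 h⁻¹ ≈ 3.1 h).

Binding is full TMDD, 1:1, with association rate k_on = k_off / K_d. The
binding flux in a compartment of volume V is k_on · (A_drug/V) · A_TNF
(amounts in pmol, concentrations in pM), dissociation k_off · A_complex,
and complex degradation k_deg,complex · A_complex. Complex degradation
removes both members — it does not regenerate free TNF-α (the
alternative reading is possible; the single-sink form was chosen because
the complex balance carries a single degradation term and the complex is
cleared as one entity). The complex, like TNF-α, does not move between
compartments.

### Disease-modulated physiology

Five processes interpolate linearly between a disease value (local
complexed fraction 0) and a healthy value (fraction 1):

| process | healthy | disease | units | coupling location |
|---|---|---|---|---|
| Q_AH (aqueous drainage) | 20 | 10 | µL/h | aqueous humour |
| Q_AV (anterior→posterior flow) | 3 | 1.5 | µL/h | ICB interstitial |
| Q_VA (posterior→anterior flow) | 15 | 7.5 | µL/h | ICB interstitial |
| f_Schlemm (Schlemm's-canal fraction) | 0.85 | 0.55 | – | aqueous humour |
| σ_AH (blood–aqueous reflection) | 0.93 | 0.80 | – | ICB plasma |

The complexed fraction A_complex / (A_TNF + A_complex) is defined as 0
when total TNF-α is 0 (the disease limit), avoiding 0/0. Before disease
induction (t < 0) all processes sit at their healthy values and SF = 1;
at t = 0 SF switches to its disease value and the recovery functions take
effect, so with no drug on board the processes jump to their disease
values.

### Drug transport

Drug moves by: vitreous↔AH bulk flows Q_VA and Q_AV; secretion from ICB
plasma into AH at Q_AH · (1 − σ_AH) · C_ICB,plasma; AH drainage Q_AH
split f_Schlemm to venous plasma (Schlemm's canal) and 1 − f_Schlemm to
ICB interstitial (uveoscleral); venous↔ICB plasma perfusion Q_ICB
(1000 µL/h); ICB plasma↔interstitial diffusive exchange PS_ICB
(45 µL/h); interstitial→venous lymph L_ICB (2 µL/h); and a lumped
first-order systemic clearance CL_sys (0.04 mL/h, a ~7-day plasma
half-life typical of an IgG in the rat). FcRn recycling and endosomal
uptake are deliberately absorbed into CL_sys; whole-body organ
disposition is out of scope.

### Calibration of the default physiology

No measured rat ocular parameter set ships with the package; the default
physiology is the package's own calibration, labelled as such in
`src/ocusim/data/default_physiology.yaml`. Magnitudes are physiological
for the rat eye (aqueous turnover ~0.3 µL/min, chamber volumes tens of
µL), and two structural targets guided the remaining freedom:

* under IV multiple dosing, steady-state drug in ICB interstitial fluid
  ≈ 14-fold above aqueous humour — in this topology the IV AH/plasma
  ratio is ≈ 1 − σ_AH, which pins σ_AH near 0.93;
* under intravitreal release, AH exposure exceeds the IV average at
  matched annual dose.

Consequently the *relative* behaviours (exposure gradients, rate
rankings, failure ladders) are meaningful, while absolute concentrations
and absolute optimal doses/rates are calibration-dependent and should
not be read as predictions for a real animal.

## Dosing

IV standard of care: loading dose (2× maintenance) one week after
disease induction, maintenance every 2 weeks starting at week 2,
strictly before the 52-week horizon — 26 administrations. Boluses are
instantaneous amount additions to venous plasma.

Intravitreal devices release at a constant (zero-order) rate into the
vitreous with a finite load fixed at construction (rate × 24 weeks),
injected at weeks 1 and 25. A premature-emptying variant releases the
same load over a duration shortened by `emptying_weeks_early`, i.e. at
the load-conserving rate rate × 24/(24 − w), and stops exactly at
exhaustion. Doses in µg convert to pmol via the molecular weight;
release rates via µg/week × 10⁶ / MW / 168.

After each IVT injection a transient intraocular-pressure perturbation
multiplies Q_VA and Q_AH by 1 + a·exp(−t/τ) with a = 0.2 and τ = 24 h
(enabled by default, one config switch to disable). The functional form
and magnitude are modelling choices — a short single-exponential decay
over ~1 day, small against the 24-week interval.

## Simulation

The ODE system (13 states) is integrated with `scipy.integrate.solve_ivp`
(BDF), restarting at every discontinuity: disease onset, each bolus,
each device start and each analytically known exhaustion time. Default
tolerances rtol 1e-8 / atol 1e-10 pmol (configurable; the design
searches use 1e-6/1e-9, where grid-refinement checks show reported
averages stable to ≲0.1%). Output is dense — hourly for the first week
after each event, 6-hourly elsewhere — and identical inputs give
identical output arrays. Because the total drug amount is a linear
invariant of the state when clearance and complex degradation are off,
the implicit solver conserves it to Newton-iteration accuracy, which the
tests verify to 1e-8 relative over a 26-bolus year.

Simulations start one week before disease induction at the healthy
steady state, verifying baseline flatness. Steady-state averages are
trapezoidal time-weighted means: weeks 50–52 for IV (one full Q2W
interval) and weeks 25–49 for IVT (the second device interval). The
published-work convention for "steady state" is not specified beyond
this; the windows are a documented package choice.

## Design computations

`Red% = (1 − C_avg/(SF·C_healthy))·100` is reported with positive sign
for reductions. The reference-dose and release-rate searches are
bisections for the smallest dose/rate whose *minimum* Red% over the
criterion locations (default: aqueous humour + ICB interstitial) meets
the target (default 90%), justified by monotonicity of steady-state
reduction in exposure (property-tested); 12 iterations with a
simulation cache, giving resolution well below 1% of the bracket.
Dense-grid scans serve as independent oracles in the tests.

The failure sweep classifies the four TNF-α concentrations at the
next-administration time (24 weeks post-dose) into an ordered ladder:
all below the 0.7 pM objective; ≥ 1 location at/above it (the
highest-concentration location reported as sentinel, ties broken
AH → ICB interstitial → ICB plasma → venous); all at/above the 1 pM
baseline; all at the 7 pM pathological level within a 1% relative band
(the rebound approaches 7 pM only asymptotically). The swept device
uses a *deployment* rate: the smallest doubling-grid multiple of the
two-location optimum that meets the objective in all four locations,
mirroring grid-based formulation selection and giving the nominal device
margin below the objective.

The sensitivity sweep re-optimizes the release rate under fold changes
(1/10 … 10×, both directions) of SF, k_off and K_d, holding the
therapeutic objective at the *nominal* 0.7 pM — otherwise the objective
would rescale with SF and the required rate would be SF-invariant by
construction. Cells with structurally invalid perturbations (SF < 1)
are reported as failed rather than dropped.

## Synthetic data

The generator closes the loop that real observations would: it emulates
sparse PK/PD sampling of the deterministic model with multiplicative
lognormal error (obs = model · e^ε, σ² = ln(1 + CV²)), the standard
observation model for concentration data. Jittered physiologies apply
independent lognormal perturbations (median-preserving; fraction-valued
parameters jittered on the odds scale so they stay in (0, 1)).

What it does *not* emulate: measurement limits of quantification,
sampling-time error, inter-animal correlation structure, or any
disease-progression variability — so recovery results demonstrate
structural self-consistency and noise robustness of the fitting
machinery, not identifiability in a real experiment. Documented
identifiable subsets for the fitter: {SF}, {SF, CL_sys},
{release rate}; fits are log-scale least squares with simulation at
every trial point, non-convergence flagged on the result.

## Problem sizes

The shipped analyses and tests use: 52-week horizons with the full
26-administration IV schedule and two-injection IVT schedule; 20-sample
observation sets over 4-week recovery studies with 20 noisy replicates
at CV 0.2; 100-triple binding-equilibrium checks; and dense-grid
optimizer oracles at 0.1 µg (dose) and 0.02 µg/week (rate) resolution.

## Known limitations

* Absolute concentrations, reference doses and optimal rates depend on
  the calibrated physiology; only directions, rankings and ratios are
  robust conclusions.
* TNF-α immobility means no cytokine spillover between eye and
  circulation; systemic TNF-α suppression under IVT dosing is driven
  entirely by the small drug fraction reaching plasma.
* Deterministic only: no inter-individual variability, no uveitis
  flares, tolerance or anti-drug antibodies.
* Device release is ideal zero-order with a hard stop; erodible-matrix
  or first-order release profiles are out of scope.
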