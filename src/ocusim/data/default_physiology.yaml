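# Default reduced ocular/systemic physiology for the uveitis-diseased rat.
# Values are calibrated package defaults, not measured data: chosen so that (i) IV multiple
# dosing yields an ICB-interstitial drug exposure ~14-fold above aqueous
# humour and (ii) intravitreal sustained release yields aqueous-humour
# exposure above the IV steady-state average.
volumes_ml:
  venous_plasma: 10.0
  icb_plasma: 0.001
  icb_interstitial: 0.005
  aqueous_humor: 0.025
  vitreous: 0.055
processes:
  q_ah: {healthy: 20.0, disease: 10.0, units: uL/h}     # aqueous drainage; disease = healthy / a, a = 2
  q_av: {healthy: 3.0, disease: 1.5, units: uL/h}       # anterior-to-posterior flow; b = 2
  q_va: {healthy: 15.0, disease: 7.5, units: uL/h}      # posterior-to-anterior flow; c = 2
  f_schlemm: {healthy: 0.85, disease: 0.55}             # Schlemm's-canal drainage fraction
  sigma_ah: {healthy: 0.93, disease: 0.80}              # blood-aqueous reflection coefficient
Q_ICB: 1000.0      # ICB plasma perfusion, uL/h
PS_ICB: 45.0       # ICB plasma<->interstitial permeability-surface product, uL/h
L_ICB: 2.0         # ICB interstitial->venous lymph flow, uL/h
CL_sys: 0.04       # lumped systemic clearance, mL/h (~7 d plasma half-life)
iop_perturbation:
  enabled: true
  amplitude: 0.2
  tau_h: 24.0
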