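# Synthetic calibrated parameter set for the dimensionless seizure-regulation
# model (NOT transcribed from any experimental supplement).  The set was
# produced by the package's calibration procedure: the pre-treatment baseline
# (A = 0, no SE) is an exact equilibrium at 1.0 FC over control for every
# species, and the administration-strategy bounds hold — the bolus critical
# dose lies in (0.6, 1.0] and the infusion critical level in (0.125, 0.25].
# Thresholds are the midpoints between the control and antagomir (bolus 1.0)
# arms' chronic-phase mean T and S levels.
# Units: rates in 1/hour, sources in FC/hour, strengths dimensionless.
model:
  lam_R1: 0.033
  lam_R2: 0.0375
  lam_R3: 0.042
  lam_T: 0.006
  lam_S: 0.003
  k1: 0.187
  k2: 1.0
  k3: 0.2125
  k4: 1.0
  k5: 0.238
  k6: 1.0
  k7: 0.60156
  k8: 1.0
  k9: 0.4077
  k10: 1.0
  alpha: 120.0
  beta: 100.0
  gamma: 140.0
  delta: 2.6
  eps: 2.34
  zeta: 5.2
  eta: 2.08
  theta: 1.82
  kappa: 4.16
  lam: 0.012
  mu_A1: 0.06
  mu_A2: 0.06
  mu_A3: 0.06
  mu_R1: 0.22
  mu_R2: 0.25
  mu_R3: 0.28
  mu_T: 0.06
  mu_S: 0.06
  se_source_multiplier: 1.5
thresholds:
  th_T: 2.7918
  th_S: 2.5795
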