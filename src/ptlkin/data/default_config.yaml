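# All-defaults run configuration. Every value here equals the package
# defaults; an empty file yields the same RunConfig. Units: M, s, M^-x s^-1.
constants:
  k1: 1.7e+7       # M-1 s-1, CATFeIII + H2O2 -> compound I
  k2: 2.6e+7       # M-1 s-1, compound I + H2O2 -> CATFeIII + O2
  k3: 1.1e+3       # M-2 s-1, NO2- + H2O2 + H+ -> ONOOH
  pKa: 6.8         # ONOOH acid dissociation (k4 = 10^-pKa * k_minus4)
  k_minus4: 1.0e+10 # M-1 s-1, ONOO- + H+ -> ONOOH
  k5: 1.7e+6       # M-1 s-1, catalase-mediated ONOO- decomposition
  k6: 5.8e+4       # M-1 s-1, ONOO- + CO2
  kP: 1.0e-7       # M s-1, mitochondrial H2O2 production
  kD4: 320.0       # s-1, ONOO- membrane diffusion
  kD5: 320.0       # s-1, NO2- membrane diffusion
  kD7: 320.0       # s-1, ONOOH membrane diffusion
phenotype:
  kD1: 920.0       # s-1, H2O2 membrane diffusion (lipid-bilayer reference)
  CAT0: 1.0e-8     # M, initial intracellular native catalase
scenario: selective_non_synergistic
time_grid:
  t1: 1.0e-2
  t2: 1.0
  tf: 100.0
  dt1: 1.0e-7
  dt2: 1.0e-5
  dt3: 1.0e-3
solver:
  rtol: 1.0e-8
  atol: 1.0e-14
  method: BDF
sweep:
  kd1_min: 100.0
  kd1_max: 2000.0
  cat0_min: 1.0e-8
  cat0_max: 1.0e-5
  n_kd1: 100
  n_cat0: 100
  kd1_spacing: linear
  cat0_spacing: linear
tau_tolerance: 0.1
tau_convention: increase
output_dir: ptlkin_runs
log_level: INFO
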