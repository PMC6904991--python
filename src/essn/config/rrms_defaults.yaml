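# Default RRMS parameter sets (rates per day, counts per mm^3).
#
# The original study's rate constants are unpublished (supplementary
# material); these sets are this package's own calibration: the `ms` set
# reproduces the disease regime (progressive irreversible ODC damage
# under the five-injection EBV protocol, ~77% of ODCs at the Lmin level
# after one year), the `healthy` set the protective regime (rapid viral
# clearance with a memory-accelerated secondary response and minimal
# damage).  Override any value via RRMSParameters.with_overrides or a
# scenario's param_overrides.
shared:
  FromTimoREG: 0.1
  FromTimoEFF: 0.1
  resting_treg_setpoint: 63.0
  resting_teff_setpoint: 1687.0
  TregDeath: 0.1
  TeffDeath: 0.15
  p_eff_dup: 0.6
  MemActivation: 0.3
  TregActivation: 0.5
  TeffActivation: 0.01
  TregDup: 0.3
  TeffDup: 1.2
  NKentry: 18.75
  NKDeath: 0.05
  NKKillsTeff: 0.001
  NKKillsTreg: 0.0005
  NKdup: 1.3e-4
  EBVinj: 0.0
  DACinj: 0.0
  DACDegradation: 0.0768
  K_EBV: 500.0
  K_Teff: 500.0
  K_Treg: 100.0
  K_IL2: 300.0
  K_DAC: 20.0
  il2_per_activation: 25.0

ms:
  TregKillsTeff: 0.001
  TeffKillsEBV: 1.0e-2
  TeffKillsODC: 0.266
  Remyelinization: 0.005

healthy:
  TregKillsTeff: 0.02
  TeffKillsEBV: 2.0e-2
  TeffKillsODC: 0.08
  Remyelinization: 0.02
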