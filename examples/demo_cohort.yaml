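# Demo cohort: the default study conditions of the synthetic generator.
# Usable as `sigforge simulate --config examples/demo_cohort.yaml --out-prefix demo`.
n_tumor: 300          # tumor samples
n_reference: 50       # diploid/reference panel for z-scoring
n_genes: 10
prognostic_genes: [G001, G002, G003]
effect_beta:          # ln(2)/alteration_shift -> hazard x2 per carried gene
  G001: 0.173286795
  G002: 0.173286795
  G003: 0.173286795
alteration_shift: 4.0 # carriers sit ~4 SD above the reference mean
risk_frac: 0.25       # carrier fraction per prognostic gene
carrier_mode: independent
hazard_model: carrier
baseline_hazard: 0.01 # events/month for non-carriers
censor_rate: 0.0043   # ~30% censoring against the baseline hazard
admin_horizon: 240.0  # months of follow-up
class_horizon_T: 120.0
seed: 0
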