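# Example pipeline configuration (all values shown are the defaults).
binding:
  k_dbp_constant: 7.0e+08     # VDBP-25OHD association constant, M^-1 (constant scheme)
  k_alb: 6.0e+05              # albumin-25OHD association constant, M^-1
  allele_k_dbp:               # genotype-specific VDBP constants, M^-1
    Gc1f: 1.12e+09
    Gc1s: 6.0e+08
    Gc2: 3.6e+08
  mw_25ohd: 400.64            # g/mol
  mw_vdbp: 58000.0
  mw_albumin: 66500.0
  mode: linear                # 'linear' (binder-total) or 'exact' (depletion-corrected)
thresholds:
  deficiency_ng_ml: 20.0      # vitamin D deficiency: total 25OHD below this
  bmi_overweight_pct: 85.0
  bmi_obese_pct: 95.0
  activity_min_per_day: 60.0
  activity_days_per_week: 3.0
  vif_limit: 3.0
  bonferroni_family: 15       # C(6,2) pairwise diplotype comparisons
  alpha: 0.05
reference_table: null         # null -> packaged synthetic DXA reference
seed: 0
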