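# Default run configuration.
#
# Economic, treatment-line and technology parameter values below are
# documented placeholders with realistic magnitudes (2023 USD scale); they
# are NOT transcriptions of any proprietary source.  Replace them with your
# own estimates to analyse a real setting.  The WTP threshold (81,630 $/QALY,
# 2023 US GDP per capita) and the 0.03 annual discount rate are standard
# health-economics conventions.
seed: 12345
model:
  horizon_months: 24
  monthly_mortality: 0.0004
  annual_followup_dropout: 0.2
economics:
  utilities:
    H: 0.85
    M: 0.72
    S: 0.58
  followup_visit_cost: 180.0
  background_treatment_cost: 40.0
  treatment_change_cost: 0.0
  annual_discount_rate: 0.03
  wtp_threshold: 81630.0
lines:
- pr_rm: 0.35
  pr_rsp: 0.2
  monthly_cost: 25.0
  adverse_discontinuation: 0.06
- pr_rm: 0.3
  pr_rsp: 0.18
  monthly_cost: 30.0
  adverse_discontinuation: 0.07
- pr_rm: 0.26
  pr_rsp: 0.16
  monthly_cost: 40.0
  adverse_discontinuation: 0.08
- pr_rm: 0.22
  pr_rsp: 0.14
  monthly_cost: 55.0
  adverse_discontinuation: 0.09
- pr_rm: 0.19
  pr_rsp: 0.13
  monthly_cost: 70.0
  adverse_discontinuation: 0.1
- pr_rm: 0.16
  pr_rsp: 0.12
  monthly_cost: 85.0
  adverse_discontinuation: 0.11
- pr_rm: 0.13
  pr_rsp: 0.11
  monthly_cost: 100.0
  adverse_discontinuation: 0.12
- pr_rm: 0.11
  pr_rsp: 0.1
  monthly_cost: 115.0
  adverse_discontinuation: 0.13
- pr_rm: 0.09
  pr_rsp: 0.09
  monthly_cost: 130.0
  adverse_discontinuation: 0.14
adaptive:
  sensitivity: 0.85
  specificity: 0.85
  monitoring_cost_monthly: 12.0
engine:
  visits_per_year_overrides: {}
  suppress_lockout_visits: false
prep:
  min_observations: 6
  ewma_alpha: 0.5
  n_clusters: 3
  kmeans_restarts: 20
  zero_row_fallback: self_loop
synthetic:
  n_patients: 444
  score_noise_sd: 1.2
  missing_fraction: 0.38
  female_fraction: 0.69
  mean_age: 45.0
scales:
  line_cost: 1.0
  pr_rm: 1.0
  pr_rsp: 1.0
  adverse: 1.0
sensitivity:
  cost_levels:
  - 0.0
  - 12.0
  - 50.0
  grid_points: 11
profiles_path: null
output_dir: outputs
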