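# Synthetic base-case parameter set for the ctDNA-guided switching model.
# Printed anchors (assay 3 x EUR 350, predictive value 0.85, ARPI split 0.5,
# WTP 80000, discounting 4%/1.5%) are fixed; all other values are plausible
# NON-PAPER magnitudes documented in ctdna_cea.synthetic (cited-trial medians,
# 2022 Dutch cost magnitudes). Identical to
# generate_parameter_set(SyntheticProfile("base_like")).
arpi_abi_share: 0.5
bsc_cost_per_cycle:
  kind: gamma
  mean: 300.0
  se: 30.0
bsc_entry_monthly_prob:
  kind: beta
  mean: 0.004
  se: 0.0008
cohort_size: 1000
ctdna_cost_per_sample:
  hi: 350.0
  kind: gamma
  lo: 100.0
  mean: 350.0
  se: 35.0
ctdna_flag_fraction:
  kind: beta
  mean: 0.4
  se: 0.04000000000000001
ctdna_n_samples: 3
ctdna_ppv:
  hi: 0.95
  kind: beta
  lo: 0.65
  mean: 0.85
  se: 0.05
cycle1_days: 28.0
cycle_days: 21.0
diagnostic_cost:
  kind: gamma
  mean: 420.0
  se: 42.0
discount_rate_costs: 0.04
discount_rate_effects: 0.015
durable_curves_equal_trial: false
durable_six_month_hold: false
horizon_years: 5.0
lines:
  abiraterone:
    admin_cost_per_cycle:
      kind: fixed
      mean: 0.0
      se: 0.0
    ae_events:
    - cost:
        kind: gamma
        mean: 600.0
        se: 60.0
      name: cardiac_hypertensive
      probability:
        kind: beta
        mean: 0.08
        se: 0.008
    drug_cost_per_cycle:
      kind: gamma
      mean: 1150.0
      se: 115.0
    os:
      form: exponential_median
      median: 34.7
      median_se: 3.4700000000000006
    pfs:
      form: exponential_median
      median: 16.5
      median_se: 1.6500000000000001
    utility:
      kind: beta
      mean: 0.8
      se: 0.08000000000000002
  arpi_durable_responder:
    admin_cost_per_cycle:
      kind: fixed
      mean: 0.0
      se: 0.0
    ae_events: []
    drug_cost_per_cycle:
      kind: gamma
      mean: 1650.0
      se: 165.0
    os:
      form: exponential_median
      median: 72.0
      median_se: 7.2
    pfs:
      form: exponential_median
      median: 48.0
      median_se: 4.800000000000001
    utility:
      kind: beta
      mean: 0.805
      se: 0.08050000000000002
  bsc:
    admin_cost_per_cycle:
      kind: fixed
      mean: 0.0
      se: 0.0
    ae_events: []
    drug_cost_per_cycle:
      kind: fixed
      mean: 0.0
      se: 0.0
    os:
      form: exponential_median
      median: 8.0
      median_se: 0.8
    pfs:
      form: exponential_median
      median: 8.0
      median_se: 0.0
    utility:
      kind: beta
      mean: 0.55
      se: 0.05500000000000001
  cabazitaxel:
    admin_cost_per_cycle:
      kind: gamma
      mean: 450.0
      se: 45.0
    ae_events:
    - cost:
        kind: gamma
        mean: 5500.0
        se: 550.0
      name: febrile_neutropenia
      probability:
        kind: beta
        mean: 0.1
        se: 0.010000000000000002
    drug_cost_per_cycle:
      kind: gamma
      mean: 3800.0
      se: 380.0
    max_cycles: 10
    os:
      form: exponential_median
      median: 13.6
      median_se: 1.36
    pfs:
      form: exponential_median
      median: 8.0
      median_se: 0.8
    utility:
      kind: beta
      mean: 0.72
      se: 0.072
  docetaxel:
    admin_cost_per_cycle:
      kind: gamma
      mean: 450.0
      se: 45.0
    ae_events:
    - cost:
        kind: gamma
        mean: 5500.0
        se: 550.0
      name: febrile_neutropenia
      probability:
        kind: beta
        mean: 0.12
        se: 0.012
    - cost:
        kind: gamma
        mean: 800.0
        se: 80.0
      name: peripheral_neuropathy
      probability:
        kind: beta
        mean: 0.05
        se: 0.005000000000000001
    drug_cost_per_cycle:
      kind: gamma
      mean: 90.0
      se: 9.0
    max_cycles: 10
    os:
      form: exponential_median
      median: 24.3
      median_se: 2.43
    pfs:
      form: exponential_median
      median: 5.3
      median_se: 0.53
    utility:
      kind: beta
      mean: 0.74
      se: 0.074
  enzalutamide:
    admin_cost_per_cycle:
      kind: fixed
      mean: 0.0
      se: 0.0
    ae_events:
    - cost:
        kind: gamma
        mean: 600.0
        se: 60.0
      name: fatigue_hypertension
      probability:
        kind: beta
        mean: 0.08
        se: 0.008
    drug_cost_per_cycle:
      kind: gamma
      mean: 2150.0
      se: 215.0
    os:
      form: exponential_median
      median: 35.3
      median_se: 3.53
    pfs:
      form: exponential_median
      median: 20.0
      median_se: 2.0
    utility:
      kind: beta
      mean: 0.81
      se: 0.08100000000000002
schema_version: 1
visit_cost_per_cycle:
  kind: gamma
  mean: 80.0
  se: 8.0
wtp: 80000.0
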