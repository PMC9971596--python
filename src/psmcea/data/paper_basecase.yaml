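# Base-case configuration: the published trial analysis's parameter values
# (costs and utilities in USD at 6.76 RMB/USD), plus a synthetic two-arm
# trial emulating the trial's size, follow-up and reported medians so the
# pipeline runs end to end without external data. To analyse real digitized
# curves, replace each arm's `simulate` block with a `files` block:
#   files: {pfs_curve: F, pfs_risk: F, os_curve: F, os_risk: F}
# where curves are CSV (time_months,survival) and risk tables CSV
# (time_months,n_risk), and add `truncate_after_months: {pfs: X, os: Y}` to
# drop terminal digitization artifacts before fitting.

seed: 20230214
horizon_cycles: 104        # 21-day cycles; >99% of the cohort dead by then
splice_mode: raw           # parametric tail not rescaled at the KM cutoff
preferred_family: weibull
family_tolerance: 0.05     # AIC/BIC proximity rule (relative)
digitize_points: 200
risk_interval_months: 3.0

arms:
  arm1:
    label: camrelizumab+chemotherapy
    km_cutoff_cycles: {pfs: 29, os: 29}   # 20.3 months read from KM directly
    simulate:
      # marginal Weibulls chosen so that, after the per-subject
      # PFS := min(PFS, OS) constraint, PFS median ~= 11.3 months and OS
      # median ~= 21.3 months (trial-reported values), and >99% of the
      # cohort is dead by cycle 104
      n_subjects: 205
      pfs_shape: 1.3
      pfs_scale: 21.18
      os_shape: 1.6
      os_scale: 26.78
      censor_rate: 0.01   # exponential dropout per month
      max_followup: 24.0
      seed: 11
  arm0:
    label: chemotherapy
    km_cutoff_cycles: {pfs: 26, os: 26}   # 18.2 months read from KM directly
    simulate:
      # PFS median ~= 8.3 months, OS median ~= 20.7 months after the
      # min(PFS, OS) constraint
      n_subjects: 207
      pfs_shape: 1.45
      pfs_scale: 12.82
      os_shape: 1.6
      os_scale: 26.03
      censor_rate: 0.01
      max_followup: 21.0
      seed: 12

economics:
  arm1:                    # camrelizumab + chemotherapy, USD per 21-day cycle
    cost_pfs: 904.48       # induction phase, cycles 0-6
    cost_maintenance: 837.13   # cycles 7-34
    cost_pd: 388.96        # progressed disease (incl. subsequent therapy)
    one_time: 1952.78      # AE management + pre-treatment workup
    drug_component: 433.14 # camrelizumab acquisition line within the above
    cap_cycle: 35          # 2-year treatment cap: all alive states -> cost_pd
  arm0:                    # chemotherapy alone
    cost_pfs: 774.54
    cost_maintenance: 707.19
    cost_pd: 421.67
    one_time: 1607.77
    drug_component: 0.0
  u_pfs: 0.804             # progression-free utility (Chinese NSCLC)
  u_pd: 0.321              # progressed-disease utility
  discount_rate: 0.05      # per year, costs and QALYs
  cycle_days: 21
  induction_end: 6         # last induction cycle
  wtp: 35936.09            # 3x GDP per capita, China 2021, USD/QALY

ae_table:                  # grade 3+ events in >10% of either arm
  puncture: 443.79
  pdl1_test: 295.86
  rows:
    - {name: neutrophil count decreased, cost_per_patient: 455.62,
       incidence_arm1: 0.38, incidence_arm0: 0.30}
    - {name: white blood cell count decreased, cost_per_patient: 455.62,
       incidence_arm1: 0.20, incidence_arm0: 0.14}
    - {name: anemia, cost_per_patient: 88.76,
       incidence_arm1: 0.19, incidence_arm0: 0.11}
    - {name: platelet count decreased, cost_per_patient: 5482.40,
       incidence_arm1: 0.17, incidence_arm0: 0.12}

psa:
  n_draws: 1000            # Monte Carlo simulations
  seed: 0
  se_fraction: 0.2         # SE = 20% of base for gamma (costs) / beta (utilities)

scenarios:
  price_cuts: [0.2, 0.3, 0.4, 0.5, 0.6, 0.7]   # camrelizumab price reductions
  utilities: {u_pfs: 0.71, u_pd: 0.67}         # Western-literature utility set
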