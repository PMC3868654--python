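country_code: FR
country_name: France
currency: EUR
epidemiology:
  population_size: 62616488
  fraction_over_18: 78%
  migraine_prevalence: 21.3%
  diagnosis_rate: 75%
  treated_fraction: 90%
  rx_treated_fraction: 50%
  triptan_fraction: 25%
  switched_triptan_fraction: 35%
  undiagnosed_treated_fraction: 90%
  segment_overrides:   # published Pop 1/Pop 2, calibrated against sales data
    pop1: 309354
    pop2: 563206
resources:
  unit_cost_switched_triptan: 7.36
  unit_cost_other_triptan: 6.12
  reimb_rate_switched: 65%
  reimb_rate_other: 65%
  gp_visit_cost: 22
  er_visit_cost: 25
  ae_event_cost: 1694
  workday_cost: 127
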