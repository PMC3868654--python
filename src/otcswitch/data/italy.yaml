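country_code: IT
country_name: Italy
currency: EUR
epidemiology:
  population_size: 60221211
  fraction_over_18: 83%
  migraine_prevalence: 11.6%
  diagnosis_rate: 50%
  treated_fraction: 90%
  rx_treated_fraction: 50%
  triptan_fraction: 19%
  switched_triptan_fraction: 9%
  undiagnosed_treated_fraction: 90%
  segment_overrides:
    pop1: 21634
    pop2: 232084
resources:
  unit_cost_switched_triptan: 9.65
  unit_cost_other_triptan: 8.05
  reimb_rate_switched: 100%
  reimb_rate_other: 100%
  gp_visit_cost: 21
  er_visit_cost: 62
  ae_event_cost: 3416
  workday_cost: 107
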