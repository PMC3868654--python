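country_code: ES
country_name: Spain
currency: EUR
epidemiology:
  population_size: 45957671
  fraction_over_18: 82%
  migraine_prevalence: 12.6%
  diagnosis_rate: 50%
  treated_fraction: 90%
  rx_treated_fraction: 50%
  triptan_fraction: 18%
  switched_triptan_fraction: 29%
  undiagnosed_treated_fraction: 90%
  segment_overrides:
    pop1: 55942
    pop2: 139250
resources:
  unit_cost_switched_triptan: 11.22
  unit_cost_other_triptan: 9.25
  reimb_rate_switched: 100%
  reimb_rate_other: 100%
  gp_visit_cost: 23
  er_visit_cost: 128
  ae_event_cost: 4320
  workday_cost: 94
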