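country_code: UK
country_name: United Kingdom
currency: GBP
epidemiology:
  population_size: 61792000
  fraction_over_18: 77%
  migraine_prevalence: 15%
  diagnosis_rate: 65%
  treated_fraction: 89%
  rx_treated_fraction: 41%
  triptan_fraction: 22%
  switched_triptan_fraction: 17%
  undiagnosed_treated_fraction: 89%
  segment_overrides:
    pop1: 62793
    pop2: 313181
resources:
  unit_cost_switched_triptan: 6.92
  unit_cost_other_triptan: 6.09
  reimb_rate_switched: 100%
  reimb_rate_other: 100%
  gp_visit_cost: 39
  er_visit_cost: 51
  ae_event_cost: 1916
  workday_cost: 120
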