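country_code: DE
country_name: Germany
currency: EUR
epidemiology:
  population_size: 81879976
  fraction_over_18: 84%
  migraine_prevalence: 10.0%
  diagnosis_rate: 50%
  treated_fraction: 90%
  rx_treated_fraction: 50%
  triptan_fraction: 31%
  switched_triptan_fraction: 23%
  undiagnosed_treated_fraction: 90%
  segment_overrides:
    pop1: 109646
    pop2: 375642
resources:
  unit_cost_switched_triptan: 6.46
  unit_cost_other_triptan: 5.59
  reimb_rate_switched: 100%
  reimb_rate_other: 100%
  gp_visit_cost: 31
  er_visit_cost: 53
  ae_event_cost: 3610
  workday_cost: 164
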