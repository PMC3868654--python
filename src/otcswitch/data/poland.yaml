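country_code: PL
country_name: Poland
currency: PLN
epidemiology:
  population_size: 38149886
  fraction_over_18: 81%
  migraine_prevalence: 10.0%
  diagnosis_rate: 50%
  treated_fraction: 90%
  rx_treated_fraction: 50%
  triptan_fraction: 5%
  switched_triptan_fraction: 3%
  undiagnosed_treated_fraction: 90%
  segment_overrides:
    pop1: 966
    pop2: 30627
resources:
  unit_cost_switched_triptan: 16.6
  unit_cost_other_triptan: 19.87
  reimb_rate_switched: 0%   # triptans not reimbursed; payer drug spend is zero
  reimb_rate_other: 0%
  gp_visit_cost: 31
  er_visit_cost: 147
  ae_event_cost: 2927
  workday_cost: 180
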