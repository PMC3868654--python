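# Behavioural constants shared by all six countries (base case).
resources:
  attacks_per_year_rx: 24          # migraine attacks/patient/year, Rx-treated (Pop 1-2)
  attacks_per_year_otc: 12         # attacks/patient/year, OTC-treated or untreated (Pop 3-6)
  gp_visits_per_year: 2.8          # migraine-specific GP visits/patient/year
  unscheduled_visit_fraction: 30%  # visits made exclusively to obtain a prescription
  er_prob_per_attack: 0.4%
  er_reduction_triptan: 65%
  contraindicated_fraction: 8%
  serious_ae_incidence: 0.1%
  ae_mitigation: 95%               # risk decrease from labelling / pharmacist training
  work_hour_attack_fraction: 35%
  prob_no_triptan_at_attack: 25%
  absenteeism_rx: 24%
  absenteeism_otc: 8%
  presenteeism_rx: 73%
  presenteeism_otc: 24%
  productivity_level: 56%          # productivity while symptomatic
  triptan_productivity_gain: 13%
  employed_fraction: 70%
  gp_visit_workdays_lost: 0.5
  gp_visit_during_work_fraction: 25%
  moh_risk: 14%                    # triptan users likely to develop MOH
  moh_mitigation: 95%              # risk decrease from small packs / pharmacist training
  moh_extra_gp_visits: 8.4
  moh_extra_attack_days: 108
  moh_absenteeism: 24%
  moh_presenteeism: 55%
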