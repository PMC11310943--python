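# Base-case inputs (Austria, 2022 EUR).  Loaded by lcscea.parameters.table1_fixture().
# Distributions and the age-utility table are filled in with documented
# defaults by the loader when omitted here.
demography:
  total_population: 8978929
  frac_aged_50_74: 0.3222
  smoking_rate: 0.2076
  mean_entry_age: 58
epidemiology:
  annual_incidence_eligible: 0.0045
  clinical_stage_distribution:
    I: 0.163
    II: 0.078
    III: 0.277
    IV: 0.482
settings:
  uptake: 0.50
  adherence: 1.0
  n_rounds: 17
  cycle_length: 0.25
  horizon: 42.0
  wtp: 50000
  discount_rate_costs: 0.05
  discount_rate_health: 0.05
costs:
  invitation_letter: 3
  gp_consult: 22
  ct_scan: 280
  diag_screen_detected: 803
  diag_clinical: 1093
  followup_ct: 280
  followup_consult: 88
  end_of_life: 7466
  stage:
    I:
      first_3_months: 8564
      rest_of_year1: 1956
      year2: 736
      second_line: 32085
    II:
      first_3_months: 8215
      rest_of_year1: 2588
      year2: 736
      second_line: 32085
    III:
      first_3_months: 16606
      rest_of_year1: 41502
      year2: 13598
      second_line: 24795
    IV:
      first_3_months: 12529
      rest_of_year1: 25442
      year2: 2517
      second_line: 24795
utilities:
  pre_progression:
    I: 0.78
    II: 0.78
    III: 0.69
    IV: 0.69
  post_progression:
    I: 0.69
    II: 0.69
    III: 0.69
    IV: 0.69
survival:
  os_5yr:
    I: 0.7863
    II: 0.5490
    III: 0.2924
    IV: 0.0591
  dpfs_1yr:
    I: 0.8780
    II: 0.8780
    III: 0.4181
    IV: 0.4013
  missed_behaves_as: II
background_mortality_multiplier: 1.0
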