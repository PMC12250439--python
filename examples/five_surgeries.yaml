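schema_version: 1
cohorts:
- name: open_heart_surgery
  subgroups:
  - kind: RWT
    scenario: reduced_wait
    n_patients: 20000.0
    utilities:
      u_wait: 0.6
      u_post_early: 0.8
      u_post_delayed: 0.78
    timeline:
      t_early: 0.2
      t_delayed: 1.5
      t_death_early: 19.0
      t_death_counterfactual: 19.0
    costs:
      direct_early: 230000.0
      direct_delayed: 200000.0
      indirect_patient_early: 15000.0
      indirect_patient_delayed: 40000.0
      indirect_caregiver_early: 5000.0
      indirect_caregiver_delayed: 15000.0
      incurrence_time_early: 0.2
      incurrence_time_delayed: 1.5
  - kind: AMS
    scenario: missed_surgery
    n_patients: 2000.0
    utilities:
      u_wait: 0.6
      u_post_early: 0.8
      u_post_delayed: 0.78
      u_missed: 0.45
    timeline:
      t_early: 0.2
      t_delayed: 0.2
      t_death_early: 19.0
      t_death_counterfactual: 12.0
    costs:
      direct_early: 230000.0
      direct_delayed: 0.0
      indirect_patient_early: 15000.0
      indirect_patient_delayed: 250000.0
      indirect_caregiver_early: 5000.0
      indirect_caregiver_delayed: 80000.0
      incurrence_time_early: 0.2
      incurrence_time_delayed: 0.2
  - kind: MA
    scenario: lifesaving
    n_patients: 800.0
    utilities:
      u_wait: 0.6
      u_post_early: 0.8
      u_post_delayed: 0.8
    timeline:
      t_early: 0.2
      t_delayed: 0.2
      t_death_early: 19.0
      t_death_counterfactual: 0.2
    costs:
      direct_early: 230000.0
      direct_delayed: 0.0
      indirect_patient_early: 15000.0
      indirect_patient_delayed: 0.0
      indirect_caregiver_early: 5000.0
      indirect_caregiver_delayed: 0.0
      incurrence_time_early: 0.2
      incurrence_time_delayed: 0.2
- name: cardiac_catheterization
  subgroups:
  - kind: RWT
    scenario: reduced_wait
    n_patients: 60000.0
    utilities:
      u_wait: 0.65
      u_post_early: 0.82
      u_post_delayed: 0.8
    timeline:
      t_early: 0.1
      t_delayed: 1.0
      t_death_early: 20.5
      t_death_counterfactual: 20.5
    costs:
      direct_early: 50000.0
      direct_delayed: 38000.0
      indirect_patient_early: 8000.0
      indirect_patient_delayed: 12000.0
      indirect_caregiver_early: 2000.0
      indirect_caregiver_delayed: 4000.0
      incurrence_time_early: 0.1
      incurrence_time_delayed: 1.0
  - kind: AMS
    scenario: missed_surgery
    n_patients: 5000.0
    utilities:
      u_wait: 0.65
      u_post_early: 0.82
      u_post_delayed: 0.8
      u_missed: 0.5
    timeline:
      t_early: 0.1
      t_delayed: 0.1
      t_death_early: 20.5
      t_death_counterfactual: 13.0
    costs:
      direct_early: 50000.0
      direct_delayed: 0.0
      indirect_patient_early: 8000.0
      indirect_patient_delayed: 120000.0
      indirect_caregiver_early: 2000.0
      indirect_caregiver_delayed: 30000.0
      incurrence_time_early: 0.1
      incurrence_time_delayed: 0.1
  - kind: MA
    scenario: lifesaving
    n_patients: 1500.0
    utilities:
      u_wait: 0.65
      u_post_early: 0.82
      u_post_delayed: 0.82
    timeline:
      t_early: 0.1
      t_delayed: 0.1
      t_death_early: 20.5
      t_death_counterfactual: 0.1
    costs:
      direct_early: 50000.0
      direct_delayed: 0.0
      indirect_patient_early: 8000.0
      indirect_patient_delayed: 0.0
      indirect_caregiver_early: 2000.0
      indirect_caregiver_delayed: 0.0
      incurrence_time_early: 0.1
      incurrence_time_delayed: 0.1
- name: cochlear_implantation
  subgroups:
  - kind: RWT
    scenario: reduced_wait
    n_patients: 1500.0
    utilities:
      u_wait: 0.55
      u_post_early: 0.85
      u_post_delayed: 0.8
    timeline:
      t_early: 0.3
      t_delayed: 2.0
      t_death_early: 45.0
      t_death_counterfactual: 45.0
    costs:
      direct_early: 400000.0
      direct_delayed: 380000.0
      indirect_patient_early: 0.0
      indirect_patient_delayed: 50000.0
      indirect_caregiver_early: 20000.0
      indirect_caregiver_delayed: 150000.0
      incurrence_time_early: 0.3
      incurrence_time_delayed: 2.0
  - kind: AMS
    scenario: missed_surgery
    n_patients: 500.0
    utilities:
      u_wait: 0.55
      u_post_early: 0.85
      u_post_delayed: 0.8
      u_missed: 0.45
    timeline:
      t_early: 0.3
      t_delayed: 0.3
      t_death_early: 45.0
      t_death_counterfactual: 45.0
    costs:
      direct_early: 400000.0
      direct_delayed: 0.0
      indirect_patient_early: 0.0
      indirect_patient_delayed: 600000.0
      indirect_caregiver_early: 20000.0
      indirect_caregiver_delayed: 300000.0
      incurrence_time_early: 0.3
      incurrence_time_delayed: 0.3
- name: retinal_surgery
  subgroups:
  - kind: RWT
    scenario: reduced_wait
    n_patients: 30000.0
    utilities:
      u_wait: 0.68
      u_post_early: 0.72
      u_post_delayed: 0.715
    timeline:
      t_early: 0.2
      t_delayed: 1.2
      t_death_early: 15.0
      t_death_counterfactual: 15.0
    costs:
      direct_early: 30000.0
      direct_delayed: 22000.0
      indirect_patient_early: 3000.0
      indirect_patient_delayed: 4000.0
      indirect_caregiver_early: 1000.0
      indirect_caregiver_delayed: 1500.0
      incurrence_time_early: 0.2
      incurrence_time_delayed: 1.2
  - kind: AMS
    scenario: missed_surgery
    n_patients: 300.0
    utilities:
      u_wait: 0.68
      u_post_early: 0.72
      u_post_delayed: 0.715
      u_missed: 0.6
    timeline:
      t_early: 0.2
      t_delayed: 0.2
      t_death_early: 15.0
      t_death_counterfactual: 15.0
    costs:
      direct_early: 30000.0
      direct_delayed: 0.0
      indirect_patient_early: 3000.0
      indirect_patient_delayed: 20000.0
      indirect_caregiver_early: 1000.0
      indirect_caregiver_delayed: 3000.0
      incurrence_time_early: 0.2
      incurrence_time_delayed: 0.2
- name: orthopedic_joint_replacement
  subgroups:
  - kind: RWT
    scenario: reduced_wait
    n_patients: 40000.0
    utilities:
      u_wait: 0.55
      u_post_early: 0.75
      u_post_delayed: 0.73
    timeline:
      t_early: 0.3
      t_delayed: 1.8
      t_death_early: 14.0
      t_death_counterfactual: 14.0
    costs:
      direct_early: 120000.0
      direct_delayed: 110000.0
      indirect_patient_early: 20000.0
      indirect_patient_delayed: 30000.0
      indirect_caregiver_early: 4000.0
      indirect_caregiver_delayed: 6000.0
      incurrence_time_early: 0.3
      incurrence_time_delayed: 1.8
  - kind: AMS
    scenario: missed_surgery
    n_patients: 1500.0
    utilities:
      u_wait: 0.55
      u_post_early: 0.75
      u_post_delayed: 0.73
      u_missed: 0.5
    timeline:
      t_early: 0.3
      t_delayed: 0.3
      t_death_early: 14.0
      t_death_counterfactual: 14.0
    costs:
      direct_early: 120000.0
      direct_delayed: 0.0
      indirect_patient_early: 20000.0
      indirect_patient_delayed: 150000.0
      indirect_caregiver_early: 4000.0
      indirect_caregiver_delayed: 25000.0
      incurrence_time_early: 0.3
      incurrence_time_delayed: 0.3
discount:
  annual_rate: 0.035
economy:
  gdp_per_capita: 56000.0
  wtp_threshold: 56000.0
  currency_label: EGP
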