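covariate,scenario_1,scenario_2,scenario_3,scenario_4,scenario_5,scenario_6
age_group,available,available,available,available,available,available
education,available,available,available,available,available,available
marital,available,available,available,available,available,available
residence,available,available,available,available,available,available
ipv_history,available,available,female_hiv,female_hiv,available,female_hiv
belief_fidelity,available,available,available,available,available,available
belief_beating_justified,available,available,available,available,available,available
partner_age_diff_large,available,available,available,available,female_hiv,female_hiv
alcohol_before_sex,available,male_hiv,available,male_hiv,male_hiv,male_hiv
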