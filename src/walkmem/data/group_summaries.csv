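label,patient_mean,patient_sd,patient_n,control_mean,control_sd,control_n,t_direction,d_direction,d_denominator,d_decimals
age_years,37.96,9.25,27,38.89,9.69,27,patient_minus_control,patient_minus_control,control_sd,2
schooling_years,12.93,2.02,27,13.11,1.93,27,patient_minus_control,patient_minus_control,control_sd,2
premorbid_iq,108.44,6.95,27,109.52,6.80,27,patient_minus_control,patient_minus_control,control_sd,2
verbal_fluency_semantic,-0.36,0.84,27,0.17,0.71,27,patient_minus_control,patient_minus_control,control_sd,2
verbal_fluency_phonemic,-0.03,0.80,27,0.15,0.94,27,patient_minus_control,patient_minus_control,control_sd,2
shifting_tmt_b_a,0.05,0.91,27,0.01,0.75,27,patient_minus_control,patient_minus_control,control_sd,2
updating_nback,7.03,2.71,27,5.23,2.05,27,patient_minus_control,control_minus_patient,control_sd,2
spatial_working_memory,9.81,1.96,27,11.18,2.42,27,patient_minus_control,patient_minus_control,control_sd,2
toj_100ms_error_proportion,0.07,0.07,27,0.03,0.05,27,patient_minus_control,control_minus_patient,control_sd,2
toj_500ms_error_proportion,0.06,0.07,27,0.02,0.03,27,patient_minus_control,control_minus_patient,control_sd,2
behavioral_stories_errors,8.63,4.11,27,7.11,3.43,27,patient_minus_control,control_minus_patient,control_sd,2
tom_stories_errors,14.67,8.15,27,11.78,7.81,27,patient_minus_control,control_minus_patient,control_sd,2
mean_story_errors,11.65,4.96,27,9.44,4.98,27,patient_minus_control,control_minus_patient,control_sd,2
chronological_score,7.41,2.70,27,7.42,2.14,27,patient_minus_control,patient_minus_control,control_sd,3
deviation_score,1.47,0.84,27,1.48,0.80,27,patient_minus_control,patient_minus_control,control_sd,2
temporal_accuracy,1.61,0.61,27,1.66,0.89,27,patient_minus_control,patient_minus_control,control_sd,2
boundaries_typicality,6.09,1.50,27,6.36,2.08,27,patient_minus_control,patient_minus_control,control_sd,2
items_recalled,25.17,7.67,27,31.11,5.33,27,patient_minus_control,patient_minus_control,control_sd,2
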