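{
  "version": 1,
  "description": "Default generator parameters per group. Calibration anchors are the published group summary cells listed under calibration_targets (mean, SD); segmentation and picture-ordering noise parameters are identical for patients and controls because the study found no group differences on those scores.",
  "walk": {
    "k_transitions": 32,
    "perceptual_fraction": 0.6,
    "salience_beta_a": 5.0,
    "salience_beta_b": 2.0,
    "n_pictures": 360,
    "length_jitter": 0.08
  },
  "checklist_size": 40,
  "groups": {
    "patient": {
      "detection_rate": 0.75,
      "jitter_sd": 0.010,
      "extra_press_rate": 2.0,
      "rater_disagreement": 0.11,
      "mallows_theta": 1.5,
      "story_theta_behavioral": 2.2,
      "story_theta_tom": 1.32,
      "recall_mean": 25.17,
      "recall_dispersion": 18.8,
      "units_mean": 22.75,
      "units_dispersion": 6.0,
      "component_probs": {
        "person": 0.013,
        "object": 0.068,
        "thought": 0.021,
        "action_with_interaction": 0.171,
        "spatial_movement": 0.871,
        "perceptual_detail": 0.023,
        "spatial_detail": 0.099,
        "comment": 0.096
      },
      "toj_error_rate_100": 0.07,
      "toj_error_rate_500": 0.06
    },
    "control": {
      "detection_rate": 0.75,
      "jitter_sd": 0.010,
      "extra_press_rate": 2.0,
      "rater_disagreement": 0.11,
      "mallows_theta": 1.5,
      "story_theta_behavioral": 2.45,
      "story_theta_tom": 1.65,
      "recall_mean": 31.11,
      "recall_dispersion": 1000000.0,
      "units_mean": 27.94,
      "units_dispersion": 39.1,
      "component_probs": {
        "person": 0.020,
        "object": 0.050,
        "thought": 0.032,
        "action_with_interaction": 0.294,
        "spatial_movement": 0.955,
        "perceptual_detail": 0.041,
        "spatial_detail": 0.121,
        "comment": 0.077
      },
      "toj_error_rate_100": 0.03,
      "toj_error_rate_500": 0.02
    },
    "reference": {
      "detection_rate": 0.75,
      "jitter_sd": 0.010,
      "extra_press_rate": 2.0,
      "rater_disagreement": 0.11,
      "mallows_theta": 1.5,
      "story_theta_behavioral": 2.45,
      "story_theta_tom": 1.65,
      "recall_mean": 34.0,
      "recall_dispersion": 1000000.0,
      "units_mean": 30.0,
      "units_dispersion": 40.0,
      "component_probs": {
        "person": 0.020,
        "object": 0.050,
        "thought": 0.032,
        "action_with_interaction": 0.294,
        "spatial_movement": 0.955,
        "perceptual_detail": 0.041,
        "spatial_detail": 0.121,
        "comment": 0.077
      },
      "toj_error_rate_100": 0.03,
      "toj_error_rate_500": 0.02
    }
  },
  "calibration_targets": {
    "items_recalled": {"patient": [25.17, 7.67], "control": [31.11, 5.33]},
    "experience_units": {"patient": [22.75, 10.43], "control": [27.94, 6.92]},
    "pct_action_with_interaction": {"patient": [17.10, 9.27], "control": [29.42, 10.81]},
    "pct_spatial_movement": {"patient": [87.07, 22.02], "control": [95.49, 16.27]},
    "chronological_score": {"patient": [7.41, 2.70], "control": [7.42, 2.14]},
    "behavioral_stories_errors": {"patient": [8.63, 4.11], "control": [7.11, 3.43]},
    "tom_stories_errors": {"patient": [14.67, 8.15], "control": [11.78, 7.81]},
    "toj_100ms_error_proportion": {"patient": [0.07, 0.07], "control": [0.03, 0.05]},
    "toj_500ms_error_proportion": {"patient": [0.06, 0.07], "control": [0.02, 0.03]},
    "boundaries_typicality": {"patient": [6.09, 1.50], "control": [6.36, 2.08]},
    "temporal_accuracy": {"patient": [1.61, 0.61], "control": [1.66, 0.89]},
    "category_rater_kappa": 0.77
  }
}
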