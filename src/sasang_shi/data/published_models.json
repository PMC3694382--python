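{
  "description": "Published two-stage health-index regression models: per-component intercepts and LASSO coefficients (VAS points per z-unit of each feature), and integrative-stage coefficients over z-scored component scores. Age and BMI entered the integrative stage but their coefficients were not published; they are null here.",
  "component_models": [
    {"constitution": "TE", "component": "face", "intercept": 63.28,
     "coefficients": {"FhL_Cr_std": 2.75, "ChLD_Y_std": -1.18, "Nose_Y_avg": 3.36}},
    {"constitution": "TE", "component": "pulse", "intercept": 59.89,
     "coefficients": {"L_PVI": 1.62, "L_PPW_PVI": -2.71, "L_Adias_HR75": 2.53,
                      "L_PSD_w3_w1": 3.74, "R_PDI": -2.19, "R_Adias_HR75": 0.56,
                      "R_PSD_w7_w1": 0.54}},
    {"constitution": "TE", "component": "skin", "intercept": 61.22,
     "coefficients": {"Wrinkle_hand": -4.98, "Wrinkle_arm_L": -1.45, "V_E": 0.42}},
    {"constitution": "TE", "component": "voice", "intercept": 61.23,
     "coefficients": {"aPPQ": -4.54, "eBW1": -4.29, "eF2": 0.29, "oF2": 1.08,
                      "oBW2": -1.24, "sF10": 4.07}},
    {"constitution": "TE", "component": "questionnaire", "intercept": 61.23,
     "coefficients": {"Exercise capability": 4.65, "Digestion": 0.30,
                      "Sleep habits": 3.78,
                      "Extroversion and broad-mindedness": 2.45}},
    {"constitution": "SE", "component": "face", "intercept": 68.53,
     "coefficients": {"FhL_Y_avg": 0.89, "FhL_Y_std": -0.26, "FhW_Y_std": -7.35,
                      "ChRU_Cb_std": -3.76, "ChRW_Cb_std": -0.16,
                      "ChLU_Cr_std": -2.24}},
    {"constitution": "SE", "component": "pulse", "intercept": 68.90,
     "coefficients": {"L_PDI": -4.83}},
    {"constitution": "SE", "component": "skin", "intercept": 67.71,
     "coefficients": {}},
    {"constitution": "SE", "component": "voice", "intercept": 67.60,
     "coefficients": {}},
    {"constitution": "SE", "component": "questionnaire", "intercept": 67.60,
     "coefficients": {"Self-estimation of health state": 2.52,
                      "Exercise capability": 7.36, "Digestion": 3.02,
                      "Sleep habits": 2.06, "Unhealthy period": 3.83}},
    {"constitution": "SY", "component": "face", "intercept": 74.35,
     "coefficients": {"FhR_Cb_std": -1.87, "ChRU_Cb_avg": 1.19,
                      "ChRD_Y_std": -3.07}},
    {"constitution": "SY", "component": "pulse", "intercept": 73.15,
     "coefficients": {"L_t4": 1.16, "L_Aall_HR75": 0.15}},
    {"constitution": "SY", "component": "skin", "intercept": 73.98,
     "coefficients": {"E": 1.88}},
    {"constitution": "SY", "component": "voice", "intercept": 74.28,
     "coefficients": {"sFHL": -1.79}},
    {"constitution": "SY", "component": "questionnaire", "intercept": 74.28,
     "coefficients": {"Self-estimation of health state": 4.11,
                      "Discomfort after eating, defecation, and urination": 1.46,
                      "Eating habits": -4.01,
                      "Extroversion and broad-mindedness": -2.49,
                      "Unhealthy period": 0.92}}
  ],
  "integrative_models": [
    {"constitution": "TE", "intercept": -279.8,
     "coefficients": {"face": 1.298, "pulse": 0.784, "skin": 0.580,
                      "voice": 1.385, "questionnaire": 0.233},
     "beta_age": null, "beta_bmi": null, "r2": 0.58, "adj_r2": 0.51},
    {"constitution": "SE", "intercept": -187.6,
     "coefficients": {"face": 0.886, "pulse": 0.787, "questionnaire": 0.874},
     "beta_age": null, "beta_bmi": null, "r2": 0.65, "adj_r2": 0.56},
    {"constitution": "SY", "intercept": -305.3,
     "coefficients": {"face": 1.710, "pulse": 0.193, "skin": 0.549,
                      "voice": 2.367, "questionnaire": 1.609},
     "beta_age": null, "beta_bmi": null, "r2": 0.38, "adj_r2": 0.30}
  ]
}
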