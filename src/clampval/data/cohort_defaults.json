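{
  "version": 1,
  "description": "Default per-stratum (sex x BMI category) means and SDs for the synthetic cohort generator, modelled on a Cameroonian clamp-study population of 87 non-diabetic adults (51 men). Units: age years; bmi kg/m2; percent_fat %; waist/hip cm; sbp/dbp mmHg; total_chol/triglycerides/hdl mg/dL; fasting_glucose mmol/L; fasting_insulin uU/mL; height cm.",
  "height": {
    "M": {"mean": 172.0, "sd": 6.5},
    "F": {"mean": 160.0, "sd": 6.0}
  },
  "strata": {
    "M": {
      "lean": {
        "n": 23,
        "age": [33.1, 11.4],
        "bmi": [22.1, 1.4],
        "percent_fat": [14.2, 3.6],
        "waist": [76.0, 4.5],
        "hip": [87.1, 5.9],
        "sbp": [122, 20],
        "dbp": [72, 9],
        "total_chol": [160, 43],
        "triglycerides": [50, 17],
        "hdl": [48, 18],
        "fasting_glucose": [4.56, 0.58]
      },
      "overweight": {
        "n": 18,
        "age": [36.9, 9.3],
        "bmi": [27.7, 1.7],
        "percent_fat": [23.2, 6.3],
        "waist": [92.8, 8.4],
        "hip": [97.2, 6.1],
        "sbp": [131, 21],
        "dbp": [76, 11],
        "total_chol": [210, 63],
        "triglycerides": [57, 20],
        "hdl": [63, 21],
        "fasting_glucose": [4.42, 0.55]
      },
      "obese": {
        "n": 10,
        "age": [38.3, 9.7],
        "bmi": [35.3, 7.4],
        "percent_fat": [33.6, 9.6],
        "waist": [109.0, 12.8],
        "hip": [117.1, 15.1],
        "sbp": [129, 10],
        "dbp": [84, 6],
        "total_chol": [275, 45],
        "triglycerides": [71, 47],
        "hdl": [70, 32],
        "fasting_glucose": [4.93, 0.56]
      }
    },
    "F": {
      "lean": {
        "n": 14,
        "age": [31.3, 12.9],
        "bmi": [23.0, 1.4],
        "percent_fat": [26.6, 6.0],
        "waist": [78.0, 6.7],
        "hip": [92.0, 9.1],
        "sbp": [123, 22],
        "dbp": [75, 9],
        "total_chol": [154, 61],
        "triglycerides": [54, 14],
        "hdl": [47, 20],
        "fasting_glucose": [4.46, 0.50]
      },
      "overweight": {
        "n": 9,
        "age": [35.3, 16.0],
        "bmi": [27.7, 1.5],
        "percent_fat": [32.5, 8.0],
        "waist": [85.4, 7.7],
        "hip": [106.9, 9.7],
        "sbp": [117, 17],
        "dbp": [71, 6],
        "total_chol": [182, 77],
        "triglycerides": [47, 15],
        "hdl": [39, 11],
        "fasting_glucose": [4.85, 0.70]
      },
      "obese": {
        "n": 13,
        "age": [34.2, 10.7],
        "bmi": [36.3, 5.9],
        "percent_fat": [40.8, 5.3],
        "waist": [102.6, 11.4],
        "hip": [119.8, 13.3],
        "sbp": [125, 6],
        "dbp": [77, 5],
        "total_chol": [235, 55],
        "triglycerides": [71, 43],
        "hdl": [58, 23],
        "fasting_glucose": [4.56, 0.43]
      }
    }
  },
  "insulin_sensitivity": {
    "mean": 10.5,
    "sd": 3.2,
    "units": "mg/min/kg fat-free mass"
  },
  "homa_ir": {
    "mean": 1.36,
    "sd": 0.85
  }
}
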