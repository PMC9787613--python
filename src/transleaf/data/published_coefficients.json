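{
  "_provenance": "Published coefficient table for the six log-linear leaf-mass equations (coefficient and standard error), together with the published fit statistics (adjusted R2, log-scale RMSE, AIC) and pooled cross-validation error metrics. Crown class enters as a variable intercept (cell means, five levels) for every equation except eq3, which has a single global intercept. sigma2 is not printed anywhere; corrected back-transformation of the packaged sets uses rmse**2 as a documented proxy.",
  "eq1": {
    "intercept_mode": "crown_class",
    "terms": ["lnDBH", "lnLL", "lnLCR", "lnSG", "lnST", "lnMAT30", "lnMAP"],
    "coefficients": {
      "cc_open_grown": -9.947,
      "cc_dominant": -9.789,
      "cc_codominant": -9.932,
      "cc_intermediate": -10.176,
      "cc_overtopped": -10.346,
      "lnDBH": 1.703,
      "lnLL": 0.413,
      "lnLCR": 0.755,
      "lnSG": 0.689,
      "lnST": 0.236,
      "lnMAT30": 2.049,
      "lnMAP": -0.191
    },
    "standard_errors": {
      "cc_open_grown": 0.334,
      "cc_dominant": 0.044,
      "cc_codominant": 0.041,
      "cc_intermediate": 0.042,
      "cc_overtopped": 0.042,
      "lnDBH": 0.017,
      "lnLL": 0.010,
      "lnLCR": 0.028,
      "lnSG": 0.053,
      "lnST": 0.024,
      "lnMAT30": 0.114,
      "lnMAP": 0.038
    },
    "fit_reference": {"adj_r2": 0.86, "rmse": 0.50, "aic": 5338.36},
    "cv_reference": {
      "kfold": {"mpe": 29.98, "mae": 4.76, "mape": 51.58, "maape": 0.39},
      "loso": {"mpe": 31.63, "mae": 5.05, "mape": 53.83, "maape": 0.40}
    }
  },
  "eq2": {
    "intercept_mode": "crown_class",
    "terms": ["lnDBH", "lnLL", "lnLCR", "lnSGp", "lnST", "lnMAT30", "lnMAP"],
    "coefficients": {
      "cc_open_grown": -8.632,
      "cc_dominant": -8.456,
      "cc_codominant": -8.601,
      "cc_intermediate": -8.839,
      "cc_overtopped": -9.009,
      "lnDBH": 1.708,
      "lnLL": 0.406,
      "lnLCR": 0.750,
      "lnSGp": 0.800,
      "lnST": 0.221,
      "lnMAT30": 1.701,
      "lnMAP": -0.180
    },
    "standard_errors": {
      "cc_open_grown": 0.360,
      "cc_dominant": 0.043,
      "cc_codominant": 0.041,
      "cc_intermediate": 0.042,
      "cc_overtopped": 0.042,
      "lnDBH": 0.017,
      "lnLL": 0.010,
      "lnLCR": 0.028,
      "lnSGp": 0.054,
      "lnST": 0.024,
      "lnMAT30": 0.118,
      "lnMAP": 0.037
    },
    "fit_reference": {"adj_r2": 0.87, "rmse": 0.50, "aic": 5287.48},
    "cv_reference": {
      "kfold": {"mpe": 29.67, "mae": 4.6, "mape": 51.05, "maape": 0.38},
      "loso": {"mpe": 31.82, "mae": 4.84, "mape": 53.41, "maape": 0.39}
    }
  },
  "eq3": {
    "intercept_mode": "single",
    "terms": ["lnDBH"],
    "coefficients": {
      "intercept": -3.711,
      "lnDBH": 1.825
    },
    "standard_errors": {
      "intercept": 0.054,
      "lnDBH": 0.018
    },
    "fit_reference": {"adj_r2": 0.74, "rmse": 0.69, "aic": 7670.81},
    "cv_reference": {
      "kfold": {"mpe": 67.15, "mae": 5.92, "mape": 91.38, "maape": 0.52},
      "loso": {"mpe": 68.48, "mae": 6.04, "mape": 93.24, "maape": 0.52}
    }
  },
  "eq4": {
    "intercept_mode": "crown_class",
    "terms": ["lnDBH", "lnLCR"],
    "coefficients": {
      "cc_open_grown": -2.490,
      "cc_dominant": -2.567,
      "cc_codominant": -2.678,
      "cc_intermediate": -3.004,
      "cc_overtopped": -3.089,
      "lnDBH": 1.647,
      "lnLCR": 0.593
    },
    "standard_errors": {
      "cc_open_grown": 0.066,
      "cc_dominant": 0.053,
      "cc_codominant": 0.049,
      "cc_intermediate": 0.049,
      "cc_overtopped": 0.050,
      "lnDBH": 0.021,
      "lnLCR": 0.030
    },
    "fit_reference": {"adj_r2": 0.79, "rmse": 0.63, "aic": 6925.52},
    "cv_reference": {
      "kfold": {"mpe": 52.51, "mae": 5.59, "mape": 76.17, "maape": 0.47},
      "loso": {"mpe": 52.34, "mae": 5.82, "mape": 79.02, "maape": 0.48}
    }
  },
  "eq5": {
    "intercept_mode": "crown_class",
    "terms": ["lnDBH", "lnLCR", "lnMAT30", "lnMAP"],
    "coefficients": {
      "cc_open_grown": -6.442,
      "cc_dominant": -6.482,
      "cc_codominant": -6.584,
      "cc_intermediate": -6.874,
      "cc_overtopped": -6.970,
      "lnDBH": 1.679,
      "lnLCR": 0.775,
      "lnMAT30": 1.063,
      "lnMAP": -0.009
    },
    "standard_errors": {
      "cc_open_grown": 0.365,
      "cc_dominant": 0.052,
      "cc_codominant": 0.049,
      "cc_intermediate": 0.049,
      "cc_overtopped": 0.050,
      "lnDBH": 0.021,
      "lnLCR": 0.033,
      "lnMAT30": 0.129,
      "lnMAP": 0.044
    },
    "fit_reference": {"adj_r2": 0.80, "rmse": 0.62, "aic": 6809.51},
    "cv_reference": {
      "kfold": {"mpe": 49.26, "mae": 5.56, "mape": 72.81, "maape": 0.46},
      "loso": {"mpe": 51.49, "mae": 5.95, "mape": 78.74, "maape": 0.48}
    }
  },
  "eq6": {
    "intercept_mode": "crown_class",
    "terms": ["lnDBH", "lnLL", "lnLCR", "lnST", "lnMAT30", "lnMAP"],
    "coefficients": {
      "cc_open_grown": -11.100,
      "cc_dominant": -9.110,
      "cc_codominant": -11.046,
      "cc_intermediate": -11.301,
      "cc_overtopped": -11.473,
      "lnDBH": 1.692,
      "lnLL": 0.346,
      "lnLCR": 0.748,
      "lnST": 0.254,
      "lnMAT30": 2.198,
      "lnMAP": -0.156
    },
    "standard_errors": {
      "cc_open_grown": 0.329,
      "cc_dominant": 0.045,
      "cc_codominant": 0.042,
      "cc_intermediate": 0.043,
      "cc_overtopped": 0.043,
      "lnDBH": 0.017,
      "lnLL": 0.009,
      "lnLCR": 0.028,
      "lnST": 0.024,
      "lnMAT30": 0.116,
      "lnMAP": 0.039
    },
    "fit_reference": {"adj_r2": 0.86, "rmse": 0.51, "aic": 5500.63},
    "cv_reference": {
      "kfold": {"mpe": 31.75, "mae": 4.79, "mape": 53.49, "maape": 0.39},
      "loso": {"mpe": 33.38, "mae": 5.08, "mape": 56.09, "maape": 0.41}
    }
  }
}
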