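{
  "description": "Published per-dose-group summary statistics (mean, SD or mean rank) for the ten TIC parameters of a three-dose-group rat mammary-tumour DCE-MRI study, with the printed omnibus statistics. The study text states 7 animals per group, but every printed F statistic (and the V_wash rank sums, which total 78 = 12*13/2) is internally consistent only with n = 4 per group; n_per_group below records the value the printed statistics imply. The E_wash row's printed group-3 SD is inconsistent with its printed F and is marked non-reconstructible.",
  "doses_mmol_per_kg": [0.2, 0.3, 0.5],
  "n_per_group": 4,
  "stated_n_per_group": 7,
  "parameters": {
    "s0": {
      "test": "anova",
      "means": [6541.874, 6503.018, 6333.638],
      "sds": [339.611, 126.257, 270.450],
      "printed_stat": 0.720,
      "printed_p": "0.513",
      "significant_pairs": [],
      "reconstructible": true
    },
    "e_first": {
      "test": "anova",
      "means": [1.197, 1.399, 1.557],
      "sds": [0.091, 0.048, 0.112],
      "printed_stat": 16.952,
      "printed_p": "0.001",
      "significant_pairs": [["0.2", "0.3"], ["0.2", "0.5"], ["0.3", "0.5"]],
      "reconstructible": true
    },
    "v_first": {
      "test": "anova",
      "means": [99.753, 115.093, 124.590],
      "sds": [2.717, 2.355, 3.768],
      "printed_stat": 69.483,
      "printed_p": "<0.001",
      "significant_pairs": [["0.2", "0.3"], ["0.2", "0.5"], ["0.3", "0.5"]],
      "reconstructible": true
    },
    "s_max": {
      "test": "anova",
      "means": [15700.428, 16150.568, 17519.888],
      "sds": [307.323, 211.007, 239.868],
      "printed_stat": 54.838,
      "printed_p": "<0.001",
      "significant_pairs": [["0.2", "0.3"], ["0.2", "0.5"], ["0.3", "0.5"]],
      "reconstructible": true
    },
    "t_peak": {
      "test": "anova",
      "means": [137.000, 129.750, 129.750],
      "sds": [41.012, 27.765, 27.765],
      "printed_stat": 0.065,
      "printed_p": "0.937",
      "significant_pairs": [],
      "reconstructible": true
    },
    "e_max": {
      "test": "anova",
      "means": [1.404, 1.484, 1.777],
      "sds": [0.116, 0.066, 0.138],
      "printed_stat": 12.510,
      "printed_p": "0.003",
      "significant_pairs": [["0.2", "0.5"], ["0.3", "0.5"]],
      "reconstructible": true
    },
    "v_max": {
      "test": "anova",
      "means": [70.497, 76.497, 88.616],
      "sds": [16.243, 13.487, 15.288],
      "printed_stat": 1.505,
      "printed_p": "0.273",
      "significant_pairs": [],
      "reconstructible": true
    },
    "e_wash": {
      "test": "anova",
      "means": [0.420, 0.378, 0.377],
      "sds": [0.057, 0.010, 0.498],
      "printed_stat": 5.248,
      "printed_p": "0.031",
      "significant_pairs": [["0.2", "0.5"]],
      "reconstructible": false,
      "note": "printed group-3 SD (0.498) is dimensionally implausible for a fraction and inconsistent with the printed F; carried as printed"
    },
    "v_wash": {
      "test": "kruskal-wallis",
      "mean_ranks": [8.250, 5.750, 5.500],
      "printed_stat": 1.423,
      "printed_p": "0.319",
      "significant_pairs": [],
      "reconstructible": true
    },
    "ser": {
      "test": "anova",
      "means": [3.216, 2.584, 1.839],
      "sds": [0.702, 0.257, 0.162],
      "printed_stat": 9.733,
      "printed_p": "0.006",
      "significant_pairs": [["0.2", "0.5"], ["0.3", "0.5"]],
      "reconstructible": true
    },
    "slope_wash": {
      "test": "anova",
      "means": [-186.778, -164.766, -150.448],
      "sds": [44.917, 17.532, 10.243],
      "printed_stat": 1.654,
      "printed_p": "0.244",
      "significant_pairs": [],
      "reconstructible": true
    }
  }
}
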