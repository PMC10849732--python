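{
  "seed": 1,
  "stages": {
    "expression": {
      "thresholds": [
        {
          "n_deg": 15,
          "threshold_pct": 0,
          "universe_size": 300
        },
        {
          "n_deg": 9,
          "threshold_pct": 1,
          "universe_size": 218
        },
        {
          "n_deg": 8,
          "threshold_pct": 3,
          "universe_size": 192
        },
        {
          "n_deg": 7,
          "threshold_pct": 5,
          "universe_size": 156
        },
        {
          "n_deg": 5,
          "threshold_pct": 10,
          "universe_size": 126
        },
        {
          "n_deg": 0,
          "threshold_pct": 30,
          "universe_size": 52
        },
        {
          "n_deg": 0,
          "threshold_pct": 50,
          "universe_size": 32
        }
      ]
    },
    "group_stats": {
      "impulse_dff_anova_F": 0.08872,
      "impulse_dff_anova_p": 0.766875
    },
    "scoring": {
      "null": {
        "impulse_responsive_fraction": 0.666667,
        "mean_dff_down": 1.262866,
        "mean_dff_up": 1.248867,
        "n_neurons": 30,
        "subtype_fractions": {
          "nose_down": 0.466667,
          "nose_up": 0.466667,
          "untuned": 0.066667
        },
        "subtype_recovery_accuracy": 1.0
      },
      "sibling_pool": {
        "impulse_responsive_fraction": 0.7,
        "mean_dff_down": 1.259129,
        "mean_dff_up": 1.261655,
        "n_neurons": 30,
        "subtype_fractions": {
          "nose_down": 0.533333,
          "nose_up": 0.433333,
          "untuned": 0.033333
        },
        "subtype_recovery_accuracy": 1.0
      }
    },
    "topography": {
      "bootstrap_mean_of_means": 21.091692,
      "cross_genotype_ks": {
        "x_um": {
          "D": 0.166667,
          "p": 0.739538
        },
        "y_um": {
          "D": 0.233333,
          "p": 0.334069
        },
        "z_um": {
          "D": 0.133333,
          "p": 0.920503
        }
      },
      "subtype_manova_p": 2.3e-05,
      "subtype_manova_wilks": 0.387049
    }
  }
}
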