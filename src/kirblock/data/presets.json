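{
  "version": "1.0",
  "comment": "Kinetic parameter presets. Blocker rate parameters for the wild-type channel; genotypes are positive multipliers on those parameters. WT, E224G, M183W and E224G/M183W unblocking pairs follow the published Woodhull parameters for Mg2+ block; theta values are calibrated so the closed-form Kd(-30)/Kd(+30) ratio in symmetric 100 mM K+ equals ~95 (Mg) and ~1.02e5 (SPM). All other multipliers are plausible synthetic values; see docs/methods.md.",
  "blockers": {
    "Mg": {
      "valence": 2,
      "kon0": 18428571.4285714,
      "delta_on": 0.075,
      "koff0": 4300.0,
      "zdelta_off": 0.48,
      "theta": 3.155384,
      "vs": 15.0,
      "kexit0": 0.0,
      "zdelta_exit": 0.0
    },
    "SPM": {
      "valence": 4,
      "kon0": 10000000.0,
      "delta_on": 0.06,
      "koff0": 30.0,
      "zdelta_off": 2.32,
      "theta": 7.412613,
      "vs": 15.0,
      "kexit0": 0.0005,
      "zdelta_exit": 2.2
    }
  },
  "genotypes": {
    "WT": {},
    "E224G": {"kon0": 0.0651163, "koff0": 0.0860465, "zdelta_off": 1.1666667, "theta": 0.0},
    "E224Q": {"kon0": 0.02, "koff0": 0.02, "zdelta_off": 1.375, "theta": 0.0},
    "E224A": {"kon0": 0.09, "koff0": 0.09, "zdelta_off": 1.35, "theta": 0.0},
    "E224C": {"kon0": 0.075, "koff0": 0.075, "zdelta_off": 1.42, "theta": 0.0},
    "E299S": {"kon0": 0.08, "koff0": 0.08, "zdelta_off": 1.38, "theta": 0.0},
    "E299A": {"kon0": 0.12, "koff0": 0.12, "zdelta_off": 1.33, "theta": 0.0},
    "E299C": {"kon0": 0.10, "koff0": 0.10, "zdelta_off": 1.44, "theta": 0.0},
    "M183W": {"kon0": 0.6511628, "koff0": 0.6511628, "zdelta_off": 0.9583333, "theta": 0.3},
    "M183N": {"kon0": 0.8, "koff0": 1.2, "theta": 0.0},
    "M183C": {"kon0": 0.8, "koff0": 1.15, "theta": 0.3},
    "G177N": {"kon0": 0.5, "theta": 0.0},
    "I176C": {"kon0": 0.7, "koff0": 1.1, "theta": 0.35},
    "I176T": {"kon0": 0.75, "koff0": 1.05, "theta": 0.3},
    "A178C": {"kon0": 0.6, "koff0": 1.1, "theta": 0.3},
    "V179C": {"kon0": 0.85, "theta": 0.4},
    "A181T": {"kon0": 0.9, "theta": 0.5},
    "D172N": {"koff0": 2.0},
    "A184Q": {"koff0": 3.0},
    "E224G/M183W": {"kon0": 0.0534884, "koff0": 0.0534884, "zdelta_off": 1.2916667, "theta": 0.0},
    "E224G/G177N": {"kon0": 0.0325582, "koff0": 24.481645, "zdelta_off": 1.1666667, "theta": 0.0},
    "E224G/M183N": {"kon0": 0.0520930, "koff0": 16.787414, "zdelta_off": 1.1666667, "theta": 0.0},
    "E224G/D172N": {"kon0": 0.0651163, "koff0": 0.1720930, "zdelta_off": 1.1666667, "theta": 0.0},
    "E224G/A184Q": {"kon0": 0.0651163, "koff0": 0.2581395, "zdelta_off": 1.1666667, "theta": 0.0},
    "E224Q/M183W": {"kon0": 0.15, "koff0": 0.15, "zdelta_off": 1.33, "theta": 0.0},
    "E224Q/M183N": {"kon0": 0.25, "koff0": 0.25, "zdelta_off": 1.30, "theta": 0.0},
    "E224Q/A178C": {"kon0": 0.35, "koff0": 0.35, "zdelta_off": 1.28, "theta": 0.0}
  }
}
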