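{
  "comment": "Published PLS and external-validation statistics for the CoMFA and CoMSIA models of the 26-compound TRPA1 agonist series. These are the printed reference constants; the package recomputes its own statistics from the activity/prediction table and from refit models.",
  "n_train": 21,
  "n_test": 5,
  "comfa": {
    "r2_cv": 0.631,
    "r2": 0.986,
    "onc": 6,
    "see": 0.154,
    "f_value": 160.559,
    "field_contributions": {"steric": 0.541, "electrostatic": 0.459},
    "r2_pred": 0.967,
    "slope_k": 0.984,
    "r0_sq": 0.984,
    "rm_sq": 0.942,
    "ratio": 0.002
  },
  "comsia": {
    "r2_cv": 0.542,
    "r2": 0.981,
    "onc": 6,
    "see": 0.180,
    "f_value": 117.466,
    "field_contributions": {"steric": 0.146, "electrostatic": 0.403, "hydrophobic": 0.160, "donor": 0.075, "acceptor": 0.215},
    "r2_pred": 0.981,
    "slope_k": 0.988,
    "r0_sq": 0.988,
    "rm_sq": 0.899,
    "ratio": -0.007
  }
}
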