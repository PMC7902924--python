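{
  "_comment": "Published calibrated parameter sets per model and condition. The PVL and PVL-2 rows are identical in both conditions in the source table and are transcribed verbatim.",
  "low": {
    "ev": {"recency_a": 0.771, "loss_weight_w": 0.079, "consistency_c": 0.282},
    "evpu": {"shape_alpha": 0.931, "loss_aversion_lambda": 1.0, "consistency_c": 1.0, "recency_A": 1.0},
    "pvl": {"shape_alpha": 0.557, "loss_aversion_lambda": 2.204, "consistency_c": 0.311, "recency_A": 0.748},
    "pvl2": {"shape_alpha": 0.557, "loss_aversion_lambda": 2.204, "consistency_c": 0.311, "recency_A": 0.748},
    "random": {}
  },
  "high": {
    "ev": {"recency_a": 0.115, "loss_weight_w": 0.728, "consistency_c": 0.819},
    "evpu": {"shape_alpha": 0.88, "loss_aversion_lambda": 0.129, "consistency_c": -0.836, "recency_A": 0.954},
    "pvl": {"shape_alpha": 0.851, "loss_aversion_lambda": 4.797, "consistency_c": 0.789, "recency_A": 0.099},
    "pvl2": {"shape_alpha": 0.851, "loss_aversion_lambda": 4.797, "consistency_c": 0.789, "recency_A": 0.099},
    "random": {}
  }
}
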