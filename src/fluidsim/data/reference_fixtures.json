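{
  "table1_counts": {
    "description": "Reported numerical composition of the five-target secondary-pharmacology datasets: (total, inactive, active) per target per dataset column.",
    "provenance": "reported",
    "columns": ["train", "test", "federated_comp", "federated_ft", "public"],
    "targets": {
      "AChM1R": {
        "train": [3811, 2829, 982],
        "test": [876, 745, 131],
        "federated_comp": [20000, 10000, 10000],
        "federated_ft": [20000, 10000, 10000],
        "public": [2191, 1288, 903]
      },
      "GABA_A": {
        "train": [3614, 3216, 398],
        "test": [877, 819, 58],
        "federated_comp": [20000, 10000, 10000],
        "federated_ft": [20000, 14915, 5085],
        "public": [2433, 1645, 788]
      },
      "5HT2B": {
        "train": [3374, 2447, 927],
        "test": [876, 709, 167],
        "federated_comp": [20000, 10000, 10000],
        "federated_ft": [20000, 10000, 10000],
        "public": [1506, 685, 821]
      },
      "hERG": {
        "train": [2285, 1388, 897],
        "test": [556, 309, 247],
        "federated_comp": [20000, 10000, 10000],
        "federated_ft": [20000, 10000, 10000],
        "public": [8298, 4157, 4141]
      },
      "COX2": {
        "train": [3042, 2815, 227],
        "test": [881, 809, 72],
        "federated_comp": [20000, 12233, 7767],
        "federated_ft": [20000, 10535, 9465],
        "public": [3228, 1545, 1683]
      }
    },
    "reported_ratios": {
      "hERG.train": 1.55,
      "hERG.test": 1.25,
      "GABA_A.test": 14.12,
      "GABA_A.public": 2.09,
      "5HT2B.public": 0.83,
      "GABA_A.federated_ft": 2.93,
      "COX2.federated_ft": 1.11,
      "COX2.federated_comp": 1.58
    }
  },
  "fillrule_gaba": {
    "description": "Federated-set fill-rule worked example: 5,085 eligible positives, abundant negatives, per-class target 10,000.",
    "provenance": "reported",
    "eligible_pos": 5085,
    "eligible_neg": 30000,
    "n_per_class": 10000,
    "expected_pos": 5085,
    "expected_neg": 14915,
    "expected_total": 20000,
    "expected_ratio": 2.93
  },
  "fillrule_cox2_ft": {
    "description": "Federated-set fill-rule worked example: 9,465 eligible positives, abundant negatives, per-class target 10,000.",
    "provenance": "reported",
    "eligible_pos": 9465,
    "eligible_neg": 30000,
    "n_per_class": 10000,
    "expected_pos": 9465,
    "expected_neg": 10535,
    "expected_total": 20000,
    "expected_ratio": 1.11
  },
  "fillrule_cox2_comp": {
    "description": "Federated-set fill-rule worked example: 7,767 eligible positives, abundant negatives, per-class target 10,000.",
    "provenance": "reported",
    "eligible_pos": 7767,
    "eligible_neg": 30000,
    "n_per_class": 10000,
    "expected_pos": 7767,
    "expected_neg": 12233,
    "expected_total": 20000,
    "expected_ratio": 1.58
  },
  "mcc_micro": {
    "description": "Hand confusion tables with closed-form MCC values.",
    "provenance": "derived",
    "cases": [
      {"TP": 50, "TN": 50, "FP": 0, "FN": 0, "mcc": 1.0, "provenance": "trivial"},
      {"TP": 0, "TN": 0, "FP": 50, "FN": 50, "mcc": -1.0, "provenance": "trivial"},
      {"TP": 30, "TN": 40, "FP": 10, "FN": 20, "mcc": 0.408248290463863, "provenance": "derived"},
      {"TP": 0, "TN": 100, "FP": 0, "FN": 0, "mcc": 0.0, "provenance": "trivial"}
    ]
  }
}
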