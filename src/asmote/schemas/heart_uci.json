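{
  "description": "UCI Heart Disease (Cleveland) layout: 13 clinical features plus the binary disease indicator 'num'.",
  "target": "num",
  "positive_label": "YES",
  "negative_label": "NO",
  "columns": [
    {"name": "age", "kind": "continuous"},
    {"name": "sex", "kind": "categorical", "categories": [0, 1]},
    {"name": "cp", "kind": "categorical", "categories": [1, 2, 3, 4]},
    {"name": "trestbps", "kind": "continuous"},
    {"name": "chol", "kind": "continuous"},
    {"name": "fbs", "kind": "categorical", "categories": [0, 1]},
    {"name": "restecg", "kind": "categorical", "categories": [0, 1, 2, 3, 4]},
    {"name": "thalach", "kind": "continuous"},
    {"name": "exang", "kind": "categorical", "categories": [0, 1]},
    {"name": "oldpeak", "kind": "continuous"},
    {"name": "slope", "kind": "categorical", "categories": [1, 2, 3]},
    {"name": "ca", "kind": "categorical", "categories": [0, 1, 2, 3]},
    {"name": "thal", "kind": "categorical", "categories": [3, 6, 7]}
  ]
}
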