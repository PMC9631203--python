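# Pinned hyperparameters for the ten benchmark classifier families.
# Values are the widely used library defaults, written out explicitly so
# reports stay reproducible across library upgrades.  Every model is wrapped
# in a StandardScaler pipeline (harmless for trees, required for the
# scale-sensitive families).
XGBoost:
  n_estimators: 100
  max_depth: 6
  learning_rate: 0.3
  eval_metric: logloss
LightGBM:
  n_estimators: 100
  num_leaves: 31
  learning_rate: 0.1
  verbose: -1
RandomForest:
  n_estimators: 100
ExtraTrees:
  n_estimators: 100
GaussianNB: {}
KNN:
  n_neighbors: 5
LogisticRegression:
  C: 1.0
  max_iter: 1000
DecisionTree: {}
SVM:
  C: 1.0
  kernel: rbf
  gamma: scale
LDA:
  solver: svd
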