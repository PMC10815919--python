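# Frequentist baseline configurations for the comparative table.
# Parameter names are the canonical scikit-learn / xgboost keyword arguments;
# the comments note the published wording each value was transcribed from.
sgd_linear:
  learning_rate: adaptive      # "learning rate: adaptive"
  power_t: 0.899               # "inverse scaling factor: 0.899"
  alpha: 0.890                 # "regularization parameter: 0.890"
huber:
  epsilon: 4.0                 # "k: 4" read as the Huber-loss robustness threshold
gradient_boosted_trees:
  subsample: 0.8
  n_estimators: 1800
  min_child_weight: 6          # "minimum child weight: 6"
  max_depth: 68
  learning_rate: 0.01
  colsample_bytree: 0.2        # "column sample by tree: 0.2"
  booster: gbtree
  reg_alpha: 0.8               # "alpha: 0.8"
  reg_lambda: 0.8              # "lambda: 0.8"
  # "minimum sample split: 5", "minimum samples leaf: 4" and "maximum
  # features: auto" have no xgboost counterpart and are not mapped.
random_forest:
  n_estimators: 1200
  min_samples_split: 10
  min_samples_leaf: 4
  max_features: sqrt
  max_depth: 20
  bootstrap: false
lasso:
  alpha: 0.01                  # "λ: 0.01"
ridge:
  alpha: 1.08                  # "λ: 1.08"
svr_poly:
  kernel: poly
  degree: 2
  C: 0.3                       # "regularization: 0.3" read as the penalty C
ols: {}                        # multiple linear regression: no hyperparameters
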