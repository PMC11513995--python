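# Hyperparameter grids for the classic-ML regressor families, editable.
# Pass one family's grid to metagraph.baseline.tune_estimator.
svm:
  C: [0.1, 1.0, 10.0, 100.0]
  epsilon: [0.01, 0.1, 1.0]
  kernel: [rbf, linear]
random_forest:
  n_estimators: [100, 300]
  max_depth: [null, 10, 30]
  min_samples_leaf: [1, 3]
gradient_boosting:
  n_estimators: [100, 300]
  learning_rate: [0.03, 0.1]
  max_depth: [2, 3]
knn:
  n_neighbors: [3, 5, 9]
  weights: [uniform, distance]
gaussian_process:
  alpha: [1.0e-10, 1.0e-2, 1.0]
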