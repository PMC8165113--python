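# Pinned "default" hyperparameters for the prediction bench, versioned here
# so results do not drift with library releases.
logistic:
  max_iter: 1000
knn:
  n_neighbors: 5
naive_bayes: {}
gradient_boosted_trees:
  n_estimators: 100
  learning_rate: 0.1
  max_depth: 3
random_forest:
  n_estimators: 100
# early stopping is deliberately off: with ~60 training samples the 10%
# validation split it carves out is too small to be a stopping signal
deep_net:
  hidden_layer_sizes: [64]
  early_stopping: false
  max_iter: 2000
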