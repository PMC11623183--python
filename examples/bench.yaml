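# Example benchmark configuration for `semsgd benchmark`.
# `grid: paper` expands to the 12-cell design
# {(2,4),(10,20),(20,40)} x sigma {0.1, 1.0} x n {100, 1000}.
seed: 1
protocol: unified
n_reps: 10
standardize: true
grid: paper
sgd:
  - {init: 2sls, learning_rate: 0.01, n_iterations: 5000}
  - {init: rnd,  learning_rate: 0.01, n_iterations: 5000}
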