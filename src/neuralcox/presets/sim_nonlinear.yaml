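# Simulated nonlinear (Gaussian) experiment
n_layers: 3
n_nodes: 17
activation: relu
optimizer: sgd_nesterov
learning_rate: 3.194e-4
lr_decay: 3.173e-4
momentum: 0.936
l2: 4.425
dropout: 0.401
n_epochs: 2000
seed: 0
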