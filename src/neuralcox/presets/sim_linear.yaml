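# Simulated linear experiment
n_layers: 1
n_nodes: 4
activation: selu
optimizer: sgd_nesterov
learning_rate: 2.922e-4
lr_decay: 3.579e-4
momentum: 0.906
l2: 1.999
dropout: 0.375
n_epochs: 2000
seed: 0
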