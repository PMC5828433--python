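# METABRIC breast-cancer cohort
n_layers: 1
n_nodes: 41
activation: selu
optimizer: adam
learning_rate: 0.010
lr_decay: 4.169e-3
momentum: 0.844
l2: 10.891
dropout: 0.160
n_epochs: 2000
seed: 0
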