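# Rotterdam / German Breast Cancer Study Group
n_layers: 1
n_nodes: 8
activation: selu
optimizer: adam
learning_rate: 0.154
lr_decay: 5.667e-3
momentum: 0.887
l2: 6.551
dropout: 0.661
n_epochs: 2000
seed: 0
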