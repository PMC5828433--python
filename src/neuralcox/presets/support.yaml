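# SUPPORT study
n_layers: 1
n_nodes: 44
activation: selu
optimizer: adam
learning_rate: 0.047
lr_decay: 2.573e-3
momentum: 0.859
l2: 8.120
dropout: 0.255
n_epochs: 2000
seed: 0
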