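# Worcester Heart Attack Study
n_layers: 2
n_nodes: 48
activation: relu
optimizer: adam
learning_rate: 0.067
lr_decay: 6.494e-4
momentum: 0.863
l2: 16.094
dropout: 0.147
n_epochs: 2000
seed: 0
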