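# Simulated treatment experiment
n_layers: 1
n_nodes: 45
activation: selu
optimizer: adam
learning_rate: 0.026
lr_decay: 1.636e-4
momentum: 0.845
l2: 9.722
dropout: 0.109
n_epochs: 2000
seed: 0
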