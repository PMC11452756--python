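# Desk-scale HAN configuration (single-CPU training).
embed_dim: 96
word_hidden: 48
sent_hidden: 48
batch_size: 32
lr: 0.012
lr_decay: 0.97
max_epochs: 45
patience: 12
threshold_t: 0.5
seed: 1
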