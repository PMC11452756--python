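# Desk-scale generative-coder configuration (single-CPU training).
max_seq_len: 128
embed_dim: 64
n_layers: 2
n_heads: 4
batch_size: 16
lr: 0.001
epochs: 10
seed: 3
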