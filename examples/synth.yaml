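# Synthetic corpus settings (defaults shown; override as needed).
num_codes: 50
vocab_noise: 500
zipf_exponent: 1.2
mean_codes_per_doc: 4.4
keyword_emit_prob: 0.95
n_docs: 2000
split_fracs: [0.8, 0.1, 0.1]
seed: 11
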