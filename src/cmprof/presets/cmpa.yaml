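# CM profile only.
w_mut: 0.0
w_sec: 0.0
w_cor: 1.0
d0: 2.8
alpha: 0.025
base: 0.5
g_open: 7.0
g_ext: 1.7
cor_aggregate: mean
base_sign: -1
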