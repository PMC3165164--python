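# CM profile + sequence profile.
w_mut: 1.0
w_sec: 0.0
w_cor: 0.5
d0: 3.2
alpha: 0.025
base: 1.0
g_open: 8.0
g_ext: 0.4
cor_aggregate: mean
base_sign: -1
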