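# Profile-profile alignment, sequence profile only.
w_mut: 1.0
w_sec: 0.0
w_cor: 0.0
d0: 3.2
alpha: 0.025
base: 0.5
g_open: 6.0
g_ext: 0.5
cor_aggregate: mean
base_sign: -1
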