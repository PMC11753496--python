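variant,v_C_per_min,tm_C,tm_se_C
M,0.5,56.5,0.3
M,1,58.6,0.1
M,2,61.4,0.1
M,4,63.0,0.1
G192C,0.5,52.7,0.2
G192C,1,54.5,0.4
G192C,2,57.4,0.3
G192C,4,58.0,0.5
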