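genotype,n_case,n_control
CC,163,219
TC,508,541
TT,444,367
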