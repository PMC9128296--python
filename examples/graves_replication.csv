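genotype,n_case,n_control
CC,471,584
TC,1606,1344
TT,1298,957
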