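trait_type: qualitative
n: 500
maf: 0.3
rho: 0.0
lambda2: 2.0
gamma: random
replicates: 500
seed: 12345
alpha: 0.05
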