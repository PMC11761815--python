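# Moment-accuracy check: empirical vs closed-form mean/variance/skewness
# of simulated g (variable study sizes, one million studies).
kind: table1
n_studies: 1000000
mode: variable
mu_delta: 0.5
tau2: 0.1
seed: 1
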