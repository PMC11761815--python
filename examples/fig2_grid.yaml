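# Estimator-performance grid: bias/variance/RMSE/coverage of the
# mixture-model, DL and REML estimators, 2,000 replicates per condition.
kind: grid
tau2_values: [0.1, 0.3, 0.5, 0.7, 0.9]
k_values: [15, 30, 45]
mu_delta: 0.5
n_replicates: 2000
seed: 1
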