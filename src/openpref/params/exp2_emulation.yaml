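# Package-calibrated Experiment 2 emulation set (see exp1_emulation.yaml and
# docs/methods.md): reported mixing weight and decay rate, rates calibrated
# to the faster, front-loaded dynamics the 0.458 1/s decay implies.
mu_Q: 10.0
sigma_Q: 22.0
mu_M: 0.11
sigma_M: 0.15
alpha: 0.641
lambda: 0.458
s_v: 10.0
n: 21
S_max: 10.0
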