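# Reference parameter estimates for Experiment 2 (open-system model), as
# reported with the original fits. See the note in table3_exp1.yaml and
# docs/methods.md; use exp2_emulation.yaml to simulate experiment-like data.
mu_Q: 633.8
sigma_Q: 17.9
mu_M: 18.3
sigma_M: 25.1
alpha: 0.641
lambda: 0.458
s_v: 10.0
n: 21
S_max: 10.0
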