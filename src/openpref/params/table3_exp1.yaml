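# Reference parameter estimates for Experiment 1 (open-system model) as
# reported with the original fits. Under this package's literal level-ladder
# rate convention these values drive the n=21 state to its boundary
# equilibrium within the first stage (see docs/methods.md, "Parameter
# conventions"); use exp1_emulation.yaml to simulate experiment-like data.
mu_Q: 226.8
sigma_Q: 10.6
mu_M: 28.5
sigma_M: 122.5
alpha: 0.285
lambda: 0.014
s_v: 10.0
n: 21
S_max: 30.0
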