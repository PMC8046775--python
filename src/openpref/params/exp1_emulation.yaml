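# Package-calibrated Experiment 1 emulation set: mixing weight, decay rate,
# level count, scale maximum and start-point spread follow the reported
# estimates; the four drift/diffusion rates are calibrated once to the
# experiment's dynamic regime (oscillating mean strength across the 3-45 s
# delays, measurable choice/no-choice divergence). See docs/methods.md.
mu_Q: 0.10
sigma_Q: 4.0
mu_M: 0.009
sigma_M: 0.040
alpha: 0.285
lambda: 0.014
s_v: 10.0
n: 21
S_max: 30.0
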