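# Methods

`openpref` implements an open-system model of constructed preference: a
hybrid of a continuous-time Markov random walk and a quantum walk over a
discrete ladder of latent preference levels, together with the statistical
layer used to analyse preference-strength data (Bayesian polynomial
regression, Bayesian t-tests, Gaussian-process regression with credible
bands) and trial-level synthetic-data generators for the two experimental
designs the model was built to explain.

## The model

**State.** Preference between two options is represented on `n` (odd,
default 21) latent levels; level 1 means "definitely prefer the left
option", level `n` "definitely prefer the right", and the midpoint
`mid = (n+1)/2` is neutral. The state is an `n x n` density matrix `rho`
combining *epistemic* uncertainty (a classical mixture over pure states)
with *ontic* uncertainty (each pure state is a complex amplitude profile
over levels that holds several potential responses at once). The diagonal
of `rho` is the probability of each rating level.

**Dynamics.** The state evolves by

    d rho/dt = -i (1 - alpha) [H, rho] + alpha * L(rho)

with a tridiagonal Hamiltonian `H` (diagonal `j * mu_Q`, a linear potential
whose slope drives preference toward one side; off-diagonals `sigma_Q`,
which disperse amplitude) and a Lindblad dissipator `L` whose jump
operators are the unit matrices `E_ij` with rates taken from the
off-diagonal band of the classical intensity matrix `K` (up-rate
`sigma_M + mu_M`, down-rate `sigma_M - mu_M`, columns summing to zero).
This rate assignment is the unique one for which `alpha = 1` makes the
diagonal of `rho` follow the classical master equation `dp/dt = K p`
exactly; `alpha = 0` is pure von Neumann (quantum-walk) dynamics. The
constraint `sigma_M >= |mu_M|` keeps all jump rates nonnegative and is
enforced at construction and, inside fitting, by the reparameterisation
`mu_M = sigma_M * tanh(theta)`.

**Propagation.** The flattened master equation is solved by matrix
exponential. Because the generator preserves Hermiticity it is real in an
orthonormal Hermitian-matrix basis; we eigendecompose that real `n^2 x n^2`
matrix once per parameter set and reuse the cached decomposition for every
duration, so a full two-condition trajectory costs one decomposition plus a
few small matrix products. After each propagation the state is
symmetrised; the trace is renormalised only when floating-point drift
exceeds 1e-10. Validity (Hermiticity, unit trace, positive semidefiniteness
to 1e-8) is asserted by `validate_density` and exercised across random
parameter draws in the test suite.

**Measurement.** A binary choice splits the ladder at the midpoint: the
right-choice operator has ones above `mid`, the left-choice operator ones
below, and both carry `sqrt(1/2)` at `mid`, so the neutral level sends half
its population to each side and `P_L^2 + P_R^2 = I`. Choice probabilities
are `Pr(R) = Tr(P_R rho P_R)`. An observed choice collapses the state by
the two-sided (Lüders) rule `P rho P / Pr` — the one-sided form found in
some write-ups leaves a coherent state non-Hermitian, while the Lüders form
reproduces the same probabilities and keeps the state valid. Note these
operators are projectors only away from the midpoint: with `sqrt(1/2)` at
`mid`, repeated collapse keeps halving the midpoint population before
renormalising, so exact idempotence holds only for states without midpoint
mass (the tests pin both behaviours).

**Timing and decay.** A trial evolves for the first stage (stimulus onset
to first response), is collapsed in the choice condition (untouched in
no-choice), and then evolves for the rating delay, rescaled for attention
decay. Two clock conventions are provided. The default, `post_response`,
rescales the delay itself: `tau = d * exp(-lambda * d)` with
`d = t2 - t1`. The `literal` option rescales the absolute rating time,
`tau2 = t2 * exp(-lambda * d)`, as printed in the original description;
at large decay rates that expression places the effective rating time
*before* the first response (with `lambda = 0.458` and `t1 = 5 s`, any
delay beyond ~1.5 s yields `tau2 < t1`), so the literal mode floors the
second-stage duration at zero and the causality-preserving post-response
clock is the default. Every fit records which convention produced it.

**Read-out.** Rating level `j` is observed with probability `rho[j, j]`;
the strength (absolute distance from the scale midpoint, in rating points)
assigned to level `j` is the logistic map
`S_j = S_max / (1 + exp(-|j - mid|))`, so model strengths lie in
`[S_max/2, S_max)`. Choice-condition predictions pool the two collapsed
branches with the model-implied response probabilities.

## Identifiability: the mixing weight is a gauge parameter

The generator is linear in its rate parameters, so only the products

    (1 - alpha) * mu_Q,  (1 - alpha) * sigma_Q,  alpha * mu_M,  alpha * sigma_M

and the decay rate `lambda` reach the dynamics. Any interior mixing weight
can be traded exactly against a rescaling of the four rates: the map
`(mu_Q, sigma_Q) -> (1-alpha)/(1-alpha') * (mu_Q, sigma_Q)`,
`(mu_M, sigma_M) -> alpha/alpha' * (mu_M, sigma_M)` carries a model at
`alpha` onto an identical model at any `alpha'` in (0, 1) (verified
numerically to 6e-14 in the test suite). Consequences:

- `alpha` cannot be estimated from mean-strength trajectories. Fitting it
  freely walks an exact ridge, and a reported interior estimate reflects
  where the optimizer happened to stop, not a property of the data. The
  pure cases `alpha = 0` and `alpha = 1` remain structurally distinct
  (they lose one component entirely), so *nested comparisons* of the three
  variants are meaningful even though the interior value of `alpha` is not.
- Open-variant fits therefore pin `alpha` at the gauge value 0.5 by
  default, which spans the identical model family with five
  well-conditioned parameters; results report the identifiable effective
  rates above. A `gauge="free"` mode retains the six-parameter search for
  comparison.

## Parameter conventions and the emulation sets

The package ships the originally reported open-system estimates verbatim
(`table3_exp1.yaml`, `table3_exp2.yaml`). Interpreted in this package's
units — per-level rates per second with the printed matrix stencils — those
values (drifts and diffusions of order 10–600 /s on a 21-level ladder)
drive the state to the intensity matrix's boundary-tilted equilibrium well
within the 5 s first stage, predicting flat strength trajectories at
~29.8/30 points for both conditions at every delay; and no uniform
rescaling of rates or time fixes this, because the printed
`sigma_Q / mu_Q` ratio (~0.05) suppresses population transfer at any time
scale (the linear potential localises the walk). We conclude those
estimates were obtained under a different internal grid/unit convention
that the printed equations do not determine, and we treat them as
reference values only.

For simulation and recovery the package defines *emulation* parameter sets
(`exp1_emulation.yaml`, `exp2_emulation.yaml`) that keep the reported
mixing weight, decay rate, level count, scale maximum and start-point
spread, and set the four rates — once, against the experiments' descriptive
phenomenology, before any recovery testing — to values that produce that
phenomenology under the literal convention: mean strength oscillating with
roughly two reversals across Experiment 1's 3–45 s delays, a measurable
choice/no-choice divergence (a few tenths of a point to ~1 point), and for
Experiment 2 faster, front-loaded dynamics (its decay rate of 0.458 /s
caps the effective second-stage time at `1/(lambda e) ~ 0.8 s`, so delay
structure is concentrated below ~12 s, consistent with the reported
acceleration of effects there).

- Experiment 1 emulation: `mu_Q = 0.10`, `sigma_Q = 4.0`, `mu_M = 0.009`,
  `sigma_M = 0.040`, `alpha = 0.285`, `lambda = 0.014`.
- Experiment 2 emulation: `mu_Q = 10.0`, `sigma_Q = 22.0`, `mu_M = 0.11`,
  `sigma_M = 0.15`, `alpha = 0.641`, `lambda = 0.458`.

`s_v` (initial truncated-normal spread) is fixed at half the width of the
level ladder, `(n-1)/2 = 10` levels; the initial weight profile is the
normal density evaluated at the integer levels and renormalised (no
continuous truncation integral — the difference vanishes after
normalisation at this spread). With so broad a start and the steep
logistic strength map, model strengths occupy the upper part of the scale
(~26–30 of 30 points); the synthetic data's absolute level and spread
therefore do not match the empirical means (~17) and SDs (~8.6) — under
the printed strength map no rating magnitude below `S_max/2` can occur.
This is an intrinsic property of the printed read-out, not of the
generator, and it does not affect recovery tests, which compare the
pipeline against its own generative model.

## Fitting

Fits minimise the summed squared difference between observed and predicted
per-condition mean strengths. Three variants: `markov` (`alpha = 1`;
free: `mu_M, sigma_M, lambda`), `quantum` (`alpha = 0`; free:
`mu_Q, sigma_Q, lambda`), `open` (gauge-pinned `alpha`; five free
parameters). `R^2` is computed against the pooled data mean, and adjusted
`R^2` penalises by the number of freed parameters (5 for the gauge-pinned
open variant, 3 for the pure variants).

The SSE surface of this model family is hostile: most of parameter space
predicts a flat trajectory (a plateau at the total-sum-of-squares level),
and the oscillatory fits live in narrow, curved, phase-matching valleys
that are aliased in the frequency-setting parameter `sigma_Q`. The
multistart procedure is built around that structure:

1. **Screening.** `n_starts` starts sampled in transformed coordinates
   (log rates, `tanh` drift ratio), with `sigma_Q` stratified over a log
   grid so every frequency decade is covered, plus a deterministic
   oscillation-dominant profile design (frequency grid x decay grid with
   quantum-dominant rate ratios). All are evaluated once and ranked.
2. **Valley descent.** The best few starts are polished by Nelder-Mead
   (robust on the rugged valley floor where finite-difference gradient
   steps stall on the surrounding plateau), then sharpened by
   trust-region least squares with a wide relative differencing step
   (1e-3; the spectral propagator's noise floor defeats square-root-of-eps
   steps).
3. **Restart.** Perturbation candidates around the incumbent plus a fresh
   descent from it.

Fits are deterministic given the seed. Recovery harnesses fit the model's
dense 1 s trajectory grid rather than only a handful of discrete delays:
six-point data are aliased in frequency and not reliably optimizable.
Even so, global convergence on noise-free data is not guaranteed within
desk-scale budgets; the recovery tests document which quantities (the
effective rates and `lambda`) are recovered and which are not
identifiable at all (`alpha`, per the gauge argument above).

## Statistical layer

- **Strength** is `|rating|`, validated against the scale bound.
- **Polynomial regression**: strength regressed on standardized powers of
  delay (`t^m / SD(t^m)`, so a raw coefficient is the standardized one
  divided by `SD(t^m)`), order 5 by default — high enough to express two
  oscillation cycles and saturated for a six-delay design. The Bayesian
  linear model uses a conjugate Normal–Inverse-Gamma prior: coefficients
  zero-mean with scale `10 * SD(y)` (weakly informative), residual
  variance Inverse-Gamma(1e-3, 1e-3). Conjugacy gives exact posterior
  draws from a seeded generator — no MCMC, bit-for-bit reproducible.
  Between-condition coefficient differences are formed from the two
  conditions' independent posteriors. HDIs are narrowest-interval
  (highest-density) at 95%.
- **Bayesian t-test**: each group gets the same conjugate model with an
  intercept only; the reported quantity is the posterior of the mean
  difference.
- **GPR**: an exact Gaussian-process posterior (squared-exponential
  kernel) over the delay -> mean-strength function, conditioned on
  per-delay condition means (1 s-binned for continuous designs).
  Hyperparameters are fixed by rule, never optimised: observation noise is
  the largest per-delay SEM (discrete designs) or the largest SEM in any
  10 s window stepped at 1 s (continuous designs); the amplitude is the
  variance of the per-delay means; the lengthscale is fit by least squares
  of `exp(-dt^2 / 2 l^2)` to within-subject correlations of strength
  between delay pairs (falling back to the median delay gap when no
  repeated measures exist); the prior mean is the grand mean. The 95%
  band is the pointwise +/-1.96 posterior SD of the latent function.
- **Divergence windows**: maximal grid intervals where one condition's
  posterior mean exits the other's 95% band, labelled *bolstering*
  (choice > no-choice) or *suppression* (no-choice > choice).
- **Effect sizes**: largest between-condition difference of the GPR means
  divided by the rating SD, and each condition's (max - min) range
  likewise. This is the plain-division reading; the original report's
  printed d for its between-condition difference does not equal
  difference/SD, and its exact computation is unstated, so the package
  reports its own transparent formula.
- **Running average**: mean strength within +/-3 s of each grid point
  (continuous-delay display); empty windows yield missing values.
- No multiple-comparison correction anywhere, mirroring the per-coefficient
  HDI / per-timepoint reporting style of the analyses this layer
  reproduces.

## Synthetic data

The generators emulate the two designs (sample sizes 105 and 62, trial
counts 48 and 160, the timing rules, scales, catch trials, and gamble
stimuli with payoff loosely negatively correlated with win probability).
Trial outcomes are drawn from the generative model itself — the model's
rating distribution is the only noise source; there is no participant
heterogeneity, no response-time model, and no extra observation noise.
Rating sign follows the drawn level's side of the midpoint (fair coin at
the midpoint); magnitudes are the rounded logistic strengths, so synthetic
rating magnitudes are confined to `[S_max/2, S_max]` (see above). A fixed
11% of simulated participants are "inattentive" and choose the dominated
catch-trial option with probability 0.75, producing exclusion rates
comparable to the ~11% observed in the first experiment; exclusion drops
participants with >= 2 dominated choices among their 4 catch trials. The
Experiment-2 incentive mapping (rating -> probability of playing the
right-hand gamble) and the gamble-playing draw (win when the uniform draw
is at least one minus the win probability) are implemented as printed.

Passing tests on these data show the pipeline is self-consistent
(generator and predictor agree; analyses recover planted structure); they
do not show that the model fits human data, and the synthetic data differ
from the real data in level and spread as noted above.

## Numerical choices

- Spectral propagation with a per-generator cached eigendecomposition;
  trace renormalisation threshold 1e-10; validity tolerance 1e-8.
- The Hamiltonian diagonal is centred before exponentiation (the intercept
  of the linear potential is dynamically irrelevant; centring improves
  conditioning at large drifts).
- Transformed-space clipping keeps `exp` finite during optimisation;
  failed or non-finite objective evaluations score as +1e6 per residual.
- Problem sizes in the test suite: unit tests of the fitting layer run at
  `n = 5` (the behaviour under test is level-count independent); dynamics
  validity and recovery tests run at the full `n = 21`. Statistical
  coverage checks use 200 replications.

## Known limitations

- `alpha` is not identifiable (gauge); reported interior estimates of it,
  here or elsewhere, are optimizer artifacts.
- Global optimisation of the oscillatory SSE surface is not guaranteed;
  recovery of the effective rates depends on the screening design finding
  the right frequency basin.
- The printed strength map bounds rating magnitudes below by `S_max/2`,
  so the synthetic data cannot reproduce the empirical rating SDs.
- The deposited study data are not bundled; the OSF-layout adapter is
  best-effort and validated only against common column spellings.
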