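# Methods

## Model

Each process *j* ∈ {1, 2} is a reversible continuous-time Markov chain on a
finite state space with generator `Q_j`: nonnegative off-diagonal
intensities `q_rs` for permitted transitions, zero row sums. The default
structure is the 3-state birth–death chain (adjacent moves only, moves to
higher-numbered states classified as deterioration), but the state space,
permitted transitions and the deterioration/improvement classification are
all explicit in `StateSpace`, so other structures are expressible.

Subject-level heterogeneity and between-process correlation enter through a
single positive frailty `U_i` with a Gamma(1/θ, 1/θ) distribution — mean
exactly 1, variance θ — multiplying the intensities through a link
`g_rs(u)` (variants `none`, `simple`, `inverse`, `power_inverse`,
`separate`; see the README table). Every variant satisfies g(1) = 1, so a
frailty of 1 recovers the baseline intensities; `power_inverse` with α = 1
coincides with `inverse` identically; `separate` replaces the shared
frailty with one independent frailty per process, so its likelihood
factorizes into two single-process frailty models.

Covariates act log-linearly on the intensities of the transitions they are
declared for, and are treated as piecewise-constant over each observation
interval at the value recorded at the interval's left endpoint — the usual
panel-data convention for dynamic covariates.

## Likelihood and numerics

States are observed only at visit times (panel observation). Given `u`, the
subject likelihood is the product over processes and intervals of
`[exp(Q_j(u) Δt)]_{x(t_k), x(t_{k+1})}`. Matrix exponentials use
scaling-and-squaring (`scipy.linalg.expm`); when many interval lengths share
one generator, a single eigendecomposition evaluates all of them at once,
with an automatic fallback to per-interval `expm` whenever the eigenvector
matrix is ill-conditioned or the reconstructed rows deviate from
stochasticity by more than 1e-8. A visit with a missing state for one
process is bridged: that process's interval runs to the next visit with an
observed state, leaving the other process untouched. Subjects with a single
visit are retained with likelihood contribution 0 (logged as a warning).

The frailty integral has no closed form for reversible panel models and is
evaluated numerically after the substitution `v = exp(−u)`, which maps
(0, ∞) onto (0, 1]. Two engines are exposed through `QuadratureOptions`:

- **adaptive** (default for one-off evaluations): `scipy.integrate.quad`
  with absolute tolerance 1e-9 and relative tolerance 1e-7, restricted to
  the v-image of the gamma distribution's [1e-12, 1 − 1e-12] quantile
  range. The truncation discards at most 2e-12 of prior mass and makes
  near-degenerate frailty distributions (θ → 0, a spike at u = 1 of width
  √θ) integrable by a generic adaptive rule.
- **fixed** (default inside `fit_mle`): 96-point Gauss–Legendre on (0, 1].
  Fixed nodes make the objective a smooth deterministic function of the
  parameters and let the cohort evaluator share transition-matrix batches
  across subjects: per likelihood evaluation, one generator per (node,
  process, covariate value) serves every subject, and per-subject
  log-likelihoods reduce to a sparse-matrix product over precomputed
  transition counts. For θ near 1 or above, the transformed integrand
  develops integrable endpoint singularities (the gamma shape 1/θ falls
  below 1) and the fixed rule loses accuracy; the adaptive engine remains
  the reference there.

Underflow over long series is controlled by scaling the integrand with the
maximum conditional log-likelihood over a coarse grid of gamma quantiles
before exponentiating, and flooring per-interval probabilities at 1e-300
before taking logs. Cohort log-likelihoods are ordered serial sums, so
results are independent of subject order and of splitting.

## Estimation

`fit_mle` maximizes the marginal likelihood by BFGS on a working scale: log
for intensities and θ (positivity, and the asymmetric natural-scale
intervals this induces match how such estimates are conventionally
reported), identity for α and covariate effects. Default starting values
are crude occurrence/exposure rates — transition counts divided by
person-time at risk in the origin state, floored at 0.01/year — with
θ₀ = 0.5 and α₀ = 1. The covariance of the working-scale estimates is the
inverse of a central-finite-difference Hessian (relative step 1e-4) of the
negative log-likelihood at the optimum; `wald_confint` exponentiates
log-scale intervals. A singular Hessian leaves the fit usable but flags
intervals unavailable. AIC is 2k − 2ℓ with k counted from the model
structure (intensities + covariate effects + variance parameters + α when
present); `lr_test` compares nested fits on the χ² scale.

## Occupancy times

The expected time in state r over [0, h] starting in r₁ is
`∫₀ʰ [exp(Qt)]_{r₁ r} dt`, computed **exactly** as the top-right block of
`expm([[Q, I], [0, 0]] · h)` — no time quadrature, so conservation (rows
summing to the horizon) holds to machine precision. Frailty averaging wraps
a one-dimensional adaptive quadrature over u (tolerance 1e-8, same
quantile-restricted v-substitution) around this exact time integral.

Joint states of two conditionally independent processes use the Kronecker
sum: `exp(Q₁t) ⊗ exp(Q₂t) = exp((Q₁ ⊕ Q₂)t)`, so the joint table is
single-state occupancy on the K₁K₂-state generator `Q₁ ⊕ Q₂` and the double
(time × frailty) integral collapses to the same one-dimensional frailty
quadrature. This is algebraically identical to integrating the product of
the two processes' transition probabilities with a multi-dimensional
adaptive rule, and numerically tighter. A Monte Carlo alternative
(`occupancy_mc`) draws frailties from the gamma distribution and averages
the conditional tables; it is seeded and reproducible. Occupancy with
dynamic covariate effects is refused — expected lengths of stay are not
well defined when intensities depend on a covariate process whose own
evolution is unmodelled.

The time origin is fixed at 0 without loss of generality (time
homogeneity).

## Synthetic cohorts

`generate_cohort` draws, per subject: a frailty (one per process for
`separate`); a visit schedule; initial states; and exact continuous-time
trajectories per process by the Gillespie algorithm (exponential holding
times, embedded-chain jumps), observed at the visit times with a
right-continuous convention at jump instants. Per-subject random substreams
are spawned from the master seed, so cohorts are byte-reproducible
regardless of batching.

Defaults emulate the motivating lupus-nephritis inception cohort: 568
subjects; visit gaps truncated-normal with mean 1.2 y, SD 0.55, floor
0.1 y (the reported gap moments; the true law is unknown, and a truncated
normal reproduces the moments simply); follow-up normal with mean 5.2 y,
SD 3.1, floored at two mean gaps; initial-state frequencies (504, 58, 6)/568
and (244, 239, 85)/568 for the two processes; inverse link with θ = 0.5 and
true intensities (0.05, 0.5, 0.1, 0.4) and (0.3, 0.6, 0.15, 1.2) per year.
The generator does **not** emulate informative observation or dropout,
misclassification, covariate dynamics, or death as an absorbing state —
passing tests therefore validate the estimator under the stated sampling
design, not robustness to those real-data features.

## Validation design and problem sizes

- Transition probabilities are cross-checked against a uniformization
  oracle and Chapman–Kolmogorov identities on randomized generators.
- Frailty integrals and empirical Bayes ratios are checked against a dense
  Simpson rule on a logarithmic u-grid (20 001 points on [1e-6, 40]),
  an oracle independent of both quadrature engines; a uniform grid is
  avoided because the integrand's curvature near u = 0 limits uniform-grid
  accuracy to ~1e-5.
- Parameter recovery runs at 600 subjects with 11 annual visits from the
  inverse model, asserting every estimate within 3 standard errors of
  truth; smaller cohorts (20–120 subjects) back the faster equivalence and
  shrinkage tests. The Monte Carlo occupancy check uses 6 000 draws so its
  0.05-year agreement band sits ~2.5 standard errors out.
- Simulator calibration compares empirical one-step transition frequencies
  (3 000 subjects) with matrix-exponential probabilities.

Reproductions of the published 5-year occupancy tables start from
intensities printed to 2–3 significant figures, which propagates to about
±0.007 years in the table entries; agreement is asserted at 0.01 years (one
unit in the last printed decimal), and exact third-decimal reproduction is
not claimed.

## Known limitations

- Time-inhomogeneous intensities, hidden/misclassified states and
  phase-type sojourns are out of scope.
- Only the five named link variants are provided; arbitrary user-supplied
  links are not accepted.
- The fixed Gauss–Legendre engine degrades for θ ≳ 1 (see above); fits in
  that regime should be confirmed with the adaptive engine.
- Expected first-passage times, visit counts and mean sojourn times are not
  implemented.
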