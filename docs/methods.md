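# Methods

## Generative model

A trial simulates one tumor subtype with `k1 = 2` stage-1 options and
`k2 = 3` stage-2 options (both configurable).  For a patient assigned
`a1` at stage 1, latent pCR occurs with probability `p1(a1)`.  The response
classifier sends her to surgery with probability `λ_sens` if she has latent
pCR and `1 − λ_spec` otherwise (a false positive).  Stage-2 entrants without
pCR gain it with probability `p2(a1, a2)` under stage-2 option `a2`, and
stage-2 nonresponders without pCR gain it at rescue with probability
`p3(a1, a2)`.

**Persistence.** A latent pCR, once achieved, persists: the patient's
surgical pCR status is 1 whichever path she subsequently takes, and her later
response indicators are drawn with probability `λ_sens`.  Under this rule the
value of regime `{a1, a2}` has the closed form

```
μ(a1,a2) = p1 + (1 − p1) λ_spec [ p2 + (1 − p2) λ_spec p3 ] ,
```

independent of `λ_sens` (the classifier's sensitivity moves patients between
observation pathways but cannot destroy an achieved pCR).  The identity
between this expression and the g-computation formula evaluated at the
observable-scale parameters implied by the generative truth
(`smartrar.implied_regime_params`) holds algebraically and is asserted to
machine precision in the tests; the simulator is additionally validated
against the closed form by forced-regime Monte Carlo over all 36
scenario × regime cells.

The six shipped scenarios (`src/smartrar/data/scenario*.yaml`) fix
`λ_sens = 0.53`, `λ_spec = 0.90`, `p3 ≡ 0.15`, `n = 200` patients and a
130-week accrual window, and vary `p1`/`p2` to produce a null configuration,
no delayed effects, purely delayed effects, antagonism, synergy, and a
two-optimum variant.

## Timing

Defaults (all configurable through `Timing`): stage-1 therapy 12 weeks, so
the surgery decision R1 is observed at `enroll + 12`; pCR is ascertained 1
week after a positive decision; stage-2 randomization happens the same week
R1 = 0 is observed; R2 at `enroll + 24`; rescue pCR at `enroll + 36`.
Probability tables are recomputed at every integer week `t` from counts
observed strictly before `t` and govern all randomizations in `[t, t+1)`.
The last week a randomization can be required is `T_end = 130 + 12 = 142`,
which also anchors the linear damping schedules `ψ_t = c·t/T_end`.

## Randomization scheme

Weekly, M = 1000 joint draws from the componentwise conjugate Beta
posteriors (uniform priors) are pushed through the value formula; the
posterior probability that option `ℓ` is part of the optimal regime is the
fraction of draws whose argmax regime uses `ℓ`.  These are damped
(`π ∝ ρ^ψ`), then clipped to `[0.05, 0.95]` by iterated
clip-and-redistribute: out-of-box entries are pinned to the bound and the
surplus/deficit is redistributed among the remaining entries in proportion
to their mass until a fixed point.  Damping before clipping keeps ψ
interpretable as the adaptation exponent; proportional redistribution
preserves rank order and guarantees box-constrained simplex membership.
Both stages' tables for a given week are computed from one shared set of
draws.  Patients enrolling up to and including the week of the 20th
enrollment are randomized uniformly at *both* stages, even if their stage-2
randomization occurs after adaptation has begun.

Ties in the argmax over regimes (probability zero under continuous
posterior draws, but possible for plug-in inputs) are broken
lexicographically by option index, keeping runs reproducible.

Randomness is organized as one root seed per trial, split into four
independent substreams (enrollment, patient trajectories, posterior draws,
assignments).  A patient's trajectory consumes a fixed number of draws
regardless of the assignment she receives, so changing the scheme or M
leaves patient-level randomness intact — common random numbers across
schemes come for free when trials share a root seed.

## Post-trial estimators

For each regime, from the final data:

- **bayes** — mean of M = 1000 posterior draws of μ, with the posterior SD
  as the uncertainty measure.  Intervals are Wald-style (mean ± z·SD,
  truncated to [0, 1]; the reported length is pre-truncation), matching the
  interval form used for the frequentist estimators.
- **samp** — plug-in of the five sample proportions into the value formula.
  The standard error is by the delta method, treating the proportions as
  independent binomials given their denominators; a nonparametric bootstrap
  over patients serves as an independent cross-check in the tests (15%
  agreement at n = 200).
- **wtsamp** — the same plug-in built from weighted proportions, each
  patient weighted by the stabilized assignment ratio (uniform reference
  probability over probability actually used) for every randomization she
  contributed; variances are of ratio-estimator form.  Under uniform
  randomization all weights are 1 and wtsamp equals samp exactly, which is
  asserted on every simulated dataset used in the tests.  The construction
  is a design choice: it restores zero-mean increments under adaptive
  assignment, and its adequacy is established behaviorally (bias reduction
  under aggressive adaptation, the uniform-randomization identity) rather
  than by a closed-form optimality argument.

A proportion with an empty denominator is imputed by its uniform-prior
posterior mean `(1 + successes)/(2 + n)` (0.5 with no data, variance 1/12)
and the estimate is flagged degenerate; sparse rescue-stage cells are the
typical trigger at n = 200.

## Monte-Carlo harness

`run_experiment` runs independent trials of one (scenario, scheme) cell and
reports: overall in-trial pCR rate; the proportion of patients whose
experience is consistent with a regime (same stage-1 option, and either
stage-1 surgery or the same stage-2 option — under uniform randomization
this is `[θ1 + (1−θ1)/k2]/k1` exactly, which the harness reproduces);
final-week randomization probabilities of the optimal-regime options; and,
per estimator, the proportion of trials identifying a true-optimal regime,
the mean estimate of the true optimal regime's value, Wald coverage and
length, and Monte-Carlo relative efficiency versus the Bayesian estimator
(bootstrap SE).  In multi-optimum scenarios identification of *any* optimal
regime counts as correct, and value/coverage metrics are reported for the
lexicographically first optimal regime.

Default experiment size is 500 replicates — a scaled-down version of the
5000-replicate full-scale runs chosen to keep a cell of 500 adaptive trials
(each with ~142 weekly updates of M = 1000 draws over 22 Beta components)
in the minutes range on one CPU; comparisons against full-scale reference
numbers use Monte-Carlo standard errors scaled by √(5000/500).

## What the generator does and does not emulate

The simulator reproduces the design's structural features: staggered
uniform enrollment, delayed observation of each stage's outcome, weekly
batched updates, burn-in, clipping, and sparse late-stage cells.  It does
not model noncompliance with the classifier's surgery recommendation,
dropout, temporal trends in pCR rates, early escalation on a
within-block imaging trajectory, site effects, or continuous-time
enrollment.  Conclusions from passing tests therefore speak to the
randomization and estimation machinery under the stated generative
assumptions, not to robustness against those real-data complications —
under temporal trends, in particular, adaptive designs are known to yield
optimistic post-trial inference.

## Numerical choices

- Clipping fixed point: tolerance 1e-12 on the simplex constraint, at most
  100 sweeps (two suffice for `k ≤ 3`).
- `damp` treats `0^0 = 1`, so ψ = 0 maps any ρ (including degenerate ones
  with zeros) to the uniform vector; an all-zero ρ is rejected.
- Posterior sampling vectorizes all 22 Beta components into a single
  `(M, 22)` draw per weekly update.
- Empty-cell imputation and tie-breaking as described above; degenerate
  estimates are flagged, never silently dropped.
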