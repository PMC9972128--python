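# Methods

## Model

`fccat` implements the Thurstonian IRT (TIRT) model for pairwise forced-choice
dominance items. Each item *i* has a latent utility
t<sub>i</sub> = μ<sub>i</sub> + λ<sub>i</sub>ᵀη + ε<sub>i</sub>,
ε<sub>i</sub> ~ N(0, ψ<sub>i</sub>²), where η is the S-vector of standardized
latent traits and λ<sub>i</sub> has exactly one nonzero entry (factorially
simple items; the sign of the loading encodes keying). The first item of a
pair {i,k} is preferred when t<sub>i</sub> > t<sub>k</sub>, giving the probit
response function

    P(Y = 1 | η) = Φ(z),   z = (μ_i − μ_k + (λ_i − λ_k)ᵀ η) / √(ψ_i² + ψ_k²).

Assumptions: dominance (monotone) items, locally independent pairs, no item
appears in more than one pair per test, and cross-scale (MFC) pairing so each
block contrasts two different traits. Triplet/quad blocks, ideal-point items
and graded preferences are out of scope.

The pairwise Fisher information in the trait metric is the rank-one matrix

    F(η) = φ(z)² (λ_i − λ_k)(λ_i − λ_k)ᵀ / [p(1−p)(ψ_i² + ψ_k²)],

whose single nonzero eigenvalue peaks on the hyperplane z = 0 (choice
probability 1/2) — the locus of trait profiles the pair measures best.
Posterior information adds the inverse prior trait covariance, Σ⁻¹, which
keeps the matrix positive-definite while the test information is still
singular (fewer informative pairs than traits). Directional SEMs are
√[(I⁻¹)<sub>ss</sub>], i.e. computed from the inverse-information diagonal so
that cross-trait correlations are accounted for, not 1/√I<sub>ss</sub>.

## Scoring

Trait profiles are scored by MAP: maximize the Bernoulli log-likelihood plus
the MVN log-prior. The analytic gradient per response is
(y − p)·φ(z)/[p(1−p)] · (λ_i − λ_k)/√(ψ_i²+ψ_k²), minus Σ⁻¹(η − mean) for
the prior; it is validated against a central finite-difference oracle in the
tests. The optimizer is damped Newton with the Fisher-plus-prior matrix as
Hessian surrogate (Fisher scoring), Armijo backtracking, and a gradient
fallback if the surrogate direction fails; defaults tol = 1e−6 on the
gradient max-norm, 100 iterations, warm start from the previous interim
estimate during CAT (prior mean cold). Non-convergence returns a flagged,
usable result rather than raising, so a session can always proceed.
Numerical guards: |z| clamped to ±8 before Φ, probabilities clamped to
[1e−10, 1−1e−10] inside likelihood/information denominators.

## Adaptive selection and static assembly

Each step enumerates all cross-scale pairs of remaining items, removes those
violating the desirability constraint |μ_i − μ_k| ≤ T (mean utility is the
desirability proxy; T = 0.5 strict, 1.0 lenient, or none), and administers
the candidate minimizing trace[(Σ⁻¹ + I_test + F_cand(interim))⁻¹] — Bayesian
A-optimality, the total posterior error variance across traits. Score ties
within relative tolerance 1e−12 are broken uniformly at random from a seeded
stream. The hot loop scores all candidates via a Sherman–Morrison rank-one
update of the posterior inverse; tests verify it agrees with explicit
inversion to 1e−10 and that rankings match brute force. The static-optimal
assembler runs the identical greedy loop with the interim estimate pinned at
the origin (the average person in the population), yielding a deterministic
fixed form.

**Information-accumulation convention.** The test information a session
carries (used by the selector, and from which per-step SEMs are reported) is
accumulated online: each administered pair's F is evaluated at the interim
estimate current when it was administered, then summed. This makes the
posterior information Loewner-monotone over a session, hence per-trait SEM
trajectories are exactly nonincreasing, and it is precisely the quantity the
A-optimality selector optimizes. Static administration applies the same
convention (interim re-estimated after every block), so adaptive and static
SEM trajectories are directly comparable. The standalone `map_estimate`
instead evaluates all pairs at the final estimate — the standard frozen-test
definition; the two agree closely once interim estimates stabilize.

## Synthetic item bank

No public calibrated bank exists, so `synthesize_bank` emulates the printed
composition of a six-scale HEXACO adjective bank:

* **Counts.** 279 items; per-scale counts (H 40, E 45, X 50, A 46, C 52,
  O 46), each inside the documented 24–81 span. Only the total and the span
  are documented; the split is the package's choice.
* **Discriminations.** Per-scale |λ/ψ| targets (mean, min, max): H (0.49,
  0.15, 0.78), E (0.52, 0.17, 0.97), X (0.68, 0.20, 1.18), A (0.61, 0.20,
  1.01), C (0.61, 0.22, 1.18), O (0.49, 0.20, 1.03). Draws come from a Beta
  distribution (concentration 4) rescaled to [min, max] with the sample mean
  re-centred onto the target. Loadings are standardized to unit total utility
  variance: λ = d/√(1+d²), ψ² = 1 − λ², so traits and utilities are on the
  calibration metric.
* **Utilities.** The documented utility summary (mean 3.61, SD 1.54, range
  [1.22, 5.80]) cannot come from a single truncated normal: on a width-4.58
  interval no truncated normal exceeds SD ≈ 1.32 (the uniform limit). The SD
  implies a bimodal desirable/undesirable mixture, which is also what
  adjective banks look like: negatively keyed adjectives are undesirable.
  Utilities are therefore drawn from a keying-linked mixture of truncated
  normals on [1.22, 5.80] — negative-keyed items from location 1.70,
  positive-keyed from 4.95, common scale 0.60, negative-keying fraction 0.42.
  These values were moment-matched once analytically (giving mean ≈ 3.62,
  SD ≈ 1.53) and are not tuned thereafter.

What the generator does **not** emulate: real per-item parameters, cross-item
utility/discrimination correlations, content overlap between scales, and any
respondent behaviour other than the model (no faking, no carelessness). Tests
passing on synthetic banks therefore demonstrate engine correctness and the
direction of design effects, not empirical SEM magnitudes of any real bank.

## Simulation design

Defaults mirror the study setup: 2,000 simulees (scaled to 500 in the
acceptance suite to fit a desk-scale run; contrasts use matched seeds, so the
paired Monte-Carlo error is small), test length 120 pairs, checkpoints every
10 blocks, conditions {adaptive, static} × {strict, lenient} with an optional
unconstrained level. The prior trait covariance is not public; the default is
unit variances with a modest HEXACO-style correlation pattern (±0.1–0.3,
positive-definiteness asserted at construction). Simulees are drawn from the
prior; each simulee's response-noise and tie-break streams derive from
`[master_seed, 1, simulee_index]`, identical across conditions, enabling
paired contrasts. Metrics per scale × checkpoint: mean directional SEM,
Pearson correlation of true and estimated scores, RMSE; Monte-Carlo SEs by
leave-one-simulee-out jackknife (contrasts jackknife the paired difference).

## Numerical and design choices

* Prior precision Σ⁻¹ is computed once per prior via Cholesky.
* The engine refreshes the running posterior inverse from scratch every 16
  rank-one updates to cap accumulated floating-point drift.
* Candidate enumeration order is lexicographic by item id; within a pair the
  lexicographically smaller id is presented first (the model is
  order-sensitive only through response coding, which the engine fixes).
* Pool exhaustion (no eligible pair) truncates a session with a flagged
  reason rather than raising mid-experiment; the CLI maps it to exit code 3.
* `problem sizes`: acceptance checks run one 120-pair session (item-usage
  arithmetic), 50 strict sessions (feasibility), and the 500-simulee 2×2
  experiment (directional effects, recovery monotonicity).

## Known limitations

* Pairs only; larger blocks would need the multidimensional-probit likelihood
  over within-block comparisons.
* A-optimality relies on interim point estimates; global-information
  selectors (e.g. Kullback–Leibler) are not implemented.
* No exposure control or content balancing beyond the desirability
  constraint.
* The synthetic bank reproduces printed summary statistics only; absolute
  precision levels on real banks will differ.
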