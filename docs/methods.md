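# Methods

## The scientific problem

In the free-choice paradigm, items are rated, chosen between, and rated
again; chosen items gain rating and rejected items lose it (the "spread of
preference"). Chen & Risen's critique is that if ratings and choices are both
noisy read-outs of stable underlying values, the same spread appears without
any causal effect of choice — a regression-to-the-mean artifact. This package
implements a model-comparison approach to that question for an *effortful*
free-choice paradigm: participants rate ~120–150 food items on a 0–100
visual-analogue scale (sessions R1, R2, R3), and in two interleaved effort
sessions (E1, E2) decide whether to squeeze a handgrip above an imposed
target level L ∈ [0.20, 1.20] (fraction of maximal force F\_max) to earn each
of 90 presented items. Targets above 1.0 are unreachable, creating failures.
Three action variables result per item and session: choice C (accept /
decline), success S (earned / failed, defined only on accepted trials) and
force F (peak force, defined only on successful trials).

## Generative model space

Hidden values V drive all behaviour:

- ratings: `R = V + ε`, `ε ~ N(0, σ_R²)`
- choice: `p(C=1) = sig(ρ_C V + η_C L − C0)`
- success: `p(S=1) = sig(ρ_S V + η_S L + S0)` (accepted trials)
- force: `F = ρ_F V + η_F L + F0 + ω`, `ω ~ N(0, σ_F²)` (successful trials)

Actions in effort session k produce a per-item bias
`b_ik = b_C C_ik + b_S S_ik + b_F F_ik + b_T` from the signed coding
(C = ±1; S = +1 earned / −1 failed / 0 declined; F = per-session z-score of
peak force over successful trials, 0 otherwise). The hypotheses differ in
where the bias lands: nowhere (H0), the next rating only (H1), all later
ratings (H2, cumulative), or the value itself (H3: `V^{k+1} = V^1 + Σ b`),
which propagates to later ratings *and* actions. Toggling the four bias
weights gives 16 models per structure; the two all-action-off settings (none
/ time-only) form the H0 family. H2 and H3 are rating-equivalent by
construction; only action likelihoods separate them, so H3 comparisons
require the extended scope (ratings + actions). In combined spaces the two
null models inherit the dynamics of the richest hypothesis present (the
time-only model is otherwise ambiguous between last-session and cumulative
drift); in the rating-only H0/H1 comparison they use the H1 structure.

## Inversion and model evidence

Each subject × model cell is inverted by MAP estimation under independent
Gaussian priors, with noise SDs log-transformed: values V1 ~ N(50, 25²)
(data-independent, to avoid double use of R1), biases ~ N(0, 5²) rating
units, ρ ~ N(0, 1²), η ~ N(0, 5²), offsets ~ N(0, 3²), log σ_R ~ N(log 10,
1), log σ_F ~ N(log 0.1, 1). These are weakly informative on the declared
scales. The log evidence is the Laplace approximation
`ln p(y|m) ≈ ln p(y, θ*) + (d/2) ln 2π − ½ ln det H`.

Numerics: the posterior has an arrow structure (≈150 item values plus ≤15
shared parameters), so the optimizer is a damped Newton descent on the
negative log joint with an analytic gradient and Hessian (validated against
finite differences to 5×10⁻⁵ relative error); a prior-whitened L-BFGS-B run
is the fallback when Newton stalls. Convergence is gradient max-norm < 10⁻⁶
(cap 500 iterations); restarts jitter the warm start by 0.1 prior SD. The
warm start uses conjugate shrinkage of item rating means for V1 and quick
IRLS/OLS moment fits for the response parameters. Non-positive-definite
Hessians at the mode are repaired by flooring eigenvalues at 10⁻⁸ (logged).
On a conjugate Gaussian toy the evidence matches the closed-form marginal
likelihood to 10⁻⁶ (the Laplace step is exact there). A known property of the
joint MAP: with three ratings per item, σ̂_R underestimates the true rating
noise by ≈ √(2/3) (the many-means ML bias); evidence *comparisons* are
unaffected, and its one downstream consequence is discussed under the
bootstrap below.

## Group level

Random-effects BMS: Dirichlet prior over population model frequencies,
variational fixed point `u_nm ∝ exp(lme_nm + ψ(α_m) − ψ(Σα))`,
`α = α0 + Σ_n u_n`, iterated to 10⁻⁶. Expected frequencies are α/Σα;
exceedance probabilities are Monte-Carlo (default 10⁵ Dirichlet draws,
seeded). For family inference the per-model prior concentration is
1/(family size × number of families), so a 2-model null family and a
14-model alternative have equal prior mass. Caveat, established against an
exact enumeration oracle: with ≤6 subjects and weakly informative evidence
(≲1.5 nats) the mean-field expected frequencies can deviate from the exact
Dirichlet posterior by up to ~0.09; with informative evidence (≳2.5 nats)
agreement is ≲0.02. An FFX variant (summed evidences) exists behind a
separate function.

BMA within a family weights each member by `exp(lme − max lme)`
(renormalized over successful fits), with structural zeros for parameters a
member switches off. Per-subject BMA estimates feed two-tailed group t-tests
(random effects across subjects); ρ parameters are checked positive the same
way.

## Synthetic cohorts

The generator replays the full paradigm: values V1 ~ N(50, 20²); R1 = V1 +
noise; items ranked on R1; 15 top + 15 bottom excluded, plus 30 random
control items in Exp-2/3 designs; the remaining 90 paired with force targets
by the diamond scheme (Exp 1: rank r gets `0.70 + s_r·0.50·(1−d_r)`,
`d_r = |r−45.5|/44.5`, sign alternating from positive at rank 1) or by
rejection-sampled permutations of the same level multiset with
|corr(rank, L)| < 0.05 per session and |corr(L_E1, L_E2)| < 0.05 (Exp 2–3).
Effort behaviour is generated sequentially per session from the response
functions, so realized actions bias later ratings (H1/H2) or values (H3).
Successful-trial force is the force function truncated below at the target
(the data invariant requires F ≥ L); failed-trial force is Uniform(0.20, L)
— the models never evaluate force on failed trials, so any
invariant-respecting choice works. Ratings are not clipped to [0, 100] by
default, preserving the Gaussian likelihood; a clip flag exists.

Default parameters (chosen once, as a realistic regime): σ_R = 5 (a
test-retest scatter of ±5 points on a 0–100 scale), ρ_C = 0.2, η_C = −4.5,
C0 = 6.85 (≈50% acceptance, strongly value- and cost-sensitive choices,
balanced accuracy ≈ 0.8), ρ_S = 0.03, η_S = −8, S0 = 7 (failures
concentrated on near- and supra-maximal targets, ~10 failures per subject),
ρ_F = 0.001, η_F = 0.85, F0 = 0.15, σ_F = 0.07 (force tracks target; linear
R² ≈ 0.9). Recovery-study effect sizes are b_C = 1.8, b_S = 0.7, b_F = 0,
b_T = −0.3 rating units — the regime of the group estimates this pipeline is
designed to detect. What the generator does not emulate: fatigue and hand
alternation effects, reaction times, rating-scale edge effects, exposure
duration. Passing recovery tests therefore show the pipeline is correct and
well-calibrated *for this data-generating process*, not that real data obey
it.

A note on identifiability: C and S are strongly correlated by construction
(S ≡ 0 on declined trials), so the success weight is estimated essentially
from the ~10 failures per subject; its per-subject standard error is ~1.3
rating units. This is why participants with too few failures are excluded
(default threshold: 3 accepted-and-failed trials) and why per-subject
model selection rarely favours adding S even when b_S = 0.7.

## The artifact, and the bootstrap control

Because presented items are the *middle* of the R1 ranking, value and
first-session rating noise are negatively correlated among them
(cov ≈ −0.56 σ_R² for middle-80% truncation). Choice tracks value, so any
estimator contrasting post-action ratings with R1 — the naive Δ-rating
regression *and* the model-based MAP — inherits a positive bias on the
choice weight (measured here: ≈ +0.01 on the z-scored naive β_C, ≈ +0.4 on
the rating-only model-based b_C, ≈ +0.09 under the extended joint fit, where
choices themselves help pin down values). Significance is therefore assessed
against a simulated null: fit H0 to each subject, then regenerate the whole
paradigm — fresh first ratings, fresh rank-based exclusion, fresh pairing —
with the fitted values as latent truth and all biases zero. Replaying the
selection step is essential: a frozen-design replay produces a null pool
without the confound (centred ≈ 0.1 instead of ≈ 0.3–0.45) and would wreck
the calibration of every downstream test. Real estimates are then compared
to the null pool per subject (95% percentile interval classification) and at
the group level by Welch tests of n real values against n values drawn from
the pool, with p averaged over 1000 redraws. The averaging makes the test
deliberately conservative (rejection needs a ≈3 null-SE excursion of the
cohort mean), which also absorbs the residual mismatch from the σ̂_R
underestimation above; its false-positive rate stays well under the nominal
5%. A median-p variant is available.

## Problem sizes used by the test suite and acceptance script

Unit tests run on scaled-down designs (24 presented of 40 items, 2–15
subjects). The acceptance suite uses study-scale cohorts: 20 replicates of
24 subjects × 90 presented items for parameter recovery; 5 replicates per
condition for family identification (reduced 8-model space: the two null
models plus choice+time and choice+success+time per hypothesis); 200 null
cohorts of 24 subjects against a 1200-sample bootstrap pool for the
type-I/artifact check. `scripts/acceptance.py` analyses one 24-subject
cohort end to end with 20 bootstrap replicates. These sizes were chosen so
the full analysis remains a desk-scale computation.

## Known limitations

- Laplace (not full variational) evidence; the approximation family matches
  the original toolbox's Gaussian posterior but not its free-energy bound.
- Joint-MAP σ̂_R bias (above); a REML-style correction is deliberately not
  applied, to keep one estimator throughout.
- Mean-field RFX-BMS inaccuracy for tiny cohorts with uninformative
  evidence (quantified above).
- The linear cumulative value update diverges under indefinite repetition;
  with two effort sessions this is immaterial.
- Exposure-duration confounds are out of scope (no trial-timing data in the
  interchange format).
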