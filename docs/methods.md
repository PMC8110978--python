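# Methods

`bayesteach` implements explanation selection by *Bayesian teaching*: an
explanation (a small set of examples, or a pixel mask) is scored by how
strongly it would lead a probabilistic *explainee model* to reproduce the
decision of the model being explained. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
backends do and do not emulate.

## The explainee model: PLDA

The explainee is a probabilistic linear discriminant analysis (PLDA)
model over feature vectors. Its generative story: an item `x` of class
`c` arises as

    x = m + A u,    u ~ N(v_c, I),    v_c ~ N(0, Ψ),   Ψ = diag(psi),

so the latent coordinates `u = A⁻¹(x − m)` have identity within-class
covariance and diagonal between-class covariance `Ψ`. Because both are
simultaneously diagonal, the predictive density of a new latent item `u*`
given `n` latent examples of one class factorizes over coordinates:

    f(u* | u_1..u_n) = N( u* | nΨ/(nΨ+I) · ū ,  Ψ/(nΨ+I) + I ),

with `ū` the example mean. For the two-example sets used throughout, the
mean is `Ψ/(2Ψ+I)(u₁+u₂)` and the variance `Ψ/(2Ψ+I)+I`. The two limits
are informative: `Ψ→0` collapses every class to the prior `N(0, I)`
(examples carry no class information), while `Ψ→∞` gives mean `(u₁+u₂)/2`
and per-coordinate variance `3/2` (the class centre is learned entirely
from the two examples, and the predictive variance is the centre's
posterior uncertainty `1/2` plus the item noise `1`).

Fitting uses the maximum-likelihood recipe of simultaneous
diagonalization: with within/between scatter matrices `S_w, S_b`
(class-count weighted), the generalized eigenproblem `S_b w = λ S_w w`
yields `W` with `Wᵀ S_w W = I`; then `A = W⁻ᵀ √(n/(n−1))` and
`psi = max(0, (n−1)/n λ − 1/n)`, with `n` the mean class size. The
balanced-class derivation is applied to unbalanced data by using the mean
class size in the two bias corrections; this is exact for balanced data
and a standard approximation otherwise. A ridge (default `1e-6`) on the
diagonal of `S_w` keeps fitting defined when classes have fewer items
than feature dimensions; with the ridge disabled a singular scatter
raises an error naming the offending dimension. Latent dimensionality
equals feature dimensionality; `truncate_psi` can zero all but the top-k
between-class variances but is never applied by default. All densities
are evaluated in log space and combined with log-sum-exp or a sigmoid of
log-density differences, since high-dimensional raw densities underflow.

### What "parameter recovery" means at fixed class count

A fit on `K` classes estimates the between-class variance from the `K`
sampled class centres, so the error against the *generating* `psi` has an
irreducible per-coordinate relative noise floor of `√(2/(K−1))` — about
20% at `K = 50` — that no amount of per-class data removes. The quantity
that does converge as items-per-class grows is the fitted `psi` versus
the between-class variance *realized* by the sampled centres, and that is
what the recovery tests measure (the monotone-decrease check estimates
the median error at each sample size from 16 replicate datasets, so the
comparison reflects the `1/√n` scaling rather than single-draw noise).
Convergence to the generating `psi` itself requires growing the number of
classes, which a separate test verifies.

## Teaching over example sets

A trial shows a target `d*`, the model's predicted category `y*`, an
alternative `y`, and two examples from each. The *simulated explainee
fidelity* of a candidate set is the explainee's probability of choosing
`y*` under equal category priors:

    f_L = f(d*|τ^{y*}) / ( f(d*|τ^{y*}) + f(d*|τ^{y}) ),

computed as a sigmoid of the log-density difference. The teaching
distribution over a candidate pool is proportional to `f_L`, normalized
over the pool actually enumerated. The candidate space is the Cartesian
product of sampled unordered example pairs per category (default 1000
pairs per side, i.e. 10⁶ candidates); pairs are unordered and
deduplicated because the predictive density is symmetric in the two
examples, so ordered pairs would double the space with no new
information. Sampling more pairs than exist falls back to full
enumeration.

Three selection policies define experimental conditions:

* **helpful** — uniform among candidates with `f_L > 0.8`. Uniform
  sampling (not argmax) preserves stimulus diversity; the threshold is
  the defining property. An empty stratum is a hard error, because the
  stratum *is* the condition.
* **random** — the 150 selected sets have fidelities spread evenly over
  the five equal-width bins of [0, 1] (`[0,.2), … ,[.8,1]`), assigned
  round-robin so counts are exactly equal when the trial count divides by
  the bin count; an empty bin falls back to the nearest non-empty bin
  with a logged warning.
* **misleading** — mirror of helpful at `f_L < 0.2`; the threshold is
  configurable since it is a design parameter rather than a derived
  quantity.

Selections are i.i.d. uniform within their stratum (a set may recur
across trials); candidate pools, not selection, enforce uniqueness.

## Saliency by teaching pixels

A mask `m ∈ [0,1]^{W×H}` is scored by `g(y|d,m)`, the classifier's
probability for category `y` on the masked image (elementwise
multiplication of the [0,1]-scaled image, per channel). The saliency map
is the Monte-Carlo expectation of masks weighted by that probability:

    E[M|y,d] ≈ Σᵢ mᵢ g(y|d,mᵢ) / Σᵢ g(y|d,mᵢ),     i = 1..N.

Masks are sigmoid-squashed draws from a stationary Gaussian process with
constant mean −100, marginal standard deviation 100, and an RBF kernel
with length scale 22.4 px on a 224×224 grid (0.1 × width on other grids);
`N = 1000` samples by default. The mean sets the fraction of the mask
that is effectively zero (`Φ(−1) ≈ 16%` of pixels exceed ½); the sd sets
how sharply values swing between 0 and 1; pre-squash values span roughly
mean ± 4 sd = [−500, 300]. A plausible alternative reading of the prior's
scale — variance 100, i.e. sd 10 — would squash essentially every value
to 0 at this mean and is exposed through `marginal_sd` but not used as
the default. Sampling is exact: the separable RBF kernel factorizes over
rows and columns, so a draw is `mean + sd · L_r Z L_cᵀ` with the 1-D
Cholesky factors (jitter `1e-6` on each axis kernel), never a full
`(WH)²` covariance.

Two renderings are provided. The **jet** rendering alpha-composites the
jet colormap of the map over the image (`alpha = 0.4`; red = important,
blue = unimportant). The **blur** rendering assigns each pixel a box-blur
window width `w(z) = ceil(30 / (1 + exp(20z − 10)))` — 30 px at `z = 0`,
15 at `z = 0.5`, 1 (identity) at `z = 1` — and averages the original
image over the window, clipped to the image bounds (rectangular near
edges, in-bounds pixels only). Even widths span `floor((w−1)/2)` pixels
before and `ceil((w−1)/2)` after the centre. The blur is computed with
per-channel summed-area tables, so cost is independent of window size.

The conditioning label for a target image is the model's predicted
category; for an example image, its source category. Masked images are
not re-normalized before classification.

## 2AFC session design

Sessions are built from the classifier's confusion matrix on a labelled
dataset (argmax posterior, ties to the lowest category index). Study
categories span the extremes of model behaviour: from the most-accurate
pool, the pool most confusable with it, the least-accurate pool, and the
pool most confusable with *that*, k categories each are sampled, unioned
and deduplicated. Confusability of a pair is the symmetrized
row-normalized off-diagonal mass (the average of both directions);
rankings break ties by category index for determinism.

The default session holds 150 trials: 50 where the model's prediction
matches the ground truth and 100 where it does not — model errors are
deliberately over-represented 2:1 so that spotting errors carries most of
the signal. Correct trials pair the prediction with one of its two most
confusable categories within the study set (drawn uniformly); error
trials pair the wrong prediction with the ground truth. Targets are drawn
without replacement (no repeats within a session) and trial order is
shuffled.

## Agents and metrics

Fidelity is agreement with the *model's* choice: sensitivity restricts to
model-correct trials, specificity to model-error trials, and the overall
fidelity is their count-weighted average (an identity the reports satisfy
exactly). Three idealized agents bracket observer behaviour: **random**
(uniform over the two options: 50% everywhere), **perfect** (always the
model's prediction: 100% everywhere), and **belief-projecting** (always
the ground truth — an observer with perfect first-order accuracy who
assumes the model agrees with them: 100% sensitivity, 0% specificity, and
33% fidelity on the 50/100 design). Metrics on empty strata are reported
as missing, never coerced to zero. Familiarity of a category pair is the
mean of binary rater judgements (seven raters in the intended use).

## Synthetic backends

The Gaussian feature generator draws data from exactly the PLDA
generative model, returning the sampled class centres so recovery tests
can compare against realized truth. The toy image backend builds small
images whose category is carried by a known rectangular region of
elevated intensity; its classifier is a closed-form softmax (gain 30 by
default) over mean masked intensity per region, so the pixels that drive
the decision are known exactly and saliency maps can be checked against
them. Overlapping regions manufacture confusable categories and are
logged. All randomness descends from one session seed through named
substreams (dataset, masks, candidate pairs, selection, session, agents),
so every stage is independently reproducible.

What these backends do **not** emulate: deep-network feature geometry
(features here are truly Gaussian with shared within-class covariance —
the PLDA assumption holds by construction), natural-image statistics,
label noise, and class imbalance. Passing tests therefore demonstrate the
correctness of the machinery — densities, selection contracts, session
invariants, estimator behaviour — not that PLDA is a good explainee model
for any particular real classifier or that selected examples help real
observers; those are empirical questions requiring a real backend and
human data.

## Problem sizes and numerical choices

Default test and analysis sizes are desk scale: candidate pools of
10⁴–10⁶ sets, GP checks on 64×64 grids with 1000 samples, recovery runs
of 50 classes × 50–1000 items at D = 3, sessions of 150 trials and
random-agent runs of 10,000 trials. Tolerances mirror the arithmetic:
closed-form identities to 1e-10–1e-12, Monte-Carlo quantities to 2–3
standard errors, distributional GP statistics to a few percent. Fidelity
ratios and teaching normalizations are always formed in log space;
`psi` is clamped at zero from below after the ML correction; the
fidelity-bin of 1.0 joins the top bin.

## Known limitations

* The unbalanced-class bias correction uses the mean class size; strongly
  unbalanced data would warrant the exact per-class likelihood.
* Selection is enumeration over a sampled candidate pool; no MCMC or
  discrete optimization for targeting specific fidelity values.
* The CLI's saliency command ships only the toy backend; wrapping a real
  classifier means implementing the three-method backend contract
  (`categories`, `featurize`, `predict_proba(image, mask)`).
* The binary-matrix + bilinear-upsampling mask family used by RISE-style
  methods is deliberately not implemented; the GP prior is the mask
  sampler here.
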