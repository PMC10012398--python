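# Methods

## Model and notation

The outcome Y takes one of K nominal categories; category 1 is the
reference. A multinomial logistic regression with Q candidate predictor
parameters per sub-model specifies

ln[P(Y=k)/P(Y=1)] = β₀,k + Σ_q β_{q,k} X_q,   k = 2,…,K,

with the softmax constraint Σ_k P(Y=k) = 1. "Candidate predictor
parameters" counts coefficients considered before any selection — each
spline/fractional-polynomial term and each interaction term counts
separately. E_k denotes the anticipated number of events in category k,
n = Σ E_k, p_k = E_k/n, p_{k,r} = (E_k+E_r)/n, and φ_{k,r} = E_k/(E_k+E_r)
is the pairwise outcome fraction.

Overfitting is quantified on the multiplicative scale by shrinkage factors:
after development, the recalibration model

ln[P(Y=k)/P(Y=r)] = α*_k + S_{MN,k,r} · LP_k

(fitted in validation data, one slope per equation on its own linear
predictor) estimates how much each sub-model's coefficients should have
been shrunk. S = 1 means perfect calibration of effects; S = 0.9 means 10%
overfitting. A well-sized development set makes the *expected* S equal a
chosen target.

## The three criteria

**Criterion (i) — pairwise shrinkage.** The sub-models are parametrically
equivalent to distinct one-vs-one binary logistic models fitted on the pair
subsets, and the distinct-logistic calibration slope converges to the
multinomial sub-model slope as n grows. The binary shrinkage-based sample
size formula

m = Q / [(S − 1) · ln(1 − R²_adj/S)]

therefore applies per pair, with the pair's anticipated Cox–Snell R². Since
the validation-time choice of reference category determines which sub-model
slopes are observable, all K(K−1)/2 unordered pairs must be controlled, not
just the K−1 pairs against one reference. Each m_{k,r} is inflated to a
whole-cohort size n_{k,r} = m_{k,r}/p_{k,r} and the criterion's requirement
is max n_{k,r}. The formula is undefined when R² ≥ S: the targeted
shrinkage is unattainable at any n, and the implementation raises an error
naming the pair rather than returning a number.

A "direct" alternative — sizing the overall heuristic shrinkage
S_VH = 1 − (K−1)Q/LR of the whole multinomial model with the binary formula
at (K−1)Q parameters — is exposed as a diagnostic
(`criterion_i_heuristic_direct`) but always emits a warning: the overall
heuristic has no fixed relationship to the per-sub-model shrinkage factors,
so meeting it can leave individual sub-models overfit. On the shipped
worked example it suggests 4509 individuals versus roughly 13,000 for the
pairwise criterion.

**Criterion (ii) — overall R² optimism.** Nagelkerke's R² is Cox–Snell R²
divided by its maximum attainable value
max(R²_CS) = 1 − exp(2·lnL_null/n) = 1 − (Π p_k^{p_k})². Requiring the
apparent-minus-adjusted Nagelkerke difference to be at most δ is equivalent
to requiring S_VH ≥ R²/(R² + δ·max R²); substituting that bound into the
(K−1)Q-parameter shrinkage formula gives

n ≥ (K−1)Q / [(R²/(R² + δ·max) − 1) · ln(1 − R² − δ·max)].

Under the conservative fallback R² = 0.15·max (an assumed optimism-adjusted
Nagelkerke R² of 0.15) and δ = 0.05, the implied shrinkage bound is exactly
0.75 regardless of max — a useful algebraic check that the test suite
exercises.

**Criterion (iii) — simultaneous precision.** The model's average predicted
risk per category tracks the observed category proportions, so precise
intercepts require precise proportions. Simultaneous (1−α) confidence
intervals for all K multinomial proportions (Goodman/Quesenberry–Hurst) use
the χ² quantile with 1 degree of freedom at upper-tail probability α/K;
the margin-of-error requirement δ gives
n_k = χ²_{1,α/K} · p_k(1−p_k)/δ² per category, maximised over k. For
α = 0.05 and K = 5 the multiplier is 6.635. This is deliberately more
conservative than a pointwise interval (for K = 2 it exceeds the classical
1.96² construction); a `pointwise` flag restores per-category pointwise
semantics for audit.

The final minimum sample size is the maximum over the three criteria. An
events-per-variable comparator, ceil(EPV·Q/p_min), is reported on request
for contrast only.

## Obtaining the R² inputs

In decreasing order of preference, resolved per pair and logged:

1. **Reported Cox–Snell R²** of previously published one-vs-one models (or
   pairwise R² from a multinomial model), used directly.
2. **Pairwise C-statistics** (conditional-risk method), converted by
   simulation: the pair's linear predictor is modelled as normal within
   outcome groups with unit variance and mean separation √2·Φ⁻¹(C); a
   large sample (default 10⁶) with event fraction φ is drawn, a
   single-covariate logistic model is fitted by Newton–Raphson maximum
   likelihood, and R²_CS = 1 − exp(−LR/n). The reported value is the mean
   of 10 seeded replicates with its Monte-Carlo standard error. By default
   the event count is fixed at round(φ·n) rather than drawn Bernoulli,
   removing a variance component; a `sampling=bernoulli` knob restores
   binomial draws. The within-group variance and non-event mean are
   immaterial by location/scale invariance of the fitted R².
3. **Nagelkerke-0.15 fallback**: R²_{k,r} = 0.15 · max(R²_{CS,k,r}), with
   the pairwise maximum computed from φ_{k,r}. The same fallback supplies
   the overall R² for criterion (ii) when none is given.

## Rounding and numerical conventions

- Intermediates are kept at full floating precision; rounding happens once,
  at the final per-pair / per-category sizes and the criterion-(ii) n.
  The default policy is ceiling (conservative); `nearest` exists for audit.
  A guard of 1e−9 prevents float dust from pushing exact integers up.
- Consequence: with the worked example's 3-d.p. published R² inputs, a few
  published pairwise sizes (derived from unrounded simulated R² values)
  are reproduced only to within ~0.5% (e.g. 13,016 vs 13,063 for the
  binding pair); the binding pair itself is unaffected. The criterion-(ii)
  bound evaluates to 1477.08 at the 3-d.p. inputs, so the smallest integer
  satisfying it is 1478; the report always includes the unrounded bound in
  a warning for traceability.
- Proportions supplied instead of counts are converted to counts by
  rounding p_k·n (with the residual assigned to the largest category) under
  a warning, since the likelihood formulas consume counts.
- Zero-count categories are a hard error in every likelihood quantity,
  never silently dropped: sizing is ill-posed for an unobserved category.
  Criterion (iii) alone treats a degenerate proportion (0 or 1) as
  contributing no requirement, with a warning.
- Pairs are stored canonically as (k, r) with k > r; the {k,r} and {r,k}
  logistic models are the same model.
- All simulation randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning, so every result is bit-reproducible
  and replicate streams are independent by construction.

## The validation simulation

`validation_sim` checks empirically that developing at criterion (i)'s n
yields the targeted sub-model shrinkage. The data-generating process is the
multinomial model itself with Q independent standard-normal covariates;
intercepts are calibrated by a fixed-point iteration on a large fixed
covariate sample (default 10⁶) until marginal category proportions match
their targets within 0.002.

The default design places the K categories at the vertices of a regular
simplex in coefficient space (all pairwise coefficient separations equal,
norm √2 at the default effect scale of 1), with equal category proportions.
This makes all pairs exchangeable — each pair's required n is the same, so
the criterion's n is binding for every pair simultaneously and the observed
shrinkage medians are directly interpretable against the target. At the
default scale the pairwise C-statistics are ≈ 0.81, in the middle of the
range typical of clinical prediction models. Effect scale, proportions, K,
Q and the full coefficient matrix are all exposed.

The experiment: (1) estimate the "true" pairwise Cox–Snell R² once from a
single large pilot sample (default 10⁶) by fitting each one-vs-one logistic
model on its pair subset; (2) size with criterion (i); (3) for each of
n_sims replicates, simulate a development set of that size, fit the
multinomial model (statsmodels MNLogit, Newton), and estimate on an
independent validation sample (default 100× the development size):

- S_MN,k,r — slopes of the constrained multinomial recalibration model,
  fitted by a dedicated Newton solver on the concave 2(K−1)-parameter
  likelihood (each equation: own intercept, own slope on its own linear
  predictor; convergence when the step's sup-norm falls below 1e−8);
- S_DL,k,r — the logistic calibration slope on the pair subset;
- S_VH — the overall heuristic shrinkage from the development fit's LR.

Replicates with missing categories, non-convergence, or diverging
coefficients (|β| > 20, a separation proxy under standard-normal
covariates) are excluded and counted, never retried — retrying with fresh
data would bias the shrinkage summaries. Summaries (medians, percentiles,
S_DL-vs-S_MN agreement) are computed only from stored per-replicate values.

With the default design, 200 replicates and a 10⁶ pilot (the sizes used by
the packaged experiment; the whole run takes well under a minute on one
CPU), the median S_MN per pair sits a few points below the 0.9 target
(≈ 0.872–0.876) — within the ±0.05 band — while the median overall
heuristic S_VH lands on 0.90 almost exactly. This reflects a known feature
of heuristic-shrinkage-based sizing: the formula targets the heuristic
factor, which is an approximation to the per-sub-model recalibration
slopes, and the approximation degrades when covariate effects are large
and samples small. Median |S_DL − S_MN| per pair is ≈ 0.045, confirming
the distinct-logistic and multinomial recalibration views agree at the
criterion's n.

### What the generator does and does not emulate

The simulated data match the model's assumptions exactly: independent
Gaussian covariates, correctly specified linear sub-models, no missing
data, no measurement error, and known "true" R² via the pilot. Passing
tests therefore show the sizing arithmetic and the shrinkage-targeting
logic are correct *under the model*; they do not speak to model
misspecification, correlated or categorical predictors, variable selection,
or penalised estimation, none of which the criteria claim to cover.

## Design choices made where the design was open

- **Evidence precedence** (direct R² > C-statistic > fallback) is a package
  decision: the options are all legitimate sources, but a deterministic,
  logged precedence keeps runs reproducible and auditable.
- **Pilot-based "true" R²** rather than an analytic value: no closed form
  exists for the Cox–Snell R² of a pair subset under the softmax DGP.
- **A single Q across sub-models**: reducing Q only in overfit sub-models
  is attractive but its consequences are not established, so it is
  deliberately not offered.
- **Category merging invalidates touched evidence**: merging changes the
  one-vs-one models, so R² values for pairs involving merged categories are
  dropped rather than silently reused; untouched pairs carry over under the
  new labels.

## Limitations

- The criteria size for shrinkage, optimism and precision — not for
  discrimination, net benefit, or prediction-error targets.
- The C-statistic → R² conversion assumes normal within-group linear
  predictors with equal variances; heavily skewed linear predictors will
  deviate.
- Ordinal outcomes can be sized with these criteria (treating the outcome
  as nominal) but the result is conservative relative to a dedicated
  ordinal model.
- Anticipated R² values taken from small or poorly validated prior studies
  propagate their own uncertainty; the criteria treat them as known.
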