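# Methods

## The problem

Bilateral-knee cohorts observe a binary outcome (e.g. presence of knee
pain) twice per person — once per knee. The two observations are
correlated: in the regime this package targets, the left–right phi
coefficient is around 0.3. A standard classification forest ignores that
correlation; the binary mixed model (BiMM) couples a forest to a logistic
random-intercept model so that the within-person structure informs
training.

## The model and algorithm

The coupling model is a Bayesian logistic mixed-effects model

    logit P(Y_it = 1) = β₀ + β₁ · RF(X_it) + b_i,     b_i ~ N(0, σ_b²),

where `Y_it` is the outcome of person `i`, knee `t` (1 = left, 2 = right),
`RF(X_it)` is the forest's class-1 probability for that knee, and `b_i` is
a per-person random intercept. β₀ and β₁ carry flat priors; the
random-intercept scale σ_b carries a weakly-informative half-normal prior
(scale 2.5).

The BiMM iteration:

1. fit a classification forest on the current working outcome;
2. take its fitted class-1 probabilities on the training rows;
3. fit the mixed model above, extract fitted probabilities
   `Q_it = logit⁻¹(β̂₀ + β̂₁ RF(X_it) + b̂_i)` and the posterior
   log-likelihood (log joint density: Bernoulli log-likelihood + Gaussian
   log density of b + log prior of σ_b);
4. stop when the absolute change in posterior log-likelihood drops below
   the tolerance (default 0.5, checked from the second iteration); else
   update the working outcome to `h(Y_it + Q_it)` and repeat.

Predictions for new rows come from the final forest alone: random effects
of unseen persons are zero by definition, so test-set prediction is
population-level.

### Split functions

`h(s)` maps `s = Y + Q ∈ [0, 2]` back to {0, 1}:

* `h1(s) = 1[s > k1]`, `k1 ∈ (0, 1)` — since `s ≥ 1` whenever `Y = 1`, h1
  can only flip 0 → 1 (sensitivity-preserving);
* `h2(s) = 1[s ≥ k2]`, `k2 ∈ (1, 2)` — flips only 1 → 0
  (specificity-preserving);
* `h3` — fixed thresholds 0.5 / 1.5; deterministic outside (0.5, 1.5),
  Bernoulli(Q) inside. Boundary points at exactly 0.5 or 1.5 (a
  measure-zero event) are assigned to the stochastic branch.

The inequalities are taken literally from their printed piecewise
definitions: h1 maps `s ≤ k1` to 0, h2 maps `s < k2` to 0.

The grid search fixes one train/evaluation split and fits a full BiMM per
candidate: k1 over 0.05…0.95 and k2 over 1.05…1.95 in steps of 0.05, plus
h3 — 39 candidates; highest evaluation AUC wins, with ties broken h1
before h2 before h3, then smaller constant. Selecting on the final test
set leaks it into model choice; `grid_search_split` requires an explicit
acknowledgement flag to do so and warns, and the packaged workflow carves
a validation split from the training persons instead.

## Numerical choices

**Mixed-model fitting** is a deterministic MAP. The outer parameters
(β₀, β₁, log σ_b) maximise the marginal posterior with b integrated out by
31-node Gauss–Hermite quadrature; with a scalar random intercept and
two-observation clusters the per-cluster integral is one-dimensional and
the quadrature is exact for practical purposes. A Laplace approximation
was evaluated first and rejected: on binary clusters of size two it
underestimates σ_b by roughly 25% (checked against the exact quadrature
profile), which matters because σ_b controls how strongly Q is anchored
to the person's observed outcomes. The optimiser is Nelder–Mead from a
plain-logistic warm start with log σ_b bounded in [−8, 3]; cluster modes
b̂ are then computed by a strictly concave per-cluster Newton iteration.
Forest probabilities are clamped to [10⁻⁶, 1 − 10⁻⁶] before the logit,
and fitted probabilities are clamped strictly inside (0, 1). When the
data carry no residual clustering the σ_b estimate sits at its lower
bound, reproducing a plain logistic fit; like any variance-component
estimate on ~500 binary pairs, single-replicate estimates scatter (the
boundary takes a point mass), so calibration claims rest on
replicate-averaged bias, which is within 10% for β₁ at 500 persons.

**Forest probabilities fed to the mixed model are out-of-bag.** In-bag
training probabilities from a forest are nearly 0/1, so Q collapses onto
Y, no label ever flips, and the iteration degenerates to a plain forest.
Out-of-bag probabilities are the forest's honest fitted values (and what
an R `randomForest` returns when asked for fitted training predictions).
Rows never out of bag (rare with enough trees) fall back to the in-bag
value; `RFParams(use_oob_probabilities=False)` restores in-bag throughout.

**Class weights.** `majority_class_weight=w` weights the majority class
at `w` with the minority at 1, so `w = 0.37` gives the minority class
1/0.37 ≈ 2.7× influence. Mean Decrease Gini importances are the forest's
impurity-based scores.

**Convergence bookkeeping.** The convergence test uses the absolute
change in posterior log-likelihood (robust to non-monotone trajectories);
max_iter defaults to 50 and reaching it is flagged, not raised. If an
update would collapse the working outcome to a single class, the previous
iteration's model is returned with a diagnostic flag. The forest is refit
with the same random state each iteration and the h3 stream is seeded, so
a fixed seed reproduces trajectories, predictions and written CSVs
byte-for-byte. A corollary used in testing: if no label flips in the
first iteration, the second iteration refits an identical forest, the
posterior log-likelihood change is exactly zero, and the BiMM equals a
plain forest with the same seed.

**Threshold metrics** classify positive strictly above the cut-off, so a
score exactly at the threshold predicts class 0. The AUC is the
Mann–Whitney statistic (ties ½). The t-test on per-partition AUCs is the
two-sample Welch test, as in the protocol, even though partitions are
shared between methods; a paired test would be more powerful but is not
the default. Importance roll-ups count a variable's average score over
the partitions where it reached the top-20 list; `absent_as_zero=True`
counts missing partitions as zeros instead.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes: two rows
per person; person-level covariates identical across a person's rows;
knee-level covariates independent per knee; a configurable fraction of
covariates drawn as Bernoulli(0.5) indicators (mirroring recoded
categorical predictors, default 40% in the reference fixture); outcome
drawn from the logistic model with intercept, covariate contribution
(linear, or a sum of two-way threshold-interaction terms under
`mechanism="tree"`) and the shared person intercept b_i.

Calibration is Monte-Carlo with fixed inner seeds, so it is a
deterministic function of the config: `calibrate_intercept` root-finds
the intercept against the smoothed prevalence estimate
`mean(logit⁻¹(c + η₀))` on a 20 000-person draw;
`tune_random_intercept_sd` sweeps σ_b over a 0.2-step grid (0–3, then
3.5, 4), recalibrating the intercept at each value, and interpolates the
monotone phi-vs-σ_b curve at the target.

The reference fixture is 3000 persons, 10 person-level + 5 knee-level
covariates with geometrically decaying alternating effects (0.5·0.85^j),
prevalence 0.27 and σ_b tuned to phi ≈ 0.3 — the scale and
prevalence/correlation regime of a bilateral knee-pain cohort.

What the generator does **not** emulate: real covariate semantics or
dependence structures, missingness, measurement error, or the 89-variable
codebook of an actual osteoarthritis cohort. Passing tests therefore show
that the algorithmic machinery behaves as specified under the assumed
generating model, not that the clinical results transfer.

## Evaluation fixtures and what they show

On synthetic fixtures with person-level holdout, the honest headline is
**ranking parity**: a BiMM whose split function was selected by the
protocol's own validation grid search matches a plain forest's test AUC
to within a few thousandths, while shifting the sensitivity/specificity
balance in the direction the split function dictates (h1 raises
sensitivity at the price of false positives). Aggressive constants
(e.g. h2 at 1.5 on a 0.27-prevalence cohort) can severely degrade AUC by
deleting most of the minority class — which is exactly why the constant
is tuned.

The high-correlation ordering fixture places all outcome signal in 8
person-level covariates (12 knee-level covariates are pure noise),
σ_b = 2, prevalence 0.3, 600 persons — "person-informative" structure in
the strongest sense. Its forests use `min_samples_leaf=10`: with
single-row leaves, trees memorise the sibling knee's label through the
shared person covariates, the out-of-bag probability absorbs the person
effect, and the mixed model sees no residual clustering (σ̂_b ≈ 0).
Leaf size 10 keeps the random-intercept estimate honest.

Problem sizes in the shipped tests and the acceptance script (cohorts of
400–3000 persons, 10–20 partitions, 60–250 trees) are chosen to keep a
full from-scratch recomputation desk-sized; they are stated alongside
each reported number.

## Known limitations

* Prediction for unseen persons is population-level; the fitted random
  effects are not used at test time, so BiMM cannot exploit test-time
  cluster identity (the longitudinal setting where it would is out of
  scope).
* One random intercept per person; no random slopes, no non-logit links.
* The posterior log-likelihood is a MAP joint density, not a sampled
  posterior; full MCMC diagnostics are out of scope.
* With one binary observation per knee, a per-knee random effect is not
  identifiable; the model is the per-person-intercept reading.
* The Welch t-test treats the two methods' AUC samples as independent
  although they share partitions; its p-values are conservative in the
  common case of positively correlated errors.
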