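# Methods

This note documents the models and procedures implemented in `skipgru`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Data model and missingness

Clinical intake tables often encode an unmeasured value as a literal 0 in
columns where a physiological zero is impossible (serum insulin, BMI,
blood pressure). `TabularDataset` therefore carries an explicit per-column
*zero-as-missing* declaration rather than treating zeros automatically: a
pregnancy count of 0 is valid data, a glucose of 0 is not, and only the
analyst can tell which is which. For the 8-feature two-class layout the
conventional declaration is {glucose, blood pressure, skin thickness,
insulin, BMI}; it is a user-supplied argument, not an inference.

Labels are factorized in first-appearance order, which is deterministic
and stable under row order. All randomness flows from one root seed,
split per stage by a CRC32-based derivation (`spawn_seed`), so any stage
is reproducible in isolation.

## Preprocessing

**Normalization** is standard min–max scaling to [0, 1], fitted per
feature with zero-coded entries excluded. Out-of-range values at
transform time (e.g. a held-out fold wider than the training folds) are
clipped to [0, 1]. A constant feature maps to 0 with a logged warning
rather than dividing by zero.

**Imputation** is threshold-driven per zero-coded feature with decision
fraction 0.05: strictly above the threshold, the feature is regressed on
all other features with a polynomial basis (default degree 2, the
smallest non-linear degree; ordinary least squares) fitted on the rows
where it is observed, and the missing entries are predicted; at or below
the threshold (but above zero) the affected rows are dropped. The strict
">" reading of the threshold is deliberate and tested at the boundary.
Predictions are clipped to the feature's observed range so an imputed
value can never collide with the reserved 0 code and cannot extrapolate
to impossible values. Row deletion (rather than column deletion) was
chosen for the small-missingness branch because it preserves features for
the downstream selector.

Pipeline order is fixed: imputation runs on raw feature units before
normalization, so imputed values participate in the min/max fit. Inside
cross-validation the imputer is fitted on training folds only; on a
held-out fold rows are never dropped — impute-action features are filled
by the fitted model and drop-action features by the training-fold mean,
because a deployed model cannot discard a patient. This is stricter about
leakage than a single global preprocessing pass.

Known limitation: when several columns are zero-coded, the predictors of
one imputation may themselves contain 0 codes from another column; each
feature is treated independently against the raw matrix, which adds noise
to the regression but keeps the procedure order-free.

## RSFS-MPA feature selection

The wrapper selector optimizes real vectors in `[0,1]^d` and binarizes
them at 0.5 (strict; an all-empty mask is rescued by forcing the largest
coordinate on). Defaults: 30 prey, 100 iterations, FADs probability 0.2,
step coefficient 0.5, Levy exponent 1.5 via the Mantegna algorithm,
spiral probability 0.5 with spiral step length k uniform on [0, 1].

Phase boundaries follow the thirds convention (phase 1 below T/3, phase 2
below 2T/3, phase 3 after). The spiral update is applied in phase 1, the
exploration phase, per prey with probability 0.5. The FADs perturbation
draws one uniform r per iteration and applies the same branch to the
whole population, with CF set equal to the adaptive parameter
`A = (1 − t/T)^(2t/T)` (the two share this form in the canonical MPA).
The spiral's L is uniform on [−1, 1]. Boundary handling is clamping.

The objective is pluggable. The default surrogate is a logistic
regression's stratified cross-validated error (3 folds, seeded once per
run so fitness is a deterministic function of the mask within a run) plus
a sparsity penalty, weighted 0.99/0.01. Running the full Skip-GRU inside
~3000 evaluations is not a sensible use of compute; the surrogate ranks
masks nearly identically on class-conditional Gaussian data, and the full
model can be plugged in at small scale via the `fitness` argument.
Fitness values are cached by mask, since many continuous positions
binarize identically.

Elitism guarantees a non-increasing best-fitness history; feasibility
(every coordinate within bounds after every operator) and exact-oracle
behavior at small d (exhaustive enumeration of all 2^d − 1 masks) are
property-tested.

## Skip-GRU classifier

Tabular rows become sequences by the scalar-per-timestep convention: each
selected feature, in dataset column order, is one timestep. The GRU cell
is the standard reset/update formulation over the concatenation
`[h_{t−1}, x_t]`, with biases included (conventional, though often
omitted in compact notation); `h_0 = 0`; the head is affine + softmax;
the loss is cross-entropy.

The jump gate is a two-layer perceptron returning a 2-way softmax whose
first component is the keep probability π_t. Two design choices make the
gate's per-feature relevance read-out identifiable, and both were
necessary in ablation:

* **Positional input.** The gate is shared across timesteps; from
  `[x_t; h_{t−1}]` alone it cannot tell features apart, since after
  normalization all features have similar marginals. A one-hot
  feature-position block is appended to the gate input, which is
  equivalent to a per-feature first-layer bias.
* **Gate usage cost.** With plain cross-entropy the gate is unidentified —
  the GRU can suppress irrelevant inputs by itself, so keep probabilities
  drift arbitrarily. A small budget term `gate_cost · mean(π_t)` (default
  0.01) in the training loss makes keeping a feature cost a little, so it
  must pay for itself through the likelihood. This follows the budget
  penalty convention of skip-RNN training. Without these two choices the
  informative-vs-noise keep-probability gap was statistically invisible;
  with them it is large and stable.

The hard skip rule (`π_t < 0.5 ⇒ h_t = h_{t−1}`, exact carry-over) is not
differentiable, so training uses the soft relaxation
`h_t = π_t·GRU(...) + (1 − π_t)·h_{t−1}` and inference uses the hard rule;
both are exposed as forward modes and coincide exactly when π_t ∈ {0, 1}.
A gate output exactly at the threshold counts as keep.

**Training.** Adam with decoupled weight decay; default learning rate
1e-4, weight decay 0.1, dropout 0.3 on the hidden state between timesteps
and before the head (training only, inverted), batch size 32, hidden size
128, clip-by-norm threshold 1.0. Clipping is global: the norm is taken
over all parameter groups jointly and, when it exceeds the threshold,
every gradient is scaled by the same factor — direction-preserving by
construction. Weights initialize from a scaled-uniform (Glorot) scheme
with zero biases. Non-finite losses or gradients raise immediately as a
training-instability signal rather than propagating silently.

The defaults above target real clinical cohorts trained for many epochs.
The test suite, the examples and the acceptance script use a small-data
recipe — hidden 16–32, learning rate 5e-3, weight decay 0.01, dropout
0.1, 60–100 epochs — because a few hundred synthetic rows neither need
nor tolerate the heavy regularization of the full-size configuration.

All gradients are hand-derived backpropagation through time in NumPy;
analytic gradients are verified against central finite differences, and
the 1-unit cell and gate against pencil-and-paper arithmetic.

## Metrics and cross-validation

Accuracy, sensitivity, precision, specificity and F1 are computed from
one-vs-rest confusion counts and reported as percentages. Binary problems
use the positive class (index 1). Three-class problems macro-average
per-class one-vs-rest values and every report is labeled with its
averaging mode; F1 is the harmonic mean of the *reported* precision and
sensitivity, so the identity F1 = 2PS/(P+S) holds in both modes by
construction. Zero-denominator cases return 0 with a logged warning,
which keeps fold aggregation total.

Cross-validation is stratified (the 103/53/844-style imbalance of real
clinical cohorts makes unstratified folds degenerate) with seeded
shuffling, k = 5 by default. Reports expose mean-over-folds, per-metric
standard deviation, and the best fold, since published summaries do not
always say which they quote.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
labels from configurable priors; informative features as class-conditional
Gaussians with adjacent class means separated by `effect_size` within-class
SDs; noise features independent of the label; an optional polynomial link
between two features for imputation experiments; an affine map of every
feature into a strictly positive clinical-looking range; and zero-coded
missingness imposed *after* that map, so 0 is out of support and
unambiguous. The ground-truth record (informative indices, pre-missingness
values, missing mask, link) suffices to score selection recovery and
imputation RMSE without re-deriving anything.

Class-conditional Gaussians were chosen because they give a computable
Bayes error, anchoring accuracy expectations. What the generator does not
emulate: real marginal shapes (skew, zero-inflation beyond the missing
code), feature correlations other than the explicit link, label noise,
and measurement batch effects. Passing tests therefore demonstrate the
machinery is correct and recovers planted structure — not that any
particular accuracy carries over to a real cohort.

Presets: `pima-like` (768 patients, 8 features, 500/268 two-class split,
missingness fractions mirroring the real intake rates of each column) and
`lmch-like` (1000 patients, 12 features, 103/53/844 three-class split).
Preset effect size is 1.0; recovery experiments elsewhere use 1.5–2.0,
chosen as a moderate, realistic separation for clinical risk factors.

## Numerical choices and degenerate inputs

* Min–max on a constant feature returns 0 (not NaN); inversion round-trips
  non-degenerate features to 1e-9 relative.
* Binarization at exactly the threshold selects nothing (strict >); the
  empty mask is rescued by argmax.
* Softmax is computed with max-shift; cross-entropy floors probabilities
  at 1e-12.
* Prediction ties break to the lowest class index.
* Surrogate CV folds are capped at the smallest class count; fewer than 2
  is an error.
* Levy draws are raw Mantegna (no extra step scale); clamping bounds the
  occasional huge step.

## Problem sizes

Tests and the acceptance script run on cohorts of 150–1000 rows with 3–12
features, hidden sizes 2–32 and ≤100 epochs — sizes at which every
property under test is already fully expressed and the whole suite runs
in a few minutes on one CPU.
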