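# Methods

`slepredict` implements and compares two ways of predicting hospitalization
for systemic lupus erythematosus (SLE) from longitudinal, irregularly
sampled clinical records: a *Differential* approach (lagged-difference
feature engineering feeding a bagged ensemble of six non-temporal
classifiers) and an *LSTM* sequence classifier. Because the underlying
clinical data are proprietary, the package ships a synthetic cohort
generator that reproduces the structural properties the methods rely on,
so every stage is exercisable and testable end to end.

## Task formulation

Each patient's record is regularized to 6-month bins. For a task
"observe X months, predict Y months ahead" (X ∈ {6, …, 36}, Y ∈ {3, 6, 9,
12}), sliding windows of k = X/6 consecutive bins are extracted per
patient, stepping one bin at a time; the label is 1 iff a hospitalization
falls in the half-open interval (window end, window end + Y]. Only windows
whose end leaves at least 12 months of follow-up are used, which makes the
instance total for a given k independent of Y: with the default timeline
(six observation bins + 12 months follow-up) each patient contributes
7 − k windows, so a 925-patient cohort yields 5550, 4625, 3700, 2775,
1850, 925 instances for k = 1…6. An event exactly on a window-end boundary
belongs to the *following* horizon, so consecutive label windows never
double-count an event.

## Synthetic cohort generator

One latent disease-activity factor per patient drives everything:

    a_i(t) = level_i + trend_i · (t − t_mid) + u_i(t),   u_i ~ AR(1)

with `level_i ~ N(0, 0.7²)`, `trend_i ~ N(0, 0.06²)` per month (trend
centred mid-observation), and monthly AR innovations (φ = 0.9, sd 0.12).
Observed channels are category-specific: laboratory values are
`loading_j · a + N(0, 0.5)`; manifestation/medication flags are indicators
of the same noisy signal exceeding a per-feature threshold; utilization
features are Poisson counts with log-rate linear in activity. Visits
arrive Poisson(2) per 6-month bin at uniform times, and each feature is
missing per visit with probability 0.2. Demographics are five static
covariates (age z-score, female flag, two binary flags, one continuous
index) that do not enter the hazard — they act as realistic nuisance
columns.

Hospitalization events are drawn month by month from

    h_i(t) = sigmoid(base + β_level · a_i(t) + β_delta · d_i(t)),

where `d_i(t)` is the difference between the last two half-year activity
averages — the scale of change that binned features can actually observe
(raw month-to-month jitter would inflate hazard variance without being
recoverable). Defaults (base −6.9, β_level 0.3, β_delta 5.0) were
calibrated once so the positive-instance prevalence at X = 6M rises from
≈2% at Y = 3M to ≈6.5% at Y = 12M, the profile the method is designed
for. Two presets bracket the operating range:

* `signal_preset()` (base −7.2, β_level 0.2, β_delta 6.0, trend sd 0.08):
  the hazard is dominated by recent *change*, so between-step delta
  features carry the signal — the premise of the Differential approach. A
  linear oracle on the delta features reaches AUC ≈ 0.86 under this
  preset, so an adequate learner should clear 0.75.
* `null_preset()` (both β = 0): labels are independent of features;
  honest evaluation must return AUC ≈ 0.5.

What the generator does *not* emulate: real marginal feature
distributions (only category types), informative visit frequency (sicker
patients visiting more often), multi-site heterogeneity, or competing
risks. Passing tests therefore demonstrate that the pipeline's mechanics
are correct and that it can recover a planted temporal signal — not that
any particular clinical performance level transfers to real data.

## Preprocessing

Visits within a bin are aggregated per category: labs averaged (multiple
lab draws in a half-year act as one averaged visit), binary flags take the
maximum (present at any visit ⇒ present that half-year), utilization
counts summed. Missing cells are then filled per feature per patient:
interior gaps by piecewise-linear interpolation through the observed bins
(observed points are honored exactly), leading/trailing gaps by
extrapolating the least-squares line through all observed points (robust
to a noisy first/last observation; constant when only one point exists).
Binary features are clipped to [0, 1] after imputation. A
`method="least_squares"` flag switches to a single fitted line
everywhere. A feature never observed for a patient falls back to the
cohort-level mean of observed cells. Imputation is idempotent and never
alters observed cells. Binning precedes imputation; an impute-first order
is not offered because interpolation is defined on the regular bin grid,
not on irregular visit times.

## Differential approach

Each windowed instance is flattened to
`[demographics (5) | raw features for steps 0…k−1 | deltas raw@t − raw@(t−1)
for t = 1…k−1]`, giving p = 5 + 52k + 52(k−1) columns (a `compact` layout
keeping only step-0 raw values is available). The identity
raw@0 + Σ deltas = raw@(k−1) holds for every row by construction.

Class imbalance is addressed by bagging with random undersampling: each
of `n_bags` (default 100) balanced bags holds *all* minority instances
plus an equal number of majority instances drawn with replacement from the
whole majority pool. One sub-ensemble of six learners — decision tree,
random forest, logistic regression, Gaussian naive Bayes, one-hidden-layer
neural network, RBF SVM (Platt-scaled probabilities) — is fitted per bag.
The bag score is the mean of the six class-1 probabilities (soft voting;
a hard vote-fraction flag exists — soft is the default because ranking
metrics need continuous scores), the model score is the mean over bags,
and the decision threshold is 0.5 (score ≥ 0.5 ⇒ positive). Features are
standardized with statistics fitted on the training split only; tree-family
learners receive the unscaled panel, all binary 0/1 columns pass through
unscaled everywhere.

## LSTM

Sequences keep their k × 52 structure with the 5 demographics appended at
every step (equal per-step dimensionality, 57). The single-layer LSTM cell
follows the standard gate equations (input, forget, output gates over
`[h_{t−1}, x_t]`; candidate state through tanh; `C_t = f∘C_{t−1} + i∘C̃`;
`h_t = o∘tanh(C_t)`), one weight set shared across steps, class-1
probability = logistic of an affine map of the final hidden state. It is
implemented directly in NumPy with exact backpropagation through time
(verified against central finite differences) and mini-batch Adam.
Training defaults are 50 epochs, batch size 72, learning rate 1e-4,
binary cross-entropy — sized for cohort-scale data; toy problems
typically want a larger learning rate. Initialization is uniform ±1/√(H+d) with
forget-gate bias 1. A non-finite loss aborts with a diagnostic rather
than training on. Imbalance is handled by minority oversampling: each
minority sequence is duplicated r − 1 times, r = round(majority/minority)
(half-to-even; floor available), applied to the training portion only.

## Evaluation

Generalization is estimated with stratified outer k-fold CV (default 20
folds; stratification is on because unstratified 20-fold splits at 1–2%
prevalence routinely produce positive-free folds, and the fold count
auto-reduces with a warning when positives are scarcer than folds). An
inner k-fold grid search selects hyperparameters by mean AUC (first
maximum on ties), one model is refit per outer fold with the chosen
parameters, and reported performance is the arithmetic mean of per-fold
metrics — never pooled scores. Metrics: accuracy, recall, specificity,
PPV, F1 and a configurable F_β at threshold 0.5, plus AUC computed as the
Mann–Whitney rank statistic with ties credited 0.5. Undefined ratios
(e.g. PPV with no positive predictions, AUC on a single-class fold) are
reported as NaN and excluded from fold averages, never coerced to 0. The
β of the "F0" slot defaults to 0.5 (weighting precision), since F_β at
β = 0 degenerates to precision exactly.

Bags, oversampling multisets and scaler statistics are computed strictly
inside each training split; `nested_cv` logs every fold assignment, bag,
oversample multiset and scaler-fit index to a run manifest so the
no-leakage property is asserted mechanically in the test suite.

Window instances overlap within a patient, and their label intervals
overlap too. Instance-level splitting is the default (all windows are
pooled and split at random); a `group_by_patient` flag keeps each
patient's windows on one
side of every split. The distinction matters: on null-preset data
(labels independent of features) instance-level splitting still yields
held-out AUC ≈ 0.58, because a model can recognize a training patient's
feature signature in the test fold and exploit the shared outcome
interval. The type-I sanity experiment (`experiments.null_auc`) therefore
holds out whole patients; the signal-recovery experiment keeps
instance-level nested CV.

## Desk-scale experiment sizes

The canned experiments are sized for a single CPU: signal recovery uses
the full 925-patient cohort at X = 12M, Y = 12M with 4 outer / 5 inner
folds, 20 bags (5 during inner selection) and a two-candidate logistic
grid (≈3–4 min); the null experiment averages 10 seeded replicates of
600-patient cohorts at X = 6M with a 40% patient-grouped holdout
(≈1–2 min). The averaging over ten replicates narrows the standard error
of the null AUC to ≈0.01 so the chance-level check is stable.

## Known limitations

* The generator's single-factor latent structure makes features more
  mutually informative than real EHR panels; absolute AUCs on synthetic
  data say nothing about clinical performance.
* Oversampling by duplication interacts with instance-level CV exactly as
  discussed above; group-aware splitting is provided but is not the
  default.
* The LSTM is CPU-bound NumPy; it is sized for cohort-scale experiments,
  not large-scale deep learning.
* No significance testing, probability calibration, or feature-importance
  analysis is included.
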