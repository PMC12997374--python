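# Methods

`spiralselect` implements a fully automated screening pipeline for
tabular clinical data with a binary outcome (its reference use case is
early chronic-kidney-disease detection from the public 25-attribute
screening table): leakage-safe preprocessing, wrapper feature selection
by a spiral-search binary gravitational search algorithm (SSS-BGSA),
classification by a deep belief network (DBNN) of stacked restricted
Boltzmann machines, hyperparameter tuning by elephant herding
optimization (EHO), nested stratified cross-validated evaluation with
probability-calibration assessment, and exact Shapley attribution of
the selected biomarkers.

## Preprocessing

Rows with at least half of their attributes missing are dropped once,
up front (the label column never counts). All remaining statistics are
fitted per training fold and applied unchanged to held-out rows:

- **Imputation.** Nominal cells take the training mode (ties break to
  the lexicographically smallest category, for determinism); numeric
  cells take the training median.
- **Domain validation.** Nominal cells are trimmed and lower-cased,
  then checked against the column's allowed category set (for example
  hypertension ∈ {yes, no}); anything else — "?", "unknown",
  misspellings — becomes missing and is later imputed. Only
  case/whitespace normalization is attempted; no fuzzy correction.
- **Outlier removal.** A row is dropped when any observed numeric cell
  is more than 3 training SDs from the training mean; constant columns
  contribute z = 0.
- **Class balancing.** SMOTE with k = 5 Euclidean nearest minority
  neighbours oversamples the minority class to parity, training folds
  only. Distances are measured on the imputed, standardized, one-hot
  encoding; a synthetic row interpolates its parents' numeric cells
  (x_i + λ(x_j − x_i), λ ~ U(0,1)) and copies nominal cells from the
  nearer parent (λ ≤ 0.5 → x_i), since categorical interpolation is
  undefined. Synthetic rows carry a flag and the cross-validation
  driver refuses any split that would put one in a test set.
- **Standardization.** Numeric columns map to training z-scores. The
  mean and SD are computed on the *median-imputed* training column, so
  a transformed training fold is exactly zero-mean/unit-variance;
  medians themselves come from observed values only. The scaling state
  used by the z-filter is fitted on the raw training fold; it is refit
  on the cleaned rows before encoding.

Order within a fold: validate → z-filter → SMOTE → impute/standardize/
encode. The row filter runs once on the raw table before any split,
matching the convention that the "preprocessed cohort" row count is a
property of the dataset, not of a fold.

## Feature selection (SSS-BGSA)

Agents are binary masks over the original attributes (a mask selects
whole one-hot groups). Fitness balances inner-CV error against subset
size: f = α·error + β·|S|/D with α = 0.9, β = 0.1. The all-zero mask is
charged error 1 so it can never win.

Gravitational dynamics follow the standard GSA form: masses
m_i = (f_max − f_i)/(f_max − f_min + ε) normalized to sum 1; force of j
on i is G·M_i·M_j·(x_j − x_i)/(R_ij + ε) with Euclidean R_ij; the M_i
cancels analytically in the acceleration so massless agents still move.
G(t) = G0·exp(−15·t/T); the force pool (kbest) shrinks linearly from N
to 1; the inertia weight w(t) falls linearly from 0.9 to 0.4. G0 = 100
and the inertia bounds are the GSA literature's usual values (none are
printed in the reference setup) and are config-exposed. Velocities
binarize through the stochastic sigmoid transfer S(v) > U(0,1); a
config switch substitutes the random-coefficient velocity memory or a
position-argument transfer, two formulation variants that circulate for
this algorithm family.

With probability SP (default 0.5; no printed value exists) an agent
takes a logarithmic-spiral step around the incumbent best instead:
x + (x_best − x)·e^{bθ}·cos(2πθ) per dimension, θ ~ r·U(−1, 1) with
spiral radius r = 0.5 and expansion constant b = 1. **Binarization of
the spiral step is the one place this implementation deliberately
departs from the literal pseudocode form.** The spiral position is a
geometric interpolation inside the unit hypercube — already on
probability scale. Passing it through the sigmoid squashes every value
into the [0.5, 0.73] band, which empirically turns the spiral into a
bit randomizer and makes SP = 0.5 *worse* than SP = 0, inverting the
algorithm's documented purpose. The default therefore thresholds the
clipped spiral position against U(0,1) directly, so θ = 0 lands exactly
on the best mask and the operator behaves as the local-exploitation
move it is described as; the sigmoid reading remains available as
`FSConfig(spiral_binarize="sigmoid")` for comparison.

Setting SP = 0 recovers plain BGSA and is the package's internal
ablation baseline.

**Surrogate fitness.** Retraining the full DBNN for every agent at
every iteration is computationally disproportionate, so mask fitness is
scored by the stratified inner-CV error of a regularized logistic
surrogate (deterministic per mask, memoized). The final model is always
the tuned DBNN on the winning mask.

## Classifier (DBNN)

Two stacked RBMs (default widths 64 and 32) are pretrained greedily by
CD-1 — one Gibbs step, sampled hidden states, mean-field visible
reconstructions — with learning rate 0.01, momentum 0.9 and weight
decay on the weights only, 50 epochs by default. Standardized inputs
are min–max rescaled to [0, 1] and treated as Bernoulli means for the
first layer (mean-field visibles), the standard practical choice for
continuous tabular inputs under a binary energy model. The stack then
unrolls into a feed-forward sigmoid network with a 2-unit softmax head,
fine-tuned by momentum SGD on cross-entropy with inverted dropout
(rate 0.3), L2 weight decay (1e-4), minibatches of 16, and early
stopping on a held-out validation split (patience 10 epochs by
default); the best-validation snapshot is returned.

Momentum SGD on sigmoid nets can diverge at aggressive learning rates
or stall at timid ones; both present as "validation never improves" and
would silently return the useless initial snapshot. `DBNNClassifier`
therefore retries at the base rate / 4 and × 4 when the first fit never
improves validation materially, and keeps the best-validated attempt.

## Hyperparameter tuning (EHO)

Five clans of ten elephants (defaults) search over (log10 η, momentum,
log10 λ, first-layer width n), with the second layer n/2; search
ranges are η ∈ [1e-4, 1e-1], momentum ∈ [0.5, 0.99], λ ∈ [1e-6, 1e-2],
n ∈ [16, 128] (none are printed; all config-exposed). Each member
drifts toward its clan matriarch (x + a(x_best − x)r, a = 0.5,
r ~ U(0,1)); the matriarch moves to β = 0.7 times the clan centre; the
worst member of each clan is reinitialized by
x_min + (x_max − x_min + 1)·rand and *clamped back into the box* (the
raw draw can overshoot the upper bound — bound integrity wins over
formula literalism). A global best kept outside the herd makes the
trace non-increasing, and the herd is seeded with the incumbent
(default) configuration, so tuning never returns a vector its own
objective scores worse than the configuration it started from — at
small evaluation budgets an unseeded herd occasionally selected
degenerate settings. The objective is the inner-CV mean squared error
of the softmax outputs against one-hot targets (summed over the two
output units, averaged over instances, averaged over folds). Stopping:
iteration improvement below 0.001 or 50 iterations (a 100-iteration
variant is a config override).

The integer width evolves continuously and is rounded at evaluation
time. The centre move replaces the matriarch's own clan update each
iteration (the formulation leaves this open).

## Evaluation

Outer stratified 5-fold cross-validation, repeated (10 repeats by
default), measures generalization only: preprocessing statistics,
SMOTE, the feature mask, hyperparameters and the network are all fitted
strictly inside each outer-training split, with model selection on
inner folds (3 by default; unstated upstream). Reported metrics are the
nine confusion-table measures (undefined ratios are reported missing,
never zero), rank-based AUC with tie correction, and the calibration
set: Brier score, expected calibration error over 10 equal-width bins
(averaged over non-empty bins; a count-weighted variant by flag), and
the calibration slope from a logistic recalibration of the outcome on
logit-clipped predicted probabilities (clip 1e-6). Aggregation is
mean ± SD over all fold×repeat results; calibration measures pool each
repeat's predictions, mirroring the per-repeat reporting convention.
Paired two-sided t-tests compare per-run accuracies of competing
configurations. The decision threshold for confusion metrics is 0.5.

## Explanation

Exact Shapley values over the selected subset: with d ≤ ~7 selected
biomarkers the 2^d coalition lattice is enumerated outright, so
efficiency (Σφ = f(x) − baseline) holds to float tolerance and no
sampling error enters the tests. The coalition value v(S) is the mean
model output over background rows (the preprocessed training fold) with
the features in S pinned to the explained patient — an interventional
replacement that assumes feature independence; attributions on strongly
correlated real biomarkers should be read with that caveat. Positive
values push the predicted CKD probability up. Global importance is the
mean absolute attribution per feature; the signed per-sample table is
retained for beeswarm-style inspection.

## Synthetic cohorts

The generator emulates the structure of the reference screening table:
400 records, 11 numeric attributes (standard normal) and 14 nominal
attributes (2–5 uniformly likely levels), positive prevalence 0.625
(250/400), 7 planted informative features, MCAR missingness. Each
informative feature contributes a signed unit-variance score to the
label logit with slope `effect_size`; latent noise (`noise_sd`, default
0.5) adds unexplained variation; the intercept is calibrated by
bisection so the realised mean probability equals the target
prevalence.

Defaults were fixed by oracle analysis of the generating model itself:
`effect_size = 4.0` places the cohort in the strongly separable regime
the real table exhibits (Bayes-optimal AUC ≈ 0.99), and
`missing_rate = 0.05` keeps single-value imputation viable given that
the planted features are *independent*. That independence is the main
deliberate simplification: real CKD biomarkers are redundant and
correlated, which is precisely why the real table tolerates much higher
per-attribute missingness and why feature selection there has several
near-equivalent optima. Passing tests on these cohorts demonstrates
that the machinery recovers planted structure and generalizes under the
stated noise model — not that the clinical numbers of the reference
study transfer to other cohorts.

`inject_high_missing_rows` builds row-filter fixtures by forcing exactly
k rows to carry ⌈frac·m⌉ missing cells, so the ≥50 % filter's removal
count is known by construction.

## Problem sizes used in tests and reporting

The shipped test suite and the acceptance script run the full pipeline
at reduced budgets chosen as the package's own desk-scale defaults: a
single evaluation repeat, selection at the full 100 iterations with the
logistic surrogate, EHO with 2 clans × 4 over 3 iterations against a
lightened training budget, DBNN fine-tuning capped at 300 epochs
(pretraining 10), and the spiral-vs-plain ablation at 40 iterations ×
10 seeds. The library defaults remain the reference values (20 agents /
100 iterations, 5 × 10 elephants, 50 pretraining epochs, 5 outer folds
× 10 repeats).

## Known limitations

- The spiral operator's binarization is a design choice (above); the
  literal sigmoid reading is preserved but demonstrably harmful.
- On the default synthetic benchmark the deep belief classifier sits a
  few AUC points below a plain logistic fit on the same selected mask:
  the planted signal is linear in the features, so the logistic model
  is the Bayes family there, and a small nonlinear network trained on a
  few hundred rows pays a variance price. On real clinical tables with
  interactions the ordering need not hold; the benchmark measures
  recovery of planted structure, not model-family superiority.
- The logistic surrogate scores masks by linear separability; a subset
  whose value is purely interactive could be under-ranked (the planted
  benchmark's signal is additive, so this does not bite there).
- Calibration-slope fitting can fail under perfect separation; it is
  then reported missing with a warning rather than extrapolated.
- The generator's independent features and MCAR missingness are
  idealizations; see the synthetic-cohorts section.
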