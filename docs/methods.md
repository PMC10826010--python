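# Methods

This note documents the models, the evaluation procedures, the fixture
generator, and the numerical and design choices made where the problem was
genuinely open. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external experiments.

## Data model

A dataset couples a static table (one row per subject) with a series block
(per subject, `T` samples of each dynamic variable on an integer time axis
`0..T-1`). A variable schema types every column (numeric/categorical,
static/dynamic, category order, current encoding). Series may be ragged and
contain NaNs before preprocessing; every downstream stage requires an
aligned, complete block.

Preprocessing follows the usual pipeline for longitudinal health data:

* **Missingness budget + linear interpolation.** Subjects whose total
  missing dynamic samples exceed a budget (default 30) are excluded and
  reported; remaining gaps are linearly interpolated.
* **Forward filling** imputes each missing cell with the most recent valid
  value (appropriate for step-like clinical measurements where a missing
  reading means "unchanged").
* **Boundary rule** (both fillers): a missing prefix is backfilled from the
  first valid sample, a missing suffix holds the last valid value. This is
  a documented convention — it keeps subjects with edge gaps rather than
  discarding them.
* **Truncation** to the length of the shortest series; **label/one-hot
  encoding** with codes fixed by schema category order (not order of
  appearance, for determinism across files); **min-max scaling** to [0, 1]
  (the range the sigmoid-output generators produce; constant columns map to
  0 and invert to the constant; inverse∘forward is the identity to 1e-9).

CSV I/O writes missing values as empty fields, accepts `NA` on read, and
round-trips values exactly (`float_precision="round_trip"`).

## Generative backends

All backends train on a flat design matrix: static numeric columns min-max
scaled, static categoricals one-hot, series min-max scaled per variable and
flattened time-major. Sampling inverts the representation (inverse scaling;
one-hot decoded by argmax).

**WGAN-GP with alignment loss.** Generator: MLP, ReLU hidden layers,
sigmoid output; critic: leaky-ReLU MLP with scalar output. Generator loss

    L_G = -E[D(G(z))] + λ · Σ_{i>j} | r̂_ij − r_ij |

with the disparity term computed per batch over the *numeric* columns of
the design matrix (one-hot indicators excluded: Pearson correlation is the
quantity being aligned, and probability indicators are not meaningfully
Pearson-correlated). λ defaults to 10.0. The critic is trained with the
interpolated-sample gradient penalty at coefficient 10 and updated 5× per
generator step; learning rate 0.001 (Adam, betas 0.5/0.9); defaults of
5000 epochs and batch 64 are the full-scale settings, with short runs used
throughout the tests. Batch-level (rather than epoch-level) real
correlations are a documented choice; so is restricting the penalty to
numeric columns.

*Gradient penalty without second-order autodiff.* The networks run on a
small numpy reverse-mode engine (`stsg.nn`). The penalty needs
`∂/∂θ ‖∇_x D(x̂)‖`; for a leaky-ReLU critic, `∇_x D` is a product of weight
matrices and activation-slope masks. The masks are locally constant (the
activation is piecewise linear, its second derivative is zero a.e.), so the
analytic product is an ordinary first-order expression in the weights. The
test suite validates this against central finite differences.

**DGAN-style backend.** A metadata MLP generates the static component
(sigmoid for numeric columns, softmax per categorical block, argmax-decoded
at sampling); its output is concatenated with fresh noise into a tanh RNN
at every iteration, and each iteration emits `S` records (so `T/S`
iterations per series; `T` not divisible by `S` is right-padded by
repeating the last sample and trimmed after generation). Two leaky-ReLU
critics — auxiliary (metadata only) and combined (metadata + series) — are
both trained with the gradient penalty at coefficient 10. The generator
minimises `-E[D_comb] − E[D_aux]`.

**Baseline.** Sampling permutes real design-matrix rows (without
replacement while `n ≤ n_real`, with replacement for the excess) and adds
Gaussian jitter of scale `jitter × per-column std` to numeric columns,
clipped to the scaled range. At jitter 0 and `n = n_real` the output *is*
the real multiset, which makes the baseline the end-to-end oracle: the
whole evaluation stack must then return its theoretical optima
(correlation similarity 1, PRD F₈ = 1, autocorrelation MAE 0, TSTR
similarity 1, MIA copy precision 1). Permutation rather than bootstrap
resampling is deliberate — a bootstrap draw would perturb the empirical
correlations and break the exactness of the oracle.

## Approaches and pseudo-cross-validation

A1 augments the real metadata with per-series max/min/mean, trains a
metadata-only generator on the augmented table, samples synthetic rows, and
couples them to the real series pool. A2 additionally trains a series-only
generator and couples synthetic metadata to the synthetic pool. A3 trains
one joint model. The joint-only DGAN backend serves A1/A2 by training
jointly and keeping the relevant component at sampling time.

**Coupling** is a minimum-distance assignment in summary space: Euclidean
distance on per-column z-scores fitted on the pool (so heart-rate and
ventilation summaries contribute comparably; a raw-space option exists).
`hungarian` solves the optimal assignment; `greedy` (kept for scale) pairs
rows in input order to the nearest unused pool subject and is never better.
Pairing is injective — reusing one real series for several synthetic
subjects would distort marginals and the privacy analysis. Synthetic
summary columns are dropped from the output by default because they
disagree with the attached series.

**Pseudo-cross-validation** trains once and samples `n_folds = 8` equally
dimensioned synthetic datasets with distinct derived seeds (per-fold
retraining is available by flag but 8× more expensive; sampling variability
is the quantity the folds are meant to absorb). Metrics are aggregated as
mean ± sample std; approaches are compared per metric with Welch's
two-sample t-test (fold variances differ between approaches, so the
unequal-variance form is the safer default), significance at p < 0.05.
Identical fold vectors are reported as p = 1 by convention.

## Evaluation details

**Record flattening** (used by DLA, PRD, TSTR, MIA): static numerics,
one-hot categoricals, per-variable series summaries, and series values
downsampled to at most 16 evenly spaced points — bounded dimension for long
series. Whether these metrics should see whole subjects or individual time
stamps is an open representational question; whole subjects are used
because the privacy unit and the coupling unit is the subject.

**Association matrix**: Pearson for numeric pairs, Cramér's V (from the χ²
statistic, zero-marginal rows/columns dropped) for categorical pairs, and
the R² of regressing the numeric feature on the categorical indicators
(equivalently the between-group variance share) for mixed pairs. Variables
covered: static variables, each dynamic variable's per-subject time mean,
and the max/min summaries. Zero-variance features yield masked (NaN) cells
excluded pairwise, never silently zeroed. The preservation score is the
standard cosine similarity between strict lower triangles; a variant that
normalises by coordinate sums instead of norms exists behind a flag for
comparability but is unbounded and not recommended.

**DLA** trains five fixed classifiers (random forest, 100 trees, Gini;
10-NN; decision tree, Gini; linear SVM, C = 100, 300 iterations; MLP with
64+32 ReLU units, Adam, batch 200, lr 0.001, 100 epochs) on a stratified
70/30 split of pooled real(0)/synthetic(1) records, standardized on the
training part, and reports held-out AUROC per model and their mean. Near
0.5 means indistinguishable. Caveat: when the synthetic set contains
verbatim copies, each held-out record has an identical opposite-label twin
in training and the score collapses *below* 0.5 — expected for the copy
oracle, not a defect.

**PRD** pools both record sets, standardizes, clusters with k-means
(k = 20, seeded, 1001 angles — conventional settings for the
cluster-histogram estimator), and sweeps `α(λ) = Σ min(λ p_c, q_c)`,
`β(λ) = Σ min(p_c, q_c/λ)` over `λ = tan θ`. A histogram-mode entry point
bypasses clustering and is verified against an independent λ-sweep to
1e-12. The summary is the maximum `F_γ` with γ = 8, weighting coverage
(recall) above sample quality. Note the single curve is *not* pointwise
symmetric under (α, β) swap for asymmetric histograms; the correct symmetry
— swapping the real/synthetic roles mirrors the curve — is what the suite
asserts.

**Autocorrelation MAE**: per variable, the sample ACF at lags
1..min(40, T−1) is averaged over subjects separately for real and
synthetic; the metric is the mean absolute difference of the two mean
functions. Constant series are masked with a warning. For A1 the value is
0 by construction (the series are real) and serves as the baseline for the
other approaches.

**TSTR/TRTR**: the task is predicting the per-subject time mean of a
target dynamic variable from all other flattened features (the paper-style
regression target for longitudinal inputs is otherwise underdetermined).
Five regressor twins mirror the DLA settings; both twins are tested on the
same held-out real subjects and the TSTR metric is the cosine similarity of
the two 5-vectors of MAEs.

**MIA**: records are flattened and per-column min-max normalized on the
union (cosine distance on raw mixed-unit records is dominated by
large-scale columns). The candidate set holds a fraction (10–50 %) of the
training subjects as members plus an equal count of holdout subjects as
non-members; a candidate is disclosed when *any* synthetic record lies
within cosine distance 0.2. Precision = members flagged / all flagged,
defined as 0 when nothing is flagged (keeps the precision curves
plottable). Equal-count non-members are a design choice: precision needs a
false-positive population, and the construction makes the copy scenario
exactly checkable (precision 1 when synthetic records are member copies and
the holdout lies beyond the threshold).

## Fixture generator

The fixture module emulates the *shapes* of the study datasets, not their
physiology, so that every stage is testable without any download.

* `exercise`: metadata {age, sex (85 % male), height, weight, temperature,
  humidity}; series {HR, VO2, VCO2, RR, VE} over a warmup → ramp →
  saturation → recovery profile. All five series share a subject effort
  amplitude `A = 80 + m·(3 z_age + 4·male + 2 z_wt) + 6 f`, with `f` a
  metadata-independent fitness latent and `m = metadata_effect`. The shared
  amplitude produces nonzero dynamic–dynamic correlations by construction;
  `m` tunes the metadata–series dependence from none (`m = 0`, |corr| < 0.1
  at n = 500) to strong (`m = 5`, corr > 0.5) — the property that separates
  joint generation (A3) and metadata coupling (A1) from independent
  generation (A2).
* `icu`: binary gender (configurable mixing weight) and 5-class ethnicity;
  six step-like series (pressures, FiO2, urine output, a binary vasopressor
  flag, integer GCS) driven by a piecewise-constant latent severity path
  (geometric segment lengths, mean 8 steps) — deliberately suited to
  forward-fill testing.

Missingness injection masks exactly `round(rate × cells)` cells, uniformly
or in contiguous blocks. What the fixtures do *not* model: realistic
marginal distributions, measurement artefacts, irregular sampling, or
long-range dependence beyond the profile/latent structure — so green tests
demonstrate correctness of the machinery, not clinical realism of any
generated data.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scale, chosen as
the smallest sizes at which each property is stable: 200-subject fixtures
for the copy oracle, n = 2000 for the DLA chance-level calibration,
50 subjects × 48 steps × 200 epochs for adversarial smoke runs (finite
losses, alignment-penalty decrease and better-than-shuffled correlation
structure on a 3-seed majority). Full-scale defaults (5000 epochs) remain
the config defaults. All randomness flows through explicit integer seeds;
training is bit-reproducible on a fixed platform. Degenerate inputs are
handled explicitly: constant columns scale to 0 and invert; zero-variance
features are masked in associations; empty clusters follow the min-with-0
semantics of the PRD formulas; identical fold vectors compare at p = 1.

## Known limitations

* The adversarial backends are faithful small-scale implementations; at
  desk scale they learn coarse correlation structure, not
  publication-grade synthesis quality.
* Cosine-threshold MIA is one attack family; attribute-inference,
  reconstruction and shadow-model attacks are out of scope.
* Autocorrelation is the only time-series-specific resemblance metric;
  trend/seasonality descriptor suites are not included.
* Coupling is hard assignment without replacement; soft or probabilistic
  matching is out of scope.
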