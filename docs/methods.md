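# Methods

`qsarbench` measures how three experimental choices shape multiclass
classification performance on descriptor data: the dataset size (NS), the
train/test split ratio (SR), and the learning algorithm (ML).  A fourth
"factor" is the performance parameter itself (PP): models are scored with a
25-parameter battery, and the analysis asks which parameters react to which
choices.  This note records the models, conventions, and design decisions,
and what the synthetic data does and does not establish.

## The factorial harness

One run walks every (NS, SR, ML) cell of a grid:

1. **Balancing.** The input table is undersampled so every class keeps the
   minority-class count (majority rows drawn uniformly without replacement;
   the minority class passes through intact).  Repeated `balance_reps`
   times so all rows eventually participate.
2. **Subsampling.** Exactly NS rows are drawn, stratified `NS // K` per
   class with the remainder assigned to seeded classes.  The sentinel
   `"total"` keeps the whole balanced table and collapses this loop to one
   iteration.
3. **Splitting.** A stratified train/test split keeps SR percent for
   training; per-class train counts follow the largest-remainder rule so
   `|train| = round(SR/100 * N)` exactly.  Repeated `split_reps` times.
4. **Fitting and scoring.** Each algorithm is fit once per split.  Two
   batteries are recorded per model: a cross-validation battery computed on
   the pooled out-of-fold predictions of a stratified k-fold CV on the
   training part, and a test battery on the held-out part.

With the default repetitions (5, 5, 5) each cell contains
5 x 5 x 5 = 125 models; with `NS = "total"` the collapsed sample loop
leaves 5 x 5 = 25.  All stage seeds are spawned deterministically
(counter-based `SeedSequence`) from one master seed, so a run is exactly
reproducible.  Failed cells (degenerate splits, adapter errors) are
recorded with their reason and the grid continues.

The CV battery is computed on pooled out-of-fold predictions rather than by
averaging per-fold batteries: early-recognition metrics are unstable on
tiny folds, and pooling gives one well-defined ranked list per model.

## The 25-parameter battery

Confusion-matrix parameters (14): ACC and Cohen's kappa are computed on the
full K x K matrix; TPR, TNR, PPV, NPV, BM (= TPR + TNR - 1), MK
(= PPV + NPV - 1), BACC, F1, Jaccard, MCC, LRp (= TPR / (1 - TNR)) and DOR
(= TP·TN / FP·FN) are computed per class one-vs-rest and macro-averaged
over the classes present in the true labels.  Macro one-vs-rest is used
throughout because it is the only scheme that extends the early-recognition
metrics naturally; MCC is the macro average of the binary per-class MCC for
internal consistency (Gorodkin's multiclass R_K would be the alternative).

Ranking parameters (11): each class c is treated as the "active" set of a
virtual screen ranked by its own score column.  With N samples, n actives,
and descending fractional ranks r_i (mid-ranks on ties; relative ranks
x_i = r_i / N):

- AUC — pairwise concordance probability, ties counting one half
  (computed by the mid-rank Mann–Whitney identity).
- AUAC = (1/n) Σ (1 - x_i) + 1/(2N), the continuous-rank convention; its
  ceiling is 1 - n/(2N), not 1.
- AP — mean over actives of the precision at that active's rank (stable
  descending sort).
- RIE(α) = Σ e^(−α·x_i) / [(n/N)(1 − e^(−α)) / (e^(α/N) − 1)], with
  α = 20 and α = 160.9.
- BEDROC(α) — RIE min–max scaled onto [0, 1] (Truchon–Bailey scaling).  We
  compute the scaling bounds exactly from the best and worst discrete
  placements of the n actives rather than with the sinh/cosh continuum
  approximation, so a perfect ranking scores exactly 1 at any N.
- EF at 1% and 5% — active rate in the top ⌈χN⌉ over the base rate n/N.
- ROC enrichment at 1% and 5% — TPR linearly interpolated at FPR = χ on
  the empirical ROC curve.

Classes with zero actives or zero inactives are skipped from the macro
average and logged.  All-equal scores never raise; fractional ranks give
AUC = 0.5.

**Clipping.** Rate denominators (LRp's 1 − TNR, PPV's TP + FP, ...) are
clipped at ε = 1/(2N) (a Haldane-style half count expressed as a rate)
before division, so all parameters are finite and the downstream Euclidean
normalization is well defined.  DOR's denominator FP·FN is a *product of
counts*, and applying the rate-scale ε there would make the clipped ceiling
scale as N³ — tiny evaluation sets that luck into one zero cell would then
dominate the normalized DOR column and invert the statistic's
size-dependence.  DOR is therefore clipped at 0.25 (half a count in each
factor), the count-scale analogue of the same convention.

## Classifier adapters

Five algorithm families enter the ML factor: gradient-boosted trees
(XGBoost), Gaussian naive Bayes, RBF-kernel SVM with probability scores, a
backpropagation multilayer perceptron, and a probabilistic neural network
(PNN).  The first four delegate to xgboost / scikit-learn at library
defaults — the benchmark deliberately compares algorithms as shipped, with
no tuning or feature selection.  The MLP stands in for resilient-backprop
feed-forward networks and the PNN is a fixed-bandwidth Parzen classifier
standing in for dynamic-decay-adjustment PNNs: the study's conclusions
concern factor effects, not any one toolbox's internals, so functionally
equivalent standard implementations are used and the substitution is
documented here prominently.

The PNN scores a query by the log mean Gaussian kernel density of each
class's training points (log-sum-exp, so scores stay finite in high
dimension); the shared bandwidth defaults to the median pairwise training
distance divided by √K, a scale-free default.  Every adapter's predicted
label is the argmax of its score row by construction.

## Normalization, ANOVA, SRD

Each of the 25 metric columns is divided by its Euclidean norm over the
rows analyzed together (one results table by default; merged tables are
normalized jointly before a combined analysis).  The long observation table
(one row per model-record and parameter) feeds a fixed-effects factorial
ANOVA with main effects PP, ML, NS, SR and a configurable set of two-way
interactions — default PP×NS, NS×SR, ML×NS, the interactions the summary
figures need; the full 25×5×4×4 factorial with all interactions is
impractical and not more informative.  Type-III sums of squares are used so
the unbalanced designs left by failed cells remain interpretable.  Tukey's
HSD locates significant level pairs; interaction-mean tables carry cell
means, SEs, and t-based 95% CIs on the cell's own degrees of freedom.

SRD (sum of ranking differences) compares the four split-ratio columns of
the 25-parameter × 4-ratio mean table against the row-maximum reference (an
ideal model that maximizes every parameter).  Columns and reference are
rank-transformed ascending with fractional ranks on ties — standard in SRD
implementations, and it keeps SRD integer-or-half valued; SRD_j is the sum
of absolute rank differences, reported as percent of the theoretical
maximum (n²/2 for even n, (n²−1)/2 for odd).  Validation is the CRRN
randomization test — the exact n! footrule distribution for n ≤ 10,
Monte-Carlo (default 10⁵ draws) above, with the 5% point marking
"better than random ranking" — and leave-one-fold-out cross-validation in
which each fold's SRD is re-expressed as percent of the reduced-n maximum.
The exact CRRN null assumes an untied reference; tied references fall back
to Monte Carlo.  Fold-level SRD values grouped by split ratio feed a
one-way ANOVA.

## Synthetic data

Real descriptor matrices (10²–10³ molecules × ~2000 Dragon-style
descriptors with a 3- or 6-class activity label) are emulated, not
downloaded.  Classes are Gaussian clouds in a low-dimensional latent space,
means `class_separation` latent SDs apart, linearly embedded into
`n_informative` descriptor columns; remaining columns are noise; a mixing
operator `(1-ρ)I + ρQ` (Q random orthogonal) induces collinearity.
Descriptor-level noise is Student-t with `noise_df = 3` by default:
real descriptor marginals are heavy-tailed and outlier-laden, and this is
the very feature that makes normality-plus-independence assumptions (naive
Bayes) costly on them — with Gaussian noise the synthetic family would be a
rotated Gaussian on which naive Bayes is close to well-specified and
therefore unrealistically strong.  Z-scoring uses the sample SD (n − 1),
recorded in the table metadata; near-constant columns (centered SD < 1e-8)
are dropped and logged.

What the generator does **not** emulate: molecular semantics, descriptor
block structure and the 0.997 intercorrelation curation of real pipelines,
label noise, and activity cliffs.  Passing trend tests on this data shows
the pipeline propagates sample-size and split-ratio effects correctly; it
does not certify effect sizes on any real chemical series.

## Desk-scale problem sizes

The bundled studies run at desk scale, chosen once: K = 3 classes of
90/85/85 rows (balanced to 255), D = 50 descriptors (20 informative),
class separation 3.0 (mid-range held-out accuracy, so learning curves have
room to rise), NS ∈ {60, 120, 240}, SR ∈ {50, 60, 70, 80}, repetitions
(2, 2, 2), 3-fold CV, and reduced fit budgets for the two expensive
adapters (XGBoost 40 trees of depth 4; MLP with one 32-unit hidden layer,
300 iterations).  Trend conclusions are drawn over 5 master seeds and
stated as majorities (≥ 3 of 5), because single-seed summaries at these
sizes share only four distinct subsample draws per cell and are visibly
noisy.  Observation tables pool CV and test rows by default; both
selectors are available.

## Known limitations

- Early-recognition metrics at NS = 60 with an 80% split evaluate on 12
  samples; EF at 1% then reads a top-1 list.  These cells are kept (they
  are part of the design) but dominate the per-cell variance.
- The exact CRRN enumeration is exponential; n > 10 always uses Monte
  Carlo.
- The PNN shares one bandwidth across classes; strongly heteroscedastic
  classes would warrant per-class bandwidths.
- Repetition indices are treated as exchangeable replicates in the ANOVA
  (fixed-effects only); a mixed model over the nested repetition structure
  is out of scope.
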