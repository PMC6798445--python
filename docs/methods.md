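# Methods

## The problem

Droplet-based single-cell RNA sequencing measures each transcript with low
capture efficiency, so a large share of the zeros in a cells × genes count
matrix are *dropouts* — transcripts that were present but missed — rather
than true biological absence. Downstream analyses (clustering, marker
detection, differential expression) degrade when these false zeros are left
in place. `netimpute` replaces the zero entries of genes worth imputing
with model predictions, and leaves every measured (nonzero) value exactly
as it was.

## Imputation model

**Gene selection.** Only genes whose raw-count variance-over-mean ratio
(VMR) exceeds a threshold (default 0.5, population variance) are imputed;
low-dispersion genes carry little structure worth recovering and pass
through untouched. Zero-mean genes have no defined ratio and are never
selected. The variance convention (divide by *n*) is configurable via
`ddof`; it only shifts the boundary cases.

**Divide and conquer.** The imputable genes are shuffled (seeded) and split
into ⌈G/S⌉ balanced subsets of at most S genes (default S = 512, sizes
differing by at most one — a balanced split avoids a degenerate tiny
sub-network when G is not a multiple of S). Each subset is the output layer
of one independent sub-network. For each target gene, the k = 5 non-target
genes with the highest absolute Pearson correlation (computed once on the
log1p matrix, ties broken by column order) are pooled, deduplicated, and
form that sub-network's input layer. Predictors may be any gene outside the
current target subset, including genes that are themselves not imputable.
When a single subset would cover *every* gene of a small matrix, the
partition is forced into two balanced subsets so predictor candidates
exist.

**Architecture.** Each sub-network is dense:
`|predictors| → 256 (ReLU) → dropout(0.2) → |targets| (softplus)`.
The trainable parameter count is `P·H + H + H·T + T`. The hidden dropout
layer is the usual overfitting guard (unrelated to measurement dropout).
The output activation is softplus rather than a hard rectifier: predictions
must be non-negative in log space, but a rectified output has exactly zero
gradient wherever its pre-activation is negative, and under the
value-weighted loss such entries are unrecoverable — training provably
stalls at a dead-output plateau (we observed the loss freezing at the
plateau value on a noiseless linear task). Softplus keeps the non-negative
range with a strictly positive gradient everywhere. Two control variants
are available: `linear` (identity activations, outputs clipped at zero at
imputation time) and `none_hidden` (a single affine map).

**Loss.** Training minimises, per cell,

    loss_c = Σ_i  Y_i · (Y_i − Ŷ_i)²

on log1p counts, averaged over the cells of a mini-batch. The weight Y_i
makes confidently measured (high) values dominate and gives zeros no
penalty at all — the model is never pushed toward reproducing the very
zeros it is meant to replace.

**Optimisation.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — the optimiser's
standard constants), learning rate 1e-4, batch size 64, at most 500
epochs. Cells are split 95%/5% (seeded, unstratified) into training and
monitoring sets; training stops early when the held-out loss has not
strictly improved for 5 consecutive epochs, and the best-epoch weights are
restored. The 5-epoch patience is the default; it is configurable because
a 10-epoch convention is also in circulation for this architecture.
Held-out cells are still imputed — the split exists only to monitor
overfitting. An optional `train_cell_fraction` trains on a random cell
subset while predicting for all cells. One master seed derives per-concern
and per-subnetwork seeds through `SeedSequence.spawn`, so adding subsets
never reshuffles earlier ones, and a fixed seed reproduces the training
log exactly in single-threaded execution. Networks run in float32; losses
are reported in float64.

**Imputation contract.** Predictions are made in log space, inverse
transformed (`expm1`), clipped at zero, and written *only* into entries
that are zero in the input and belong to imputable genes. Every other
entry is bit-identical to the input. Re-imputation is not idempotent (a
filled zero is no longer zero); only the preservation contract is claimed.

## Masking benchmark

To score an imputer on real data where the truth is unknown, the benchmark
hides known values in a dropout-like way. Per gene, the proportion of
zeros is paired with the log1p mean of its positive values; a logistic
p(x) = 1/(1 + exp(−shape·(x − mid))) is fitted to these points by
nonlinear least squares (initialised at mid = median x, shape = −1,
tolerances 1e-8). Then for each gene up to `n_per_gene` (default 10)
nonzero entries are drawn without replacement with probabilities
proportional to the fitted dropout probability of each entry's own log1p
value — low values, the plausible dropout victims, are hidden
preferentially — recorded, and set to zero. Only nonzero entries are
maskable (masking a zero is unobservable), and sampling is without
replacement because masking the same entry twice is meaningless. The
per-entry argument (rather than the gene mean) is used because a
gene-level constant would make every cell equally likely, defeating the
point of a dropout model.

Recovery is scored on log1p values restricted to the masked coordinates:
overall MSE, overall Pearson correlation, and MSE grouped per gene and per
cell. Two reference points calibrate the numbers: the zero baseline
(leave the masked matrix as is) and the gene-mean baseline (fill zeros
with the gene's positive-value mean). A useful imputer must beat both.

## Downstream metrics

Clustering agreement uses the standard chance-adjusted pair-counting and
information-theoretic indices (adjusted Rand, adjusted mutual information
with arithmetic normalisation, Fowlkes–Mallows) plus the silhouette
coefficient on any externally supplied embedding; the embedding itself
(UMAP or otherwise) is an input, not something this package computes.

Differential-expression recovery: per group, every gene is tested in-group
vs rest with Welch's t-test on log1p values (the unequal-variance form is
the safer default when group sizes differ); p-values are
Benjamini–Hochberg adjusted within the group; the top 500
smallest-adjusted-p genes per group are *extracted* and pooled into the
method's called set, each pooled gene keeping its maximum calling
probability 1 − p_adj across the groups that extracted it. The ROC is
computed over **all** genes: a gene outside the pool is simply not called
(probability 0), and the truth is whether the gene's DE factor differs
from 1 in at least one group. Scoring only the pooled genes instead
would be degenerate here: a one-vs-rest test also detects genes that are
DE only in *other* groups (their effect shifts the "rest" mean), so the
top lists consist almost entirely of genes that are DE somewhere and the
restricted ROC has no negatives. Over all genes, the score rewards
pulling weakly expressed true DE genes into the called set — the thing
imputation is supposed to enable — and we verified the behaviour is
right-way-round: restoring the exact pre-dropout counts (an oracle no
method can beat) raises this AUC substantially, and the trained model
lands just below the oracle. Degenerate t-tests (zero variance on both
sides) are assigned p = 1.

FISH-style comparison: cells are normalised by a housekeeping-gene factor
mean(hk)/hk(cell) after trimming cells strictly below the 10th or above
the 90th percentile of the housekeeping gene (linear-interpolation
percentiles); per-gene inequality is summarised by the Gini coefficient
Σ|xᵢ−xⱼ|/(2n²μ); method values are rescaled per gene by an efficiency
factor mean(reference)/mean(method) before a two-sample K-S statistic is
computed. Where reference and method vectors are paired, per-gene MSE and
correlation are reported as the conventional mean squared error and
Pearson correlation; a `strict_formula` switch instead evaluates the
summed squared error and a covariance/(variance·variance) ratio for
comparability with conventions that normalise by variances rather than
standard deviations.

## Synthetic data generator

The simulator provides the controlled conditions every other module is
tested under: gamma-distributed gene base means, per-group log-normal DE
factors (a `de_prob` fraction of genes per group, inverted to
downregulation with probability ½), log-normal library sizes, expected
counts formed by normalising each group's mean profile to proportions and
scaling by library size, Poisson counts, and entry-wise logistic dropout
with argument log1p(expected count). Ground truth (group labels, DE
factors, expected rates, pre-dropout counts, dropout mask) is recorded in
full. The default design is 4000 genes × 2000 cells in five groups with
proportions 10/10/20/20/40% and dropout mid = 1, shape = −0.5.

Defaults for the remaining parameters are: `de_prob = 0.1`,
DE factors `exp(N(0.1, 0.4))`, gene means `Gamma(shape 8, rate 0.5)`,
library sizes `exp(N(10.3, 0.2))` (≈ 30k counts per cell). The last two
were calibrated once, jointly, so that the dropout curve is recoverable
from the simulated data itself: the benchmark's logistic fit reads the
per-gene zero proportion, and when expected counts are small, Poisson
sampling zeros (absent from the dropout model) inflate those proportions
and bias the fitted (mid, shape) severely. With the chosen defaults the
fit recovers mid within ~5% and shape within ~2%, at an overall zero
fraction of ~37%. This is a deliberate trade-off: a sparser regime
(50–70% zeros, common in shallow droplet data) is easily produced by
lowering `libsize_location` or the gamma shape, but in that regime the
zero fraction no longer identifies the dropout curve and the recovery
loop does not close. The dropout logistic uses the same log1p convention
as the masking benchmark precisely so the two are mutually recoverable.

What the simulator does *not* emulate: biological over-dispersion trends
(it is Poisson, not gamma-Poisson with a BCV curve), batch effects,
trajectories/paths, ambient RNA, doublets. Passing tests on this
generator therefore demonstrate correctness of the algorithms under
clean group structure, not performance on any particular real dataset.

## Problem sizes used in the shipped experiments

The full simulated experiment (4000 × 2000, five groups, default
training) is the package's headline run; the test suite exercises the
same code paths on smaller designs (60–1500 genes, 80–1000 cells) chosen
so that per-gene expected counts match the full-size regime — the library
size must scale with gene count, otherwise a small gene panel at a full
library produces counts far outside the intended range. The
learnability fixtures strengthen group structure (`de_prob` 0.4–0.5, DE
factor location 1.0) so that default training converges quickly; with the
default subtle effect sizes, more epochs or more cells are needed for the
model's advantage over the gene-mean baseline to appear.

## Known limitations

- The imputer requires the transform-time gene set to equal the fit-time
  gene set (same order); no automatic re-alignment.
- Sub-networks are trained sequentially; they are independent by
  construction (results do not depend on execution order) but no
  multi-process scheduler is shipped.
- The logistic dropout fit assumes genes span a range of expression
  levels; matrices where all genes are either always-zero or never-zero
  cannot constrain the curve and are rejected.
- ROC AUC for DE recovery is computed over the pooled top-n genes only,
  so its value depends on n and is not comparable across different n.
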