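# Methods

## Model

A subject is a graph over a fixed node vocabulary: 19 ordinal nodes (nine
depression items, seven anxiety items, three quartile-coded scale totals) and
up to four binary nodes (lifetime suicide attempt, major depressive episode
(MaDE), gender, institution type). All subjects share one adjacency — the
matrix of pairwise correlations between node codes on the training split with
entries |ρ| < threshold zeroed — and differ only in their node features, a
6-slot one-hot per node (slots 1–4 for ordinal levels, slots 5–6 for binary
states). Six slots, rather than a scalar code, are used so that level-resolved
input gradients exist for the attention plots.

The classifier is a graph isomorphism network. Layer k computes
`h_v = MLP_k((1+ε_k) h_v + Σ_u A_vu h_u)` with a learnable per-layer ε
initialized at 0; the aggregation uses the signed correlation weights and is
evaluated as a sparse matrix product, so a layer costs O(edges · batch ·
width). Node features of every hidden layer are sum-pooled into per-layer
graph features, concatenated, and mapped to a scalar score by a linear
classifier with a sigmoid. Training minimizes binary cross-entropy with Adam.

Two-stage workflow: a MaDE GIN is trained on the small labeled subset
(vocabulary: questionnaires + gender + institution only) and pseudo-labels
every unlabeled subject (true labels are never overwritten; binarization at
probability ≥ 0.5). The acute-SI stage then trains three members on
differently resampled training data — under-sampling to negative:positive
ratios 10 and 5, SMOTE-NC over-sampling to ratio 1 — and averages their
sigmoid scores (soft voting). Member checkpoints minimize validation loss
among epochs whose validation sensitivity and specificity both exceed 0.80 at
threshold 0.5; if no epoch qualifies, the minimal-loss checkpoint is kept with
a prominent warning (the qualifying-epoch rule is otherwise undefined in that
case).

## Key parameters

| parameter | default | notes |
|---|---|---|
| edge correlation / threshold | Spearman, 0.6 | Pearson available; signed weights kept (a config choice — magnitude-only aggregation is not used) |
| GIN depth / width | 5 layers / 64 units (16 in the shipped experiment profiles) | MLP = two affine maps with ReLU |
| ε mode | learnable, init 0 | fixed-zero available |
| optimizer | Adam, lr 1e-3, batch 256 (128 in experiment profiles) | all seeded |
| batch normalization | off | implemented (train-time batch stats, eval-time running stats) but disabled by default so scores are independent of batch partitioning; enable via `GinConfig(batch_norm=True)` |
| dropout | 0 | |
| balance ratios | u1: 10, u2: 5, SMOTE-NC: 1 | ratio = negatives per positive after resampling |
| SMOTE-NC k | 5 | Euclidean distance on ordinal codes plus the median-of-stds penalty per differing nominal attribute; ordinal interpolants round back to the level grid; nominal values by neighbor majority vote, the seed row breaking ties |
| validation split | stratified 80/20 | the external test split is never resampled and never used for edge fitting, quartile fitting, checkpointing or pseudo-label training |
| quartile coder | 25/50/75 percentiles, linear interpolation, fitted on the training split | ties map to the lower level; the resilience total is reverse-coded |
| pseudo-label threshold | 0.5 | |
| checkpoint floors | sens, spec > 0.80 at threshold 0.5 | |

Decision thresholds for sensitivity/specificity are 0.5 throughout (a Youden
option would be a natural extension; it is deliberately not implemented to
keep the operating point fixed and comparable).

## Synthetic cohort generator

Four latent traits (depression, anxiety, resilience, self-esteem) are drawn
from a multivariate normal with correlations (dep–anx 0.6, resilience and
self-esteem −0.4/−0.5 with the distress traits, +0.5 with each other). Item j
is `λ_j · trait + N(0,1)` cut into four levels at its own marginal quartiles;
λ defaults to 1.5 (communality ≈ 0.69), so same-scale items correlate at
ρ ≈ 0.65 — above the 0.6 edge threshold — while cross-scale correlations fall
below it, giving the two-cluster within-scale edge structure expected of
these instruments. Scale totals are integer scores driven by their owning
trait. Binary outcomes follow logistic models whose intercepts are calibrated
by bisection (tolerance 1e-6 on the mean probability) to exact target
prevalences: acute SI 1%, lifetime suicide attempt 1.4%, MaDE 5% with a
~1.1% labeled fraction. Planted effects (magnitudes typical of the
psychiatric risk literature): SI depends on depression (1.2), anxiety
(0.4), resilience/self-esteem (−0.3), lifetime SA (2.6, an odds ratio of
order 10), MaDE (1.3), female gender (1.3), hospital setting (0.7), and a
dominant item-specific anhedonia effect (PHQ_2 latent, 1.6) so the
top-saliency item is known by construction.

The anhedonia coefficient deserves a note on how it was fixed. Because all
depression items load equally on the shared trait, an item's *marginal*
association advantage saturates as the direct effect grows (ΔAUC ≈ 0.013
regardless of coefficient) and is far below test-split sampling noise; only
the *conditional* (partial) effect distinguishes the planted item, and its
recoverability from ~140 positive training cases is the binding constraint.
An estimator-independent oracle — conditional logistic regression on the
one-hot items at the study's training-split size, repeated over Monte-Carlo
cohorts — recovers the planted item's rank-1 saliency in only 5/10 cohorts
at a coefficient of 0.8, 9/10 at 1.2, and 10/10 (median margin +33%) at
1.6. The default is therefore 1.6, the smallest tested value the oracle
certifies unanimously; with a weaker planted effect, rank-1 recovery at this
sample size is impossible for any method, not merely for this one.

A continuous ideation criterion score (KSSI) is
generated from the SI liability for ~6% of subjects. The generator also
supports a deterministic MaDE rule (depression above a quantile) for
pseudo-label accuracy experiments.

What the generator does **not** emulate: multi-center distribution shift
between training and test populations (the external "test center" here is an
i.i.d. random split), item-level missingness, response styles
(acquiescence, careless responding), floor effects of symptom items in
healthy populations, and non-Gaussian trait dependence. Passing recovery
tests therefore show that the pipeline recovers structure *of this kind* at
these sample sizes; they do not certify performance on real, shifted,
messier cohorts.

## Numerical choices

* The GIN, including backpropagation to parameters and inputs, is implemented
  directly on numpy arrays; gradient correctness is pinned by central
  finite-difference tests (relative tolerance 1e-4) with and without batch
  normalization.
* Quartile/ordinal ties map to the lowest eligible level
  (`searchsorted(..., side="left")`); values outside the reference range
  clamp to levels 1/4.
* AUC counts score ties as 1/2; confusion metrics use the ≥-threshold rule; a
  class absent from the labels yields NaN rates, never silent zeros.
* DeLong confidence intervals use the normal approximation clipped to [0,1];
  identical score vectors in the paired test return difference 0 with p = 1.
* The dependent-correlation comparison uses Steiger's z on Fisher-transformed
  Spearman correlations; at n ≈ 40 it agrees with a subject-resampling
  bootstrap only to within ~0.1 in p (the tests assert exactly that band
  rather than hiding the approximation error).
* Constant node columns get zero correlations with a warning; all-zero
  attention rows/columns are left as zeros with a warning.
* One master seed fans out to every stage through `numpy.random.SeedSequence`;
  two runs with the same seed agree bit-for-bit.

## Experiment profiles and problem sizes

The default study profile runs 20,000 subjects (30% external test split) with
a 16-unit, 5-layer GIN; member Adam schedules are sized per member (60 epochs
for the small under-sampled sets, 12 for the large SMOTE-balanced set, batch
128). The multi-seed recovery suite uses a reduced profile (30/30/8 epochs,
attention averaged over a 2,000-subject subsample) — saliency means are
stable well below that subsample size. The SVM baseline is fitted on a
6,000-subject stratified subsample of the training partition (kernel SVMs
scale quadratically); prevalence is unchanged, so its characteristic
sensitivity collapse under extreme imbalance is unaffected. The
LASSO-logistic baseline selects its penalty by 3-fold stratified
cross-validation over 8 log-spaced values. Both baselines consume the same
flattened one-hot features the GIN sees.

## Design choices on genuinely open points

* **Correlation flavor** — Spearman on integer codes by default (robust for
  ordinal data); Pearson by config.
* **Signed vs absolute edges** — signed weights are aggregated as stored;
  a sign-blind variant would change what "negative coupling" contributes and
  is intentionally not the default.
* **One shared pseudo-label set** — all three SI members consume the same
  pseudo-labels rather than re-deriving them per member.
* **Edge matrix and resampling** — the edge matrix is fitted on the original
  (un-resampled) training split so synthetic minority rows cannot distort the
  population correlation structure; resampling happens on the tabular
  representation before graph encoding.
* **Ensemble attention** — the mean of member input gradients, taken with
  respect to the raw (pre-sigmoid) output, averaged over all subjects of the
  chosen split (not only correctly classified ones).
* **Quartile pooling** — totals are quartile-coded against pooled
  training-split cut points (not per-center), and applied unchanged to
  validation/test data.

## Known limitations

Sum-pooling with a shared adjacency means the model cannot express
subject-specific connectivity; the pseudo-label stage inherits any bias of
the small labeled subset; checkpoint selection at threshold 0.5 can leave the
ratio-10 member below its sensitivity floor on imbalanced validation folds
(the fallback warning fires routinely in that regime); and all reported
numbers are synthetic-cohort results — they demonstrate mechanism recovery,
not clinical performance.

One negative finding deserves emphasis. **Gradient attention does not
resolve item-level dominance among near-exchangeable items at this sample
size.** In the synthetic cohort all depression items load equally on one
trait, and the planted anhedonia item differs from its siblings only through
its conditional (partial) effect. The trained GIN's L1-column saliencies for
the nine depression items then agree to within ~1%, and which item ranks
first varies with the cohort draw (all three ensemble members agree within a
cohort, so the lottery is at the cohort level, not the initialization
level). The rank-1 recovery experiment (10 seeded runs) accordingly fails —
PHQ_2 tops the ranking in only a minority of runs — even though a
conditional logistic regression fitted to the *same resampled rows*
recovers PHQ_2's dominance with a 10–33% margin. Two targeted probes locate
the cause in representation learning, not in the attention arithmetic:
removing all graph edges (eliminating any aggregation smearing) leaves the
attention equally undiscriminating, and permutation importance shows the
trained network's predictions do not preferentially exploit the planted
item's unique component (AUC drop 0.011 when permuting PHQ_2 versus up to
0.018 for sibling items). Wider models (32 units), batch normalization and
schedules up to 200 epochs do not change this. In short: with ~160 positive
training cases, the GIN learns the shared depression factor but does not
break the exchangeability symmetry, so its saliency ranking within a
homogeneous item cluster is not trustworthy at this scale — a caveat that
applies equally to interpreting such attention plots on real cohorts where
true item effects are close.
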