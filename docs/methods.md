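# Methods

This note records the modeling and numerical choices behind `graphomics`:
what the pipeline computes, which decisions were genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Synthetic data generator

The generator (`graphomics.synthetic`) emulates the statistical structure
the graph classifiers are designed to exploit, not any real cohort's
marginals.

**Directional class signal.** Each view assigns every class a non-negative
prototype direction. Features are partitioned into `n_classes + 1` disjoint
blocks — one shared baseline block plus one block per class — and each
prototype is `w·baseline + (1−w)·class_block` with `w = 1/(1 +
signal_strength)`. Because the blocks are mutually orthogonal and
non-negative by construction, between-class cosine similarity is an exact,
monotonically decreasing function of `signal_strength`: 1 at strength 0,
approaching 0 (orthogonal prototypes) as strength grows. This makes the
separation dial continuous and testable. A sample of class c is

    x_i = s_i · max(p_c + ε_i, 0),   ε_i ~ N(0, noise_sd²),
    s_i = exp(N(0, scale_jitter_sd²))

where `s_i` is a per-sample multiplicative factor shared across that
sample's features (drawn independently per view, as platform-specific batch
effects would be). Cosine similarity is invariant to `s_i`; Euclidean
distance — and hence the RBF kernel — is not. `magnitude` mode instead
shares one direction across classes and separates them by scalar offsets
`1 + c·signal_strength`; `mixed` applies both.

**Defaults.** 150 samples, 2 classes, three views of 100/100/50 features,
`signal_strength 4`, `scale_jitter_sd 0.5`, `noise_sd 0.1`, no missing
entries. These are the benchmark's standard conditions: a strongly
directional signal (between-prototype cosine ≈ 0.06) under substantial
magnitude nuisance (scale factors spanning roughly 0.4–2.5).

**Labels** are allocated by largest remainder from `class_proportions`
(exact counts, ties to the lower class index) and shuffled with the seed;
every class must receive at least two samples so stratified splitting is
well-posed. Missing entries are injected uniformly at an exact
`round(rate·n_entries)` count, never emptying a row or column. Generation
is fully determined by the seed.

**What it does not emulate:** methylation beta distributions, count
overdispersion, feature–feature correlation structure, view-specific
dimensionality of real panels. Passing the benchmark shows the pipeline
recovers angular class structure under magnitude nuisance; it does not
certify performance on real cohorts.

## Preprocessing

Per-modality chain: `log2(1+x)` → coarse variability filter → KNN
imputation (k = 5) → quantile normalization → final fixed-size selection.
Quantile normalization is rank-based and therefore ill-defined on matrices
with missing entries, so imputation precedes it even though normalization
is conventionally listed first; with complete input the order is
immaterial.

- **Log base** 2 with pseudocount 1 (the genomics convention; any base
  difference is absorbed by quantile normalization downstream).
- **Quantile normalization** maps every sample's values onto the mean
  order-statistic distribution across samples; within-sample ties receive
  the mean of the reference values they span, making the result independent
  of tie ordering and idempotent on tie-free data.
- **Variability ranking** uses the sample SD (ddof 1); ties break toward
  the earlier feature index, and surviving features keep their original
  order.
- **KNN imputation** fills entry (i, f) with the mean of feature f over the
  k samples nearest to i by Euclidean distance restricted to mutually
  observed coordinates; donors lacking feature f fall back to the
  next-nearest sample. The distance is deliberately *unscaled* (no
  missingness-proportion correction), matching the literal nearest-neighbor
  rule the tests' brute-force oracle implements.
- Final feature counts are configuration values (defaults 1000/1000/200 for
  mRNA/methylation/miRNA-like views, clipped to the available width); each
  stage can be toggled per modality.

## Graph construction

All six metrics produce edge *affinities* in [0, 1]: distance metrics are
converted by `w = 1 − d` (hybrid-distance affinities are clamped below at 0
for signed data). Each node keeps its k best neighbors (largest affinity,
self excluded, ties to the lower sample index; default k = 10), the kept
edges are symmetrized by elementwise maximum — a union rule that, unlike
mutual-kNN, cannot isolate nodes — the diagonal is zeroed, and the
normalized operator `D̃^{−1/2}(A+I)D̃^{−1/2}` is formed. Graphs are weighted
(not binarized) after sparsification.

A consequence of the `w = 1 − d` conversion worth stating plainly: each
distance metric yields exactly the same graph as its similarity counterpart
(`1 − (1 − cos) = cos`, and likewise for RBF and the hybrids with
β = α). The six constructions therefore collapse into three distinct
graph families here. Alternative conventions — weighting edges by the
distance itself, or binarizing — would break the tie but produce
non-monotone or uninformative edge weights; the affinity convention keeps
every edge weight a similarity, which is what the normalized graph
convolution assumes. Empirical differences reported elsewhere between
similarity- and distance-built graphs must hinge on such a convention
choice.

The RBF bandwidth defaults to the median heuristic
`γ = 1/(2·median‖xᵢ−xⱼ‖²)` over all unordered sample pairs, zero-distance
pairs included; data whose median pair distance is zero raise an error. For
explicit tuning, the grid search evaluates γ ∈ {10⁻⁴, …, 10} and hybrid
weights {0.1, 0.3, …, 0.9} by internal validation accuracy on the training
split only, with ties resolved toward the smaller γ, then the smaller
weight.

## Models and training

Per view: a two-layer GCN (64-unit ReLU hidden layer, direct c-logit
output, softmax). No biases, dropout or normalization layers are used — the
minimal reading of the propagation rule. Hidden nonlinearities are ReLU
throughout. The fusion head flattens the per-sample outer product of the m
view probability vectors (row-major, view 1 slowest-varying — the order is
fixed so archives and tests are portable) and applies a 128/64-unit ReLU
MLP with a c-dimensional softmax output projection (required whenever
c ≠ 64).

The networks are implemented directly in numpy with a hand-written backward
pass and an Adam optimizer (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, coupled L2
weight decay 5·10⁻⁴ added to the gradient). The models are small enough —
a few hundred nodes, ≤ 128-unit layers — that full-batch numpy training is
fast, dependency-free and bit-reproducible from one seed. Initialization is
Glorot-uniform. The joint loss is the unweighted sum of every view head's
cross-entropy plus the fusion head's, at training nodes only; the `no_vcdn`
ablation omits the (parameter-free) average-fusion term from the loss and
uses the average only for prediction.

Training is transductive: graphs span all samples and unlabeled nodes
(y = −1, the scikit-learn semi-supervised convention) contribute structure
but no loss. A stratified 10% of the labeled nodes is carved out for early
stopping (the 70/30 split protocol defines no validation set, so one must
be invented; carving it from the training side avoids touching test
labels). Training stops when validation loss has not improved for 20
consecutive epochs (strict improvement, evaluated after each update) or at
2500 epochs; the best-validation parameters are restored.

## Benchmark and statistics

The benchmark runs each metric × model variant over five stratified 70/30
splits (seeds 0–4 by default; per-class allocation by rounding, so class
ratios match the global ratio within one sample, with splits re-drawn — and
models re-initialized — per seed). Results are reported per split and as
mean ± SD, with tidy CSV output; identical configurations reproduce
byte-identical CSVs in single-threaded use.

Comparisons against the cosine-similarity baseline use paired two-tailed
t-tests (pairing by split seed), 95% confidence intervals
`mean ± t₀.₉₇₅,ₙ₋₁·sd/√n`, and Cohen's d in the pooled-SD
independent-groups form (n₁+n₂−2 denominator). Degenerate conventions,
chosen and documented rather than left to library defaults: all-zero
paired differences give p = 1; zero-variance nonzero differences give the
p → 0 limit; zero pooled SD gives d = 0 when means agree and signed
infinity otherwise. Multiclass sensitivity/specificity/precision are
one-vs-rest macro averages; classes absent from the evaluated subset are
excluded from macro averages with a warning, a never-predicted class
contributes precision 0, and a class spanning the entire subset has
undefined specificity and is skipped. AUC is one-vs-rest macro-averaged
from the probability columns; constant scores score 0.5.

## Problem sizes and ceiling effects

The shipped benchmark regime (150 samples, three views, binary labels,
strength-4 directional signal, 0.5 scale jitter, 0.1 noise) was chosen as a
clean instantiation of the design assumptions, and the full pipeline
recovers it essentially perfectly: all graph families reach test AUC ≈ 1.0.
Two consequences are worth keeping in mind. First, the cosine ≥ RBF and
full ≥ average-fusion orderings hold at this regime partly *by tie* — the
task is easy enough that graph quality is not the bottleneck. Second, the
paired comparison statistics are then degenerate by construction (p = 1,
d = 0): identical per-split scores carry no evidence either way. The
statistical machinery itself is verified against hand-worked examples
independently of the benchmark. Harder regimes (lower signal strength,
higher noise, more classes) are a one-line change to `SyntheticSpec` for
users who want the metrics to separate.

## Known limitations

- Transductive only: `predict` applies to the samples seen at `fit`; an
  inductive extension (graph extension for new samples) is not implemented.
- The `w = 1 − d` affinity convention collapses distance metrics onto their
  similarity counterparts (see above); the six-way comparison is genuinely
  a three-way comparison under this convention.
- Preprocessing is fit on the full matrix (transductively), consistent with
  the graph construction; a strictly inductive train-only fit would be
  needed for deployment-style evaluation.
- The generator's nuisance model (log-normal per-sample scale) is the
  mechanism cosine similarity is invariant to; benchmarks built on it
  cannot, by design, favor magnitude-sensitive metrics.
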