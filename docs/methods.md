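# Methods

## Model

The classifier treats disease gene prioritization as semi-supervised
binary node classification on the PPI graph: a few genes carry labels
(disease-associated or background), the rest are unlabeled, and the
graph plus the GO annotations supply the structure that lets label
information generalise.

**Features.**  Per namespace (MF/CC/BP) the term catalog is the sorted
union of all directly annotated terms; gene *i*'s vector is the 0/1
membership indicator over that catalog.  The three matrices share one
width *m* — the largest catalog — by zero-padding shorter catalogs on
the right, which preserves the indicator semantics (a padding column
is a term no gene has).  Direct annotations only: no DAG ancestor
propagation and no evidence-code filtering, so the vectors reflect the
annotation source as-is.  Genes missing from the annotation file get
all-zero rows rather than being dropped, because the PPI graph
legitimately contains unannotated genes.

**Propagation.**  The convolution uses the raw self-loop-augmented
adjacency `Ã = A + I` (no degree normalization by default; a
`normalize_adjacency` switch exists).  Since the inputs are binary,
propagation replaces sums with ORs: `C = sign(Ã·X)` computed with
sparse integer products and thresholding — dense N×N storage is never
materialised.  OR output is itself binary, so
`or_propagation_depth` rounds of OR reach the depth-k neighbourhood
while remaining well-defined; the default is one round.  Deeper layers
operate on real-valued activations where OR has no meaning, so they
are the plain feed-forward stack `h^k(x) = ReLU(W^k h^{k-1} + b^k)`.

**Heads and losses.**  The embedding is taken after `l1` of the
`l = l1 + l2` layers.  Class probabilities are a softmax over
`[e, h^l(x)]·w_y`; concatenating the embedding with the final hidden
layer lets the label head see both the context-shaped representation
and the deepest features.  The supervised loss is mean cross-entropy
over labeled genes.  The unsupervised loss is the logistic loss of
classifying context pairs, `−E log σ(γ·w_c^T e_i)`, with one context
weight vector per graph node.  Context pairs mix two sources (each
50% by default): random-walk co-occurrence (walk length q = 10,
window d = 3) injects graph structure, and shared-label pairs inject
label information; half of all draws are negatives (γ = −1), sampled
uniformly (graph) or across classes (label).

**Training.**  Plain SGD (learning rate 0.01, no momentum), at most
200 epochs, each epoch one gradient step on `L_s` over N1 = 64 labeled
samples followed by one step on `λ·L_u` over N2 = 64 context triples
(λ = 1 by default).  Weights are Glorot-uniform, biases zero.  Early
stopping monitors the supervised loss on a held-out 20% stratified
split of the labeled genes and stops after 10 epochs without
improvement, returning the best-epoch parameters.  Gradients are
hand-derived NumPy float64 and clipped at global norm 5 as a
divergence guard; the test suite checks them against central finite
differences (relative error < 1e-4, observed ~1e-9).  All sampling
flows from a single `numpy` generator seeded by `ModelConfig.seed`, so
training is bit-reproducible.

**Labels.**  The data provide positives only (the seed set).  The
binary classifier therefore samples seeded background negatives —
3 per positive, drawn from genes outside the seed set and outside the
held-out target — a standard device in prioritization methods that
lack curated negatives.  The held-out target itself is never labeled
in either class.

## Prioritization protocol

One model triple (MF/CC/BP) is trained per disease per left-out gene;
the same PPI topology carries the three feature matrices.  The
artificial linkage interval of a target is the target plus the 99
nearest eligible genes by genomic midpoint distance on its own
chromosome, falling back to other chromosomes only when that
chromosome runs out; other seed genes are never eligible.  Candidate
scores are the positive-class probabilities averaged over the three
namespaces (score averaging rather than rank averaging, because the
three outputs are commensurable probabilities; `aggregate="rank_mean"`
is available).  Ties break lexicographically by gene ID, which makes
ranking deterministic.  A `fast_loocv` mode trains once per disease on
the full seed set and reuses the models for every interval; it leaks
the target's label into training and is an approximation, off by
default.

## Evaluation

**Threshold-rank AUC.**  For cutoffs t = 0..T, sensitivity(t) is the
percentage of lists whose target ranks within the top t, and FPR(t)
the mean fraction of the 99 decoys in the top t.  The truncated curve
is closed by the chord to (1, 1) and integrated by trapezoid.  This
closure is what keeps the published calibration anchors at every
threshold — perfect = 100 exactly, uniform-random ≈ 50, all-targets-
last = 0 on the full sweep; a span-normalized truncation instead sends
a random ranker to ~T/2 percent, which contradicts the anchors.  The
construction lives behind the single function
`eval_stats.threshold_auc` so alternatives can be swapped.

**Precision/recall/F1** pool the lists at a cutoff: each list
contributes its target as the one positive and the decoys as
negatives.  Recall is TP/(TP+FN), the standard definition.  Undefined
metrics (zero denominators) raise rather than silently reporting 0.

**Friedman statistics.**  Within-disease ranks (1 = best, average
ranks on ties), per-method mean ranks, and the chi-square statistic
`12/(nk(k+1))·ΣR_j² − 3n(k+1)` with the tie correction
`1 − Σ(t³−t)/(nk(k²−1))`; p-values use the chi-square approximation
(what standard statistics packages report), not the exact permutation
distribution.  The shipped 16-disease AUC tables
(`src/gcngp/data/auc_table_*.csv`) reproduce the published mean ranks
and chi-square values exactly at printed precision.

## Synthetic data

The generator emulates the two information channels of real data and
nothing else.  A planted-partition graph gives the network channel:
background edges at `p_out = 0.01`, intra-module edges at
`p_in = 0.3` among `n_disease = 20` of `n_genes = 300` genes.
Per-namespace annotations give the feature channel: 60 terms of which
8 are enriched, carried by disease genes with probability 0.6 versus
0.05 background.  The term counts and probabilities are chosen so a
disease gene shares a few enriched terms with its module — comparable
to the enrichment a curated disease gene set shows — while background
genes carry a realistic scatter of annotations; the channel strengths
are deliberately modest so the task is non-trivial.  Genes sit at
regular 10 kb offsets on 5 chromosomes, so linkage intervals are
well-defined and dense.  Each channel can be ablated independently
(`p_in = p_out` kills the network signal; equal term probabilities
kill the feature signal), which is how the chance-level control is
produced.

What the generator does *not* emulate: scale-free degree
distributions, annotation-count heterogeneity across genes, multiple
overlapping diseases, or realistic gene spacing.  Passing tests on
these fixtures therefore demonstrate that the machinery recovers a
clustered, co-annotated module under controlled conditions — not
field performance on curated interactomes.

A single global seed fans out to per-component substreams
(`SeedSequence.spawn`), so adding a generator leaves existing outputs
byte-identical.

## Problem sizes and numerical choices

The default study runs leave-one-out over the 20 planted disease genes
(3 namespace models per left-out gene, 60 trainings) in well under a
minute on one core; the evaluation suite and the reproduction script
are sized accordingly.  Probabilities are computed with max-shifted
softmax and `logaddexp`-based logistic losses for stability; log
arguments are clipped at 1e-300.  Degenerate inputs fail loudly:
empty graphs, empty label sets, non-binary inputs to the OR operator,
intervals with fewer than 99 eligible genes, and non-finite losses all
raise with diagnostics.

## Known limitations

Training a width-16 network with plain SGD is initialization-
sensitive: across training seeds the planted-module LOOCV threshold-10
AUC varies in roughly the 75–96 band (the degree-only baseline on the
same fixture sits near 90, because planting a dense module makes
degree itself informative).  The per-gene retraining protocol is
faithful but quadratic in the seed-set size; `fast_loocv` trades
correctness for speed.  Real GAF inputs are consumed column-wise
without qualifier handling (`NOT` annotations are not excluded), and
coordinates are taken as given rather than fetched from an assembly.
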