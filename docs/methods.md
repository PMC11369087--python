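# Methods

## Sequence representations

A representation is a total mapping from the 20 standard amino acids to an
ordered symbol set, applied position-wise (length is always preserved).
Three are built in:

* `no_reduction` — identity, k = 20, symbols in alphabetical order.
* `hydro` — k = 5 hydropathy groups.  Each residue's Kyte–Doolittle
  hydropathy score is normalized to [0, 1] via (KD + 4.5)/9 and binned into
  five equal-width bins; `H_1` is the most hydrophilic bin, `H_5` the most
  hydrophobic.  Resulting groups:
  `H_1` = {R,K,N,D,Q,E,H}, `H_2` = {P,Y}, `H_3` = {W,S,T,G},
  `H_4` = {A,M,C}, `H_5` = {F,L,V,I}.
* `conform` — k = 7 groups of residues with similar main-chain/side-chain
  conformational (φ/ψ) behaviour, in the style of published
  conformational-similarity reductions: `C_1` = {A,E,K,Q,R} (long
  polar/charged, helix-compatible), `C_2` = {C}, `C_3` = {D,N} (short
  amide/acid side chains with distinctive backbone preferences),
  `C_4` = {F,H,I,L,M,V,W,Y} (bulky hydrophobic/aromatic), `C_5` = {G} and
  `C_6` = {P} (the two conformational outliers), `C_7` = {S,T} (small
  hydroxyl pair).

Published reduction figures rarely pin the exact assignments, and several
variants circulate; both tables therefore ship as plain TSVs
(`src/ampfeat/tables/`) and any user partition can be substituted via
`load_alphabet(path)`, so results remain reproducible against any specific
published grouping.  Group labels `H_i`/`C_i` are also the monogram feature
names, keeping explanation outputs readable.

## Composition and co-occurrence features

For a represented sequence of length n over k symbols:

* monogram vector: per-symbol count divided by n (sums to 1);
* co-occurrence matrix G^δ: counts of ordered pairs (a_t, a_{t+δ}),
  t = 1..n−δ, divided by the pair total n−δ (sums to 1 when any pair
  exists).  δ = 1 is the adjacent-dipeptide matrix.  No pseudo-counts.

Degenerate input: when δ ≥ n there are no pairs; the all-zero matrix is
returned (pair_count 0) rather than an error so that a dataset of mixed
lengths still produces a constant-width feature table.  The flattened
bigram block of such a sequence is all zeros, which is the honest encoding
of "no information at this offset".

## Texture statistics

Five scalars of the normalized matrix (indices 1-based; only differences
i−j matter): energy Σ G², entropy −Σ G log₂(G+ε), homogeneity
Σ G/(1+(i−j)²), contrast Σ (i−j)² G, dissimilarity Σ |i−j| G.
ε defaults to 1e−12 and is configurable: it exists purely to avoid
log(0) and is negligible against the smallest possible nonzero cell
(1/k² ≥ 1/400 at k = 20).  Entropy uses base 2 (bits).  The all-zero
matrix yields all-zero statistics.

## Skip-gram embeddings

The trainer is a self-contained numpy implementation of skip-gram with
negative sampling: one input (embedding) matrix and one output (context)
matrix, SGD over (center, context) pairs within a symmetric window, with
`negative` noise words per pair drawn from the unigram^0.75 distribution
and a linearly decaying learning rate.  It is single-threaded and bit-wise
deterministic for a fixed seed — reproducibility was preferred over the
throughput of multi-worker trainers, which is not needed at peptide-corpus
scale.

Defaults: n-gram size 3 (the ProtVec convention), window 5, epochs 10
(3 inside cross-validation, where the model is retrained per fold),
min_count 1 (so tiny corpora are fully covered), dimension 50 on the
standard alphabet and 300 on reduced alphabets.  Training corpora use the
shifted non-overlapping n-gram convention: each sequence yields one
document per shift offset 0..n−1.  A sequence embedding is the sum of its
*overlapping* n-gram vectors; out-of-vocabulary n-grams contribute zero
(logged), keeping the output length fixed.  Vectors round-trip through the
word2vec text format for interoperability with externally trained models.
The training corpus for the packaged workflow is the input dataset itself;
a larger pretrained vector file can be loaded instead when available.

## Feature assembly

Concatenation order is representation-major, then feature type in the
fixed order counts → mat → tfeat → pro2vec, then offset, then within-block
index (symbols in alphabet order; matrix row-major).  Any fixed order is
equivalent for the classifiers used; fixing one makes extraction a pure
function of (sequence, spec, models) and keeps feature names stable.
Names: monograms are the bare symbol ("K", "H_2"); bigrams "AB(δ)"
("H_2H_2(1)"); texture "<rep>:<stat>(δ)"; embeddings "<rep>:p2v_<i>".
Bare standard letters cannot collide with prefixed group labels, and a
collision guard asserts global uniqueness.

## Synthetic data generator

The generator emulates the *shape* of a curated AMPylation dataset:
31-mer windows, 153 positive / 250 negative by default.  Negatives are
i.i.d. draws from UniProt-like background amino-acid frequencies.
Positives can differ in three independently switchable ways: the centre
residue is drawn from {T, Y} (the primarily modified residues; the centre
of a negative window is left at background), the overall composition is
tilted by per-residue log-odds (`composition_shift`), and a literal motif
can be planted downstream of the centre.  What it does **not** emulate:
homology structure between windows (real datasets need redundancy
reduction), position-specific context preferences around real sites, and
class imbalance beyond the chosen counts.  Passing tests therefore
demonstrate that the pipeline recovers signal it is known to contain and
invents none where there is none — not that any particular accuracy is
attainable on real modification data.

## Evaluation

Stratified k-fold (default k = 10, shuffled, seeded) or stratified 80:20
hold-out.  Metrics are computed from the confusion counts at a 0.5
probability threshold — accuracy, precision, recall, F1, MCC — plus
AUC-ROC from the raw scores; fold values are aggregated by the mean.  A
metric whose denominator is zero (e.g. precision with no predicted
positives) is defined as 0 and logged; note the all-wrong classifier
(tp = tn = 0 with fp, fn > 0) has a *defined* MCC of −1.  Models run at
library defaults with a fixed seed; the network uses one hidden layer of
width min(10, ⌈d/2⌉) — the "capped at 10 or half the input size" rule read
as a minimum — giving input, hidden and sigmoid-output layers.  When the
spec includes `pro2vec`, embedding models are retrained on each fold's
training sequences only, so the representation never sees test data.

## Shapley explanations

The subset value function is interventional: v(S) fixes the features in S
to the instance's values and averages the model output over an explicit
background sample (the training split, capped at 100 seeded-subsampled
rows in the packaged workflow).  `exact_shapley` enumerates all 2^d
subsets with the classical weights |S|!(d−|S|−1)!/d! and is the
verification tool (guarded at d ≤ 16; cost O(2^d·|background|)).
`sampled_shapley` averages marginal contributions over seeded random
feature orderings — unbiased, with the residual between the estimate's sum
and f(x) − base spread uniformly so local accuracy holds exactly (residual
logged).  Scores explained are predicted probabilities (for forests, the
fraction of trees voting positive).  Third-party explainers can be plugged
in; `validate_adapter` rejects any output violating local accuracy.  The
axioms (efficiency, symmetry, null player) and the equivalence of the
subset-enumeration and permutation-average forms are asserted in the test
suite against independent oracles.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which each property is meaningfully exercised: embedding-bearing
checks use tens of peptides and few epochs; the chance-level-AUC check
uses 1000 label-independent peptides (sampling noise on a 10-fold AUC is
then well inside the ±0.05 band); exact-vs-permutation Shapley agreement
uses 6 features (720 orderings, exact to 1e−10).  The full published grid
(3 representations × 4 feature types × 3 offsets, six models) is available
through `ampfeat grid` but is not part of the default test run.
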