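# Methods

## Feature model

Each sequence is represented by k_max numbers, one per k-mer size
k = 1..k_max. For a given k, the sequence's overlapping windows (offsets
0..N−k) are counted, converted to relative frequencies
P_k = c_ik / (N−k+1), and collapsed to a single entropy value. Three
families are implemented:

- Shannon, H_S = −Σ p log₂ p (bits);
- Tsallis, H_T = (1 − Σ pᵠ)/(q − 1), log-free;
- Rényi, H_R = log₂(Σ pᵠ)/(1 − q) (bits).

Sums run over observed k-mers only; because 0ᵠ = 0 for every q > 0 this is
identical to summing over all |A|^k possible words. q ≤ 0 is rejected rather
than given an ad-hoc meaning.

**Units at q = 1.** Shannon and Rényi are printed with log₂ and therefore
measured in bits; the Tsallis formula is log-free, and its analytic q → 1
limit is the Shannon entropy in *nats* (H_S · ln 2). We evaluate q = 1 by
these analytic limits instead of raising an error, and test the two limit
conventions explicitly rather than hiding the discrepancy by silently
rescaling.

**Why entropy features can classify.** The entropy of the k-mer
distribution is permutation-invariant in the words: it measures the *shape*
of the composition (how concentrated it is), not which particular words
dominate. Classes that differ in compositional skew, repeat structure, or
correlation order are separable; classes that are symbol-relabelings of one
another (e.g. an exact A↔T/C↔G mirror) are not. This property drives the
design of the synthetic fixtures (below).

## Alphabets, ambiguity, and the denominator

DNA (ACGT), RNA (ACGU), and protein (20 amino acids) alphabets are kept
distinct; U is never silently recoded to T (an explicit `map_u_to_t` helper
exists for mixed files). Detection is by residue set, with composition ties
(an all-A sequence) resolving to DNA unless overridden.

Out-of-alphabet symbols are masked to the ambiguity character (N or X) by
default; a `drop_sequence` policy removes such records instead. Windows
containing a masked position are excluded from counting, and the denominator
becomes the number of *valid* windows so the frequencies remain a true
probability distribution. A `strict_denominator` switch restores the fixed
N−k+1 denominator for exact-replication runs; which convention an upstream
implementation uses on dirty input is generally undocumented, so both are
available. Counting is strand-specific (no reverse-complement
canonicalization): all |A|^k words are indexed separately, in fixed
lexicographic order (A<C<G<T etc.), which pins the raw-frequency feature
layout bit-exactly.

Degenerate rows (sequence shorter than k, or all windows ambiguous) yield
0.0 — not a missing value — keeping feature tables rectangular and
ML-ready; affected (id, k) pairs are reported as warnings and flagged on the
`FeatureVector`.

## Defaults and tunables

| parameter | default | meaning / rationale |
|---|---|---|
| k_max | 24 | feature count per sequence; entropy at k spans word lengths up to 24 |
| family | tsallis | the generalized family under study |
| q | 2.0 | entropic index; subextensive indices 1.1 < q < 5 classify best |
| q grid | 0.1..10.0 step 0.1, minus 1.0 | 99 values; 1.0 is the Shannon limit and excluded by default |
| hold-out | 70/30 stratified | single-partition evaluation |
| CV | 10-fold stratified | fold assignment fixed per (table, seed), reused across classifiers |
| normalization | min–max, train-fitted | constant columns map to 0; test values are not clipped |

Classifier families: Gaussian naive Bayes, random forest, bagging,
multi-layer perceptron, and gradient boosting (scikit-learn's
`GradientBoostingClassifier` as the boosted-ensemble family), all at library
defaults plus the run seed — the harness is a protocol, not a tuning study.
The MLP gets `max_iter=500` purely so small tables converge.

Conventions fixed where a choice had to be made: splits and folds are
stratified (stable class ratios on small fixtures); min–max ranges are
fitted on training data only, which is leakage-safe (a `paper_mode` flag
fits on the full table for replication studies); binary recall/F1/AUC treat
the lexicographically larger label as positive; multiclass recall/F1 are
macro-averaged and AUC is one-vs-rest macro (labeled as such in reports);
best/worst-q ties break toward the smaller q; in the entropy-family
comparison a metric tie credits one win to each family; a single-class test
partition leaves AUC undefined (reported missing with a warning) rather
than fabricating 0.5.

## Dimensionality-reduction baseline

The comparison baseline feeds raw k-mer frequency vectors
(k = 1..k_max concatenated; sparse CSR) through truncated SVD
(scikit-learn) or UMAP (umap-learn) down to 24 components — the same width
as the default entropy table — then cross-validates identically. The
reducer is fitted on the training rows of each fold only. k_max is capped
at 10 for nucleotides and 5 for proteins, past which the |A|^k feature
explosion stops being tractable on a desk. Dense vector construction refuses
above 200 000 columns and points to the sparse route.

## Synthetic fixtures

Fixtures are order-m Markov chains (order 1 by default: it produces k-mer
structure visible at several k, which is exactly what entropy-over-k
measures; orders 0 and 2 are available). The first `order` symbols are drawn
uniformly; all randomness flows from one integer seed through numpy
`SeedSequence` spawning, so per-class streams are independent yet the whole
dataset reproduces bit-for-bit. Default lengths are uniform in [200, 500] —
within the regime where entropy features carry signal, yet cheap.

- `separable_pair`: a strongly GC-skewed chain (per-row entropy ≈ 1.5–1.6
  bits) vs. a mildly AT-skewed chain (≈ 1.9 bits). The two were
  deliberately *not* made mirror images: entropy features cannot see a pure
  symbol relabeling, so the classes differ in skew magnitude, not just
  direction.
- `null_pair`: both labels drawn from one uniform chain — the chance-level
  negative control.
- `multiclass3`: uniform, skewed, and self-transition-heavy ("repetitive")
  chains; the repetitive chain matches the uniform one at k = 1 but not at
  higher k, exercising the multi-k structure of the features.

What the fixtures do *not* emulate: gene structure, ORFs, codon bias,
GC-isochores, repeat families, or the length distributions of real
transcripts. Passing tests therefore demonstrate that the implementation is
correct and that the protocol detects compositional signal when present and
reports chance when absent — not that any particular accuracy will be
reached on real data.

A sequence-length experiment (`length_effect_experiment`, lengths 50 / 250 /
1000 / 5000) reports how accuracy varies with sequence length — entropy
estimates at large k are noisy on short sequences — but no monotonicity is
asserted as a hard test, since the separable fixture can saturate at every
length.

## Problem sizes and numerical choices

The test suite and the acceptance script run the protocol at desk scale,
the package's chosen study conditions: 50–100 sequences per class, 20 seeded
hold-outs for the chance-level control, a 4-point q grid {0.5, 2, 5, 9.6}
with two classifiers for the scan shape, and k ≤ 10 (SVD baseline k ≤ 6)
for the raw k-mer matrix. Feature CSVs serialize floats at 10 significant
digits, which makes repeated extractions byte-identical. Tolerances used in
tests: pseudo-additivity to 1e-9 (exact identity, float error only); q → 1
limits to 1e-4 at q = 1 ± 1e-6 (first-order truncation error);
probability-sum checks to 1e-12.

## Known limitations

- Entropy features are blind to symbol relabelings (see above); problems
  whose classes differ only by which words dominate, not how concentrated
  the distribution is, need complementary descriptors.
- On sequences much shorter than 2^H(k), high-k entropy estimates are
  dominated by the window count (support saturates at N−k+1), so features
  at large k mostly encode length; this is the mechanism behind the
  better-with-longer-sequences behavior.
- The harness deliberately performs no hyperparameter search and no
  significance testing between classifiers.
- UMAP's embedding is only reproducible with its `random_state` set, which
  forces single-threaded nearest-neighbor search; SVD is the faster and
  exactly deterministic baseline.
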