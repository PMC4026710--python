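# Methods

## Corpus model and preprocessing

A corpus is an ordered list of documents → paragraphs → lowercase tokens.
The paragraph is the fundamental unit: it is both the co-occurrence window
of the paragraph-mode graph and the "document" over which document
frequency (df), IDF, and PMI are computed. Tokenization keeps maximal
lowercase alphabetic runs with internal apostrophes and discards
everything else; paragraph breaks default to blank lines and are
configurable as a regex.

Cleaning applies three filters in a fixed order:

1. **stoplist** — a bundled 127-word English function-word list by default,
   injectable as a file;
2. **wordlist** (optional) — types absent from a dictionary wordlist are
   dropped; optional because synthetic corpora are whitelisted by
   construction;
3. **hapax** — types with corpus-wide frequency < 2 (counted *after* the
   first two filters) are dropped in a single pass.

Whether hapax counting should precede or follow the wordlist filter is
genuinely open; we count after, treating the dictionary filter as part of
corpus definition. Single-pass hapax removal is sufficient because
removing one type never changes another type's count — the operation is
exactly idempotent, which a property test verifies along with token
conservation (tokens in = tokens retained + Σ removed per stage).
Length-1 paragraphs are retained in the cleaned corpus (they carry df
information) but contribute no edges.

`idf(w) = log10(n_docs / df(w))`, choosing log base 10 for consistency
with the PMI definition below. A word in every paragraph has idf 0, which
deliberately makes the inverse-IDF normalizations (7, 8) undefined there —
see *Degenerate inputs*.

## Graph construction

Paragraph mode pairs every token *position* with every other position in
the same paragraph; fixed-k mode pairs positions at distance ≤ k in the
cleaned token sequence (k = 1 links only adjacent tokens). Each pair
increments the edge weight by 1 regardless of separation. Identical-type
positional pairs are skipped: self-loops are meaningless for the pair
metrics. Counting is positional, so the paragraph [a, b, a] yields edge
a–b with weight 2. An O(n²) naive enumerator is kept in the test suite as
an oracle; the production builder (which aggregates by type counts per
paragraph) must match it exactly on random corpora, in both modes.

Edges are stored once per unordered pair; files are TSV edge lists sorted
lexicographically plus a node table and a JSON sidecar, and the round trip
is lossless and validating (duplicate pairs, self-loops, and non-positive
weights are rejected with line numbers).

## Normalization schemes

Fifteen schemes rescale an edge weight by its endpoints' f, df, or idf
(see `gold.normalize` for the full table). Scheme 1 is the identity;
scheme 2 is `PMI = log10(w·n_docs/(df1·df2))`. Schemes 12–15 divide the
weight by `(f1+f2)` or `(f1·f2)` multiplied or divided by its log10 —
the normalizer is named by what it does to the denominator. All schemes
are symmetric in the endpoints; all are linear in the weight except PMI
(doubling the weight adds log10 2).

A monotonicity caveat: the inverse-df and log-frequency schemes (9, 10,
12–15) never increase when endpoint frequency rises with the weight held
fixed, and are property-tested for it. The inverse-IDF schemes (7, 8)
*increase* with frequency, because idf itself is an inverse-frequency
quantity — dividing by it inverts twice. They are retained as defined.

## Association and similarity features

Association, calc `raw`: the scheme applied to the direct edge weight
(scheme 2 then *is* the edge's PMI). Absent edge → 0, "no relationship".

Association, calc `pmi`: PMI computed from the raw weight, then rescaled
by the scheme's multiplicative frequency factor. **Composition caveat**:
scheme 2 is the PMI transform itself, not a multiplicative factor, so
`assoc_pmi_n02` is defined as plain PMI and numerically equals
`assoc_pmi_n01`. Both names are kept so the 2 × 15 grid is complete and
enumerable. Absent edge → sentinel −10 with the mask bit set (finite for
classifiers, below any observable PMI at desk scale).

Similarity decomposes the two adjacency lists into overlap (Vo) and
exclusive (Vn1, Vn2) sets, endpoints excluded. Per-node weights are
normalized with their own edge's endpoint statistics before summation,
then **floored at 0**: scheme 2 can be negative on small corpora, and a
negative weight would break both the [−1, 1] range of Methods 1–4 and the
positivity requirement of the magnitude transform. A sub-chance edge
simply contributes no evidence; a floored-to-zero overlap weight
contributes 0 to the magnitude-scaled sum. Set sizes |Vo| and |Vn| =
|Vn1| + |Vn2| are structural (normalization-independent), and Method 2's
non-overlap sum is divided by the *joint* |Vn|.

Methods: M1 = (Σov − Σnon)/(Σov + Σnon); M2 size-normalizes both sums; M3
replaces each overlap pair (w1n, w2n) by `(w1n+w2n)/(max/min)`; M4 = M3 +
size normalization; M5 = mean magnitude-scaled overlap weight only (≥ 0,
unbounded, 0 for empty overlap). Empty overlap degenerates M1–M4 toward
−1 naturally; an isolated pair (no weight anywhere) returns 0 with the
mask bit set. Identical-word pairs are rejected — self-similarity is
undefined by the overlap construction.

The feature vector enumerates all 105 combinations in a fixed order
(30 association, then 75 similarity); per-feature domain errors become
masked NaNs rather than failures.

## Classification protocol

A multilayer perceptron with one hidden layer of 20 neurons, L2 penalty
α = 1.0, and at most 300 optimizer iterations, evaluated over repeated
(default 10) stratified 70/30 train/test splits, each reseeded
deterministically from the master seed; the report (per-iteration
accuracies, mean, summed confusion matrix) is a pure function of
(features, labels, seed). Stratification is our choice — with ~20 pairs
per class, unstratified splits are unstable. Within each split, masked
NaNs are imputed with the training-column minimum (a masked feature means
"less related than anything observed") and features are z-scored with
training-split statistics; the 105 features span orders of magnitude and
an L2-regularized MLP needs comparable inputs. Whether a particular
off-the-shelf classifier would standardize internally is unknowable from
the outside; the standardization here is an explicit, documented choice.
The confusion matrix is stored summed over iterations so its cells add up
exactly to the total number of test predictions.

Feature analysis: round 1 scores each feature alone (5 splits), keeps the
top 50 (ties broken by name for determinism); round 2 scores all
C(50, 2) = 1225 unordered pairs. The scorer is injectable so structural
properties of the sweep can be checked without paying for 6 000 MLP fits.
A linear-SVM-weight feature selector is provided as a utility for
reducing the set further. A grouped comparison runs the protocol on the
30 association columns and the 75 similarity columns separately.

## LSA baseline

A term-by-paragraph count matrix over the same cleaned corpus is factored
by truncated SVD; word vectors are U·s and pairs are scored by cosine.
Raw counts are the default weighting — transparent rather than guessing a
library's internal default — with a log-entropy switch available.
Dimensionality defaults to 300 and scales down for small corpora; for
matrices with min dimension ≤ 400 a dense LAPACK SVD is used (enabling an
exact rank check and full-rank reconstruction), otherwise ARPACK with a
fixed start vector. Requesting k above the (numerical) rank raises an
error. The cosine of a numerically zero vector is 0 with a warning. The
cosine feeds the same classifier protocol as a one-column feature table;
a raw-vector mode is deliberately not the default.

## Synthetic corpus generator

The generator emulates the statistical shape of a cleaned web-forum
corpus: Zipf-distributed type frequencies (exponent 1.0, the standard
natural-language value, which also exercises the frequency normalizations
meaningfully) and lognormal paragraph lengths targeting mean ≈ 10.5 and
median ≈ 7 tokens. Those length targets govern the base text; planted
insertions add a few tokens per paragraph on top. Defaults: 500 base
types, 10 topics, 200 paragraphs, 20 planted pairs per relation class at
strength 0.8 (≈ 10 insertion paragraphs per planted word), 20 unrelated
pairs.

A topic-mixture family was chosen because it yields the
direct-co-occurrence vs shared-context dissociation the three relation
classes embody: paragraphs draw one topic (with a 20% corpus-wide
background admixture); *associated* pairs are co-inserted adjacently into
random paragraphs across topics (direct edge, little shared context);
*similar* pairs are synonyms of one topic inserted into disjoint
paragraph sets (shared context, direct co-occurrence suppressed); *both*
pairs split their insertions between the two mechanisms. Planted words
live outside the Zipf base sample, so suppression is exact by
construction. Unrelated pairs are cross-topic base words with realized
frequency ≥ 2 (guaranteeing survival of hapax removal). Generation is
bit-identical for a fixed (spec, seed).

What passing tests on this generator do **not** show: real corpora have
misspellings, protowords, register variation, polysemy, and far heavier
frequency tails; planted relations here are cleaner and stronger than
free-association or category norms, so absolute accuracies on synthetic
data (near 1.0 at the defaults) say nothing about accuracy on real
stimulus sets — only that the graph carries the planted distinction and
the pipeline recovers it above a permutation null.

## Problem sizes

The reference validation conditions are: 200 random mini-corpora (≤ 50
paragraphs × ≤ 10 tokens) for builder–oracle equivalence; 500 random
graphs (≤ 30 nodes) for metric invariants; 50 replicate synthetic corpora
at the default spec for the planted-separation check (threshold: planted
minus unrelated mean ≥ 3 × the standard error of the unrelated per-seed
means); and a 100-permutation label-shuffle null for the three-class
classification run, all chosen as the package's reference scale.

## Known limitations

- Edge weights ignore token distance within the window and word order;
  directional association is out of scope.
- Graph-wide normalization is computed lazily per query; no materialized
  normalized edge dump beyond the TSV export.
- The PMI absent-edge sentinel (−10) and min-imputation are pragmatic
  conventions for finite feature matrices, not estimates of unobserved
  PMI.
- Document-level (arbitrary-span) similarity inputs and distance-binned
  weight profiles are not implemented.
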