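# gold

Graph-of-language-distribution modeling of word **association** and
**semantic similarity** from co-occurrence statistics.

Psycholinguistics distinguishes two ways words can be related: *associated*
words co-occur in the same contexts (mold–bread), while *similar* words
share meaning by occurring in the same kinds of contexts without
necessarily co-occurring (table–bed); many pairs are both (aunt–uncle).
This package represents a text corpus as a weighted undirected graph —
nodes are word types, an edge weight counts how often two words co-occur
inside a window (a whole paragraph, or only adjacent positions) — and
derives both relation signals directly from the graph:

- **Association** lives on the *direct edge* between the two words: the raw
  weight `w`, or pointwise mutual information
  `PMI = log10(w · n_docs / (w1df · w2df))`, where `df` is the number of
  paragraphs containing a word.
- **Similarity** lives in the *shared neighborhood*: the pair's neighbors
  split into the overlap set `Vo` (connected to both) and non-overlap sets
  `Vn1`, `Vn2`, and five methods compare summed weights to the two regions,
  e.g. Method 1 = (Σ overlap − Σ non-overlap) / Σ total ∈ [−1, 1].
  Methods 3–5 first pass each overlap weight pair through the
  magnitude-difference transform `(w1+w2) / (max(w1,w2)/min(w1,w2))`,
  which rewards balanced connections.

Because raw weights scale with word frequency, every metric exists in 15
normalization flavours (raw, PMI, and sum/product combinations of f, df,
idf with log transforms), giving a 105-dimensional feature vector per word
pair (30 association + 75 similarity). A repeated-split neural-network
protocol (single hidden layer of 20 units, L2 penalty 1.0, stratified
70/30 splits) measures how well those features separate relation classes,
with a truncated-SVD LSA baseline for comparison, and a synthetic-corpus
generator plants ground-truth associated/similar/both pairs so the whole
pipeline is testable without external data.

## Worked example

The toy neighborhood of the pair *(grumpy, cat)*: two shared neighbors —
*face* with weights (9, 52) and *depressed* with weights (2, 3) — plus
*mood* (4) only for grumpy and *whiskers* (6) only for cat
(`examples/03_pair_metrics.py`):

```text
overlap nodes: {'face': (9, 52), 'depressed': (2, 3)}
grumpy-only: {'mood': 4}  cat-only: {'whiskers': 6}
magnitude transform face: (9, 52) -> 10.56 (of 61 raw)
magnitude transform depressed: (2, 3) -> 3.33 (of 5 raw)
Method 1: 0.7368
Method 2: 0.7368
Method 3: 0.1629
Method 4: 0.1629
Method 5: 6.9455
```

Method 1 is the plain proportion difference (66−10)/76 = 0.7368. The
magnitude transform shrinks the unbalanced pair (9, 52) to 10.56 — 18% of
its raw mass — but keeps the balanced (2, 3) at 67%, so Methods 3–4 drop
to 0.16; Method 5 is the mean transformed overlap weight
(10.56 + 3.33)/2 = 6.9455.

On the default synthetic corpus (500 base types, 200 paragraphs, 20
planted pairs per class) the full 105-feature classifier separates the
three relation classes perfectly (`examples/04_synthetic_classification.py`):

```text
corpus: 200 paragraphs; {'associated': 20, 'similar': 20, 'both': 20, 'unrelated': 20}
graph: 330 nodes, 9067 edges
mean accuracy: 1.0000 over 10 iterations
```

## Command line

A thin CLI wires the stages: `gold preprocess`, `gold build-graph`,
`gold metrics`, `gold classify`, `gold ablation`, `gold lsa`,
`gold synth`, and `gold pipeline` (all of them end to end). Every command
writes a manifest with input/output checksums; reruns with the same seed
are byte-identical. `gold pipeline --out run/` is the quickest tour.

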