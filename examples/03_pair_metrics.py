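"""The overlap decomposition and the five similarity methods, worked out.

Reconstructs the textbook toy neighborhood: the pair (grumpy, cat) shares
two neighbors — "face" with weights (9, 52) and "depressed" with weights
(2, 3) — while "mood" (weight 4) belongs only to grumpy and "whiskers"
(weight 6) only to cat.  Prints the magnitude-difference transform of each
overlap node and all five similarity scores on raw weights.
"""

from gold import build_graph, decompose, magnitude_scale, similarity
from gold.corpus import CleanCorpus

# paragraphs repeated to realize the exact edge weights
paragraphs = (
    [["grumpy", "face"]] * 9 + [["cat", "face"]] * 52
    + [["grumpy", "depressed"]] * 2 + [["cat", "depressed"]] * 3
    + [["grumpy", "mood"]] * 4 + [["cat", "whiskers"]] * 6
)
clean = CleanCorpus(paragraphs=paragraphs, vocabulary={t for p in paragraphs for t in p})
g = build_graph(clean, "paragraph")

d = decompose(g, "grumpy", "cat")
print("overlap nodes:", {n: w for n, w in d.vo.items()})
print("grumpy-only:", d.vn1, " cat-only:", d.vn2)

for node, (w1, w2) in d.vo.items():
    print(f"magnitude transform {node}: ({w1}, {w2}) -> {magnitude_scale(w1, w2):.2f} "
          f"(of {w1 + w2} raw)")

for m in range(1, 6):
    v, _ = similarity(g, "grumpy", "cat", m, norm=1)
    print(f"Method {m}: {v:.4f}")
# Methods 1-4 are proportion differences in [-1, 1]; Method 5 is the mean
# magnitude-scaled overlap weight (unbounded above, 0 with no overlap).
# Unbalanced overlap weights like (9, 52) are shrunk hard by the transform.
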