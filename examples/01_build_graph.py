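"""Tokenize a small text, clean it, and build both co-occurrence graphs.

Prints the removal log, the type statistics, and the edge lists of the
paragraph-window graph and the adjacency (window = 1) graph.  Paragraph
windows connect everything that shares a paragraph; window 1 connects only
immediately adjacent tokens of the cleaned text.
"""

from gold import build_graph, compute_stats, default_stoplist, preprocess, tokenize

TEXT = """\
The grumpy cat sat on the mat. The cat stared at the dog.

A grumpy dog barked at the cat. The dog sat on the mat.

The cat and the dog shared the mat. The mat was grey.
"""

raw = tokenize(TEXT)
clean = preprocess(raw, stoplist=default_stoplist())
print("paragraphs:", clean.paragraphs)
print("removed per stage:", clean.removal_log)

stats = compute_stats(clean)
for w in sorted(stats.f):
    print(f"  {w:8s} f={stats.f[w]}  df={stats.df[w]}  idf={stats.idf[w]:.3f}")

for window in ("paragraph", 1):
    g = build_graph(clean, window)
    print(f"\n{g.window_mode} graph: {g.n_edges} edges, total weight {g.total_weight}")
    for u, v, w in g.edges():
        print(f"  {u}--{v}: {w}")
# Edge weights count token pairs inside the window: 'cat--mat' is heavier in
# paragraph mode because the two words share paragraphs without being adjacent.
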