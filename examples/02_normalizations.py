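"""Evaluate all 15 edge-weight normalization schemes on one edge.

High-frequency words carry heavy weights merely because they are frequent;
each scheme rescales the raw co-occurrence count by the endpoint words'
frequency, document frequency, or IDF.  Scheme 1 is the raw weight and
scheme 2 is PMI (zero when the words co-occur exactly as often as their
frequencies predict, negative below chance).
"""

from gold import (
    METHODS,
    NormalizationDomainError,
    build_graph,
    default_stoplist,
    normalize_weight,
    preprocess,
    tokenize,
)

TEXT = """\
cats chase mice. mice fear cats.

cats sleep all day. dogs chase cats.

mice eat cheese. cats watch mice eat.
"""

clean = preprocess(tokenize(TEXT), stoplist=default_stoplist())
g = build_graph(clean, "paragraph")

u, v = "cats", "mice"
print(f"edge {u}--{v}: raw weight {g.edge_weight(u, v)}, "
      f"f=({g.stats.f[u]}, {g.stats.f[v]}), df=({g.stats.df[u]}, {g.stats.df[v]})")
for mid, method in METHODS.items():
    try:
        value = normalize_weight(g, u, v, mid)
        print(f"  {mid:2d} {method.name:20s} {value:10.4f}")
    except NormalizationDomainError as err:
        # a word occurring in every paragraph has idf 0, so the inverse-IDF
        # schemes are undefined on this toy corpus — surfaced, not clamped
        print(f"  {mid:2d} {method.name:20s}   undefined ({err})")
# Inverse-frequency schemes (7-10, 12-15) shrink edges of frequent words;
# multiplicative schemes (3-6, 11) amplify them instead.
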