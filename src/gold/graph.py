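"""Weighted undirected word co-occurrence graph.

Two window modes are supported:

* ``"paragraph"`` — every token position in a paragraph is paired with every
  other position in the same paragraph (the big-window graph);
* ``fixed k`` (an integer) — each position is paired with positions at
  distance ≤ k in the cleaned paragraph; ``k = 1`` links only immediately
  adjacent tokens (the small-window graph).

Counting is positional: a repeated type contributes one increment per
positional pair.  Pairs of identical types are skipped — self-loops carry no
information for the pair metrics.  Length-1 paragraphs contribute nothing.
All pairs in a window increment the edge weight by exactly 1 regardless of
separation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import CleanCorpus, CorpusStats, compute_stats

__all__ = ["CooccurrenceGraph", "build_graph", "write_graph", "read_graph"]


@dataclass
class CooccurrenceGraph:
    """Symmetric weighted graph with per-node corpus statistics.

    Edges are stored once per unordered pair in ``adj`` (a dict-of-dicts
    adjacency mirrored in both directions); weights are positive integers.
    """

    stats: CorpusStats
    adj: dict[str, dict[str, int]] = field(default_factory=dict)
    window_mode: str = "paragraph"

    @property
    def n_docs(self) -> int:
        return self.stats.n_docs

    @property
    def vocabulary(self) -> set[str]:
        return set(self.stats.f)

    def edge_weight(self, u: str, v: str) -> int:
        """Raw co-occurrence count for the unordered pair, 0 if absent."""
        return self.adj.get(u, {}).get(v, 0)

    def neighbors(self, w: str) -> dict[str, int]:
        return self.adj.get(w, {})

    def edges(self):
        """Iterate (u, v, weight) once per edge, lexicographically ordered."""
        for u in sorted(self.adj):
            for v in sorted(self.adj[u]):
                if u < v:
                    yield u, v, self.adj[u][v]

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.adj.values()) // 2

    @property
    def total_weight(self) -> int:
        """Sum of edge weights = number of counted token pairs."""
        return sum(w for nb in self.adj.values() for w in nb.values()) // 2

    def weighted_degree(self, w: str) -> int:
        return sum(self.adj.get(w, {}).values())


def build_graph(clean: CleanCorpus, window: str | int = "paragraph") -> CooccurrenceGraph:
    """Count token-pair co-occurrences and materialize the graph.

    Parameters
    ----------
    clean:
        Filtered corpus; must be nonempty.
    window:
        ``"paragraph"`` or a positive integer window size ``k``.

    Raises
    ------
    ValueError
        On an empty corpus or an unrecognized window mode.
    """
    if not clean.paragraphs:
        raise ValueError("cannot build a graph from an empty corpus")
    if isinstance(window, str) and window != "paragraph":
        if window.isdigit() and int(window) > 0:
            window = int(window)
        else:
            raise ValueError(f"unknown window mode: {window!r}")
    if isinstance(window, int) and window < 1:
        raise ValueError(f"window size must be >= 1, got {window}")

    counts: Counter[tuple[str, str]] = Counter()
    if window == "paragraph":
        for para in clean.paragraphs:
            n = len(para)
            if n < 2:
                continue
            # aggregate by type first: positional pairs of types a != b in a
            # paragraph number c[a]*c[b]; identical-type pairs are skipped
            c = Counter(para)
            types = sorted(c)
            for i, a in enumerate(types):
                ca = c[a]
                for b in types[i + 1:]:
                    counts[(a, b)] += ca * c[b]
    else:
        k = window
        for para in clean.paragraphs:
            n = len(para)
            if n < 2:
                continue
            for i in range(n):
                a = para[i]
                for j in range(i + 1, min(i + k + 1, n)):
                    b = para[j]
                    if a == b:
                        continue
                    counts[(a, b) if a < b else (b, a)] += 1

    adj: dict[str, dict[str, int]] = {}
    for (a, b), w in counts.items():
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w
    mode = "paragraph" if window == "paragraph" else f"fixed-{window}"
    return CooccurrenceGraph(stats=compute_stats(clean), adj=adj, window_mode=mode)


# ---------------------------------------------------------------------------
# file round-trip: edge TSV + node TSV + JSON sidecar


def write_graph(graph: CooccurrenceGraph, out_dir: str | Path) -> None:
    """Write edges.tsv (lexicographic), nodes.tsv, and meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("word_u\tword_v\tweight\n")
        for u, v, w in graph.edges():
            fh.write(f"{u}\t{v}\t{w}\n")
    with open(out / "nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("type\tf\tdf\tidf\n")
        for w in sorted(graph.stats.f):
            fh.write(
                f"{w}\t{graph.stats.f[w]}\t{graph.stats.df[w]}\t"
                f"{graph.stats.idf[w]:.10g}\n"
            )
    meta = {
        "window_mode": graph.window_mode,
        "n_docs": graph.n_docs,
        "n_nodes": len(graph.stats.f),
        "n_edges": graph.n_edges,
        "total_weight": graph.total_weight,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1), "utf-8")


def read_graph(in_dir: str | Path) -> CooccurrenceGraph:
    """Inverse of :func:`write_graph`; validates edge-file invariants.

    Raises
    ------
    ValueError
        On malformed lines (with line number), duplicated unordered pairs,
        self-loops, or non-positive weights.
    """
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text("utf-8"))

    f: dict[str, int] = {}
    df: dict[str, int] = {}
    idf: dict[str, float] = {}
    with open(src / "nodes.tsv", encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n") != "type\tf\tdf\tidf":
            raise ValueError(f"{src / 'nodes.tsv'}:1: bad header {header!r}")
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{src / 'nodes.tsv'}:{i}: expected 4 fields")
            w, fs, dfs, idfs = parts
            f[w], df[w], idf[w] = int(fs), int(dfs), float(idfs)

    adj: dict[str, dict[str, int]] = {}
    seen: set[tuple[str, str]] = set()
    with open(src / "edges.tsv", encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n") != "word_u\tword_v\tweight\n".rstrip("\n"):
            raise ValueError(f"{src / 'edges.tsv'}:1: bad header {header!r}")
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{src / 'edges.tsv'}:{i}: expected 3 fields")
            u, v, ws = parts
            try:
                w = int(ws)
            except ValueError:
                raise ValueError(
                    f"{src / 'edges.tsv'}:{i}: non-integer weight {ws!r}"
                ) from None
            if u == v:
                raise ValueError(f"{src / 'edges.tsv'}:{i}: self-loop {u!r}")
            if w < 1:
                raise ValueError(f"{src / 'edges.tsv'}:{i}: weight must be >= 1")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise ValueError(
                    f"{src / 'edges.tsv'}:{i}: duplicate unordered pair {key}"
                )
            seen.add(key)
            adj.setdefault(u, {})[v] = w
            adj.setdefault(v, {})[u] = w

    stats = CorpusStats(n_docs=int(meta["n_docs"]), f=f, df=df, idf=idf)
    return CooccurrenceGraph(stats=stats, adj=adj, window_mode=meta["window_mode"])
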