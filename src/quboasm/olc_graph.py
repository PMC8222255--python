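"""Directed overlap (OLC) graph construction and analysis.

Vertices are fragments (reads or k-mers); a directed edge u -> v records
the longest exact suffix-prefix overlap of at least ``min_overlap``
characters between the string of u and the string of v.  Overlaps are
exact-match only: the intended inputs are error-free, so no alignment
scoring is needed.  Full containment (one fragment inside another) yields
no edge.

Also provided: acyclicity check with topological order, exhaustive
single-edge-cut partitioning at toy scale, Hamiltonian-path search used as
a classical exact route and test oracle, and TSV/CSV/DOT export.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .synthetic_data import SequenceRecord

__all__ = [
    "OLCGraph",
    "GraphPartition",
    "overlap_length",
    "build_olc_graph",
    "is_acyclic",
    "partition_single_edge_cuts",
    "enumerate_hamiltonian_paths",
    "find_hamiltonian_path",
]


def overlap_length(a: str, b: str, min_overlap: int = 1) -> int | None:
    """Longest L >= min_overlap with suffix(a, L) == prefix(b, L), or None.

    Exact match only; L is strictly less than both lengths, so containment
    does not count as an overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not a or not b:
        raise ValueError("empty strings have no overlaps")
    max_l = min(len(a), len(b)) - 1
    if max_l < min_overlap:
        return None
    # anchor on the min_overlap-length prefix of b; scan its occurrences in
    # the suffix window of a from the left so the first verified hit is the
    # longest overlap
    anchor = b[:min_overlap]
    pos = a.find(anchor, len(a) - max_l)
    while pos != -1:
        L = len(a) - pos
        if L <= max_l and a[pos:] == b[:L]:
            return L
        pos = a.find(anchor, pos + 1)
    return None


class OLCGraph:
    """Directed overlap graph with labelled vertices carrying strings.

    Thin wrapper over a :class:`networkx.DiGraph`; vertex order is the
    insertion order of the distinct fragments, and each edge stores the
    exact overlap length as the ``overlap`` attribute.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self._order: list[str] = []

    # -- construction -----------------------------------------------------
    def add_vertex(self, label: str, seq: str) -> None:
        if label in self._g:
            raise ValueError(f"duplicate vertex label {label!r}")
        self._g.add_node(label, seq=seq)
        self._order.append(label)

    def add_edge(self, u: str, v: str, overlap: int) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if overlap < 1:
            raise ValueError("overlap length must be >= 1")
        self._g.add_edge(u, v, overlap=overlap)

    # -- accessors --------------------------------------------------------
    @property
    def vertices(self) -> list[str]:
        return list(self._order)

    @property
    def N(self) -> int:
        return self._g.number_of_nodes()

    @property
    def M(self) -> int:
        return self._g.number_of_edges()

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edges in lexicographic (vertex-index) order."""
        idx = {v: i for i, v in enumerate(self._order)}
        return sorted(self._g.edges(), key=lambda e: (idx[e[0]], idx[e[1]]))

    def seq(self, label: str) -> str:
        return self._g.nodes[label]["seq"]

    def overlap(self, u: str, v: str) -> int:
        return self._g.edges[u, v]["overlap"]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def successors(self, u: str) -> list[str]:
        return list(self._g.successors(u))

    def predecessors(self, v: str) -> list[str]:
        return list(self._g.predecessors(v))

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def adjacency_matrix(self) -> np.ndarray:
        """0/1 adjacency in vertex order."""
        idx = {v: i for i, v in enumerate(self._order)}
        m = np.zeros((self.N, self.N), dtype=int)
        for u, v in self._g.edges():
            m[idx[u], idx[v]] = 1
        return m

    def __repr__(self) -> str:  # pragma: no cover
        return f"OLCGraph(N={self.N}, M={self.M})"

    # -- serialisation ----------------------------------------------------
    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["u", "v", "overlap"])
            for u, v in self.edges:
                w.writerow([u, v, self.overlap(u, v)])

    def to_adjacency_csv(self, path: str | Path) -> None:
        m = self.adjacency_matrix()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + self.vertices)
            for label, row in zip(self.vertices, m):
                w.writerow([label] + row.tolist())

    def to_dot(self, path: str | Path) -> None:
        lines = ["digraph olc {"]
        for v in self.vertices:
            lines.append(f'  "{v}" [label="{v}\\n{self.seq(v)}"];')
        for u, v in self.edges:
            lines.append(f'  "{u}" -> "{v}" [label="{self.overlap(u, v)}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edge_tsv(cls, path: str | Path, seqs: dict[str, str]) -> "OLCGraph":
        g = cls()
        for label, s in seqs.items():
            g.add_vertex(label, s)
        with open(path, newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if header[:3] != ["u", "v", "overlap"]:
                raise ValueError(f"unexpected edge-list header {header!r}")
            for u, v, ov in r:
                g.add_edge(u, v, int(ov))
        return g


def build_olc_graph(
    fragments: Sequence[SequenceRecord],
    min_overlap: int,
    collapse_duplicates: bool = True,
) -> OLCGraph:
    """All-against-all exact suffix-prefix overlap graph.

    With ``collapse_duplicates`` (default) one vertex is created per
    distinct fragment string, labelled by the string itself; otherwise one
    vertex per record, labelled by the record id.  For k-mer input with
    ``min_overlap = k - 1`` this realises the (k-1)-overlap rule.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments to build an overlap graph")
    g = OLCGraph()
    if collapse_duplicates:
        seen: set[str] = set()
        for f in fragments:
            if f.seq not in seen:
                seen.add(f.seq)
                g.add_vertex(f.seq, f.seq)
        if g.N == 1:
            warnings.warn("all fragments identical: degenerate single-vertex graph")
            return g
    else:
        for f in fragments:
            g.add_vertex(f.id, f.seq)
    labels = g.vertices
    contained = 0
    for u in labels:
        su = g.seq(u)
        for v in labels:
            if u == v:
                continue
            sv = g.seq(v)
            ov = overlap_length(su, sv, min_overlap)
            if ov is not None:
                g.add_edge(u, v, ov)
            elif su != sv and (su in sv or sv in su):
                contained += 1
    if contained:
        warnings.warn(
            f"{contained // 2 or contained} containment pair(s) detected; "
            "contained fragments produce no edges"
        )
    return g


def is_acyclic(g: OLCGraph) -> tuple[bool, list[str] | None]:
    """(True, topological order) for a DAG, else (False, None)."""
    dg = g.to_networkx()
    if nx.is_directed_acyclic_graph(dg):
        return True, list(nx.topological_sort(dg))
    return False, None


@dataclass
class GraphPartition:
    """Vertex blocks with exactly one edge between consecutive blocks."""

    parts: list[list[str]]
    cut_edges: list[tuple[str, str]]
    success: bool
    message: str = ""


def _single_cut_edges(dg: nx.DiGraph) -> Iterator[tuple[tuple[str, str], set, set]]:
    """Yield edges whose removal leaves exactly two weakly connected halves
    with no other edge crossing between them."""
    und = dg.to_undirected(as_view=False)
    for u, v in list(dg.edges()):
        und.remove_edge(u, v)
        comps = list(nx.connected_components(und))
        if len(comps) == 2:
            yield (u, v), comps[0], comps[1]
        und.add_edge(u, v)


def partition_single_edge_cuts(g: OLCGraph, n_parts: int) -> GraphPartition:
    """Split the graph into ``n_parts`` weakly connected blocks such that
    consecutive blocks are joined by exactly one edge.

    Exhaustive recursion over single-edge cuts (toy scale); returns a
    failure status, never raises, when no such split exists.
    """
    if n_parts < 2:
        raise ValueError("n_parts must be >= 2")
    dg = g.to_networkx()
    if not nx.is_weakly_connected(dg):
        return GraphPartition([], [], False, "graph is not weakly connected")

    def recurse(sub: nx.DiGraph, parts_left: int):
        if parts_left == 1:
            return [set(sub.nodes)], []
        for (u, v), ca, cb in _single_cut_edges(sub):
            # u's side comes first in the ordering: the cut edge points
            # from the first block into the second
            first, rest = (ca, cb) if u in ca else (cb, ca)
            if v not in rest:
                continue
            sol = recurse(sub.subgraph(rest).copy(), parts_left - 1)
            if sol is not None:
                parts, cuts = sol
                return [first] + parts, [(u, v)] + cuts
        return None

    sol = recurse(dg, n_parts)
    if sol is None:
        return GraphPartition(
            [], [], False, f"no split into {n_parts} single-edge-connected blocks"
        )
    parts, cuts = sol
    order = {v: i for i, v in enumerate(g.vertices)}
    return GraphPartition(
        parts=[sorted(p, key=order.get) for p in parts],
        cut_edges=cuts,
        success=True,
    )


# ---------------------------------------------------------------------------
# Hamiltonian-path search (classical exact route and test oracle)


def enumerate_hamiltonian_paths(g: OLCGraph, limit: int | None = None) -> list[list[str]]:
    """All Hamiltonian paths by backtracking (small graphs only)."""
    dg = g.to_networkx()
    n = g.N
    paths: list[list[str]] = []

    def extend(path: list[str], used: set[str]) -> bool:
        if len(path) == n:
            paths.append(list(path))
            return limit is not None and len(paths) >= limit
        for w in dg.successors(path[-1]):
            if w not in used:
                path.append(w)
                used.add(w)
                if extend(path, used):
                    return True
                used.remove(w)
                path.pop()
        return False

    for start in g.vertices:
        if extend([start], {start}):
            break
    return paths


def find_hamiltonian_path(
    g: OLCGraph, node_budget: int = 5_000_000
) -> list[str] | None:
    """One Hamiltonian path, or None if none exists (or the search budget
    is exhausted).

    Backtracking with two standard accelerations suited to overlap graphs:
    successors are tried longest-overlap-first (consecutive genomic
    fragments share the longest overlaps), and vertices of in-degree 0
    are tried as start vertices first.
    """
    dg = g.to_networkx()
    n = g.N
    if n == 0:
        return None
    if n == 1:
        return [g.vertices[0]]
    succ = {
        u: sorted(dg.successors(u), key=lambda w: -dg.edges[u, w]["overlap"])
        for u in dg.nodes
    }
    budget = [node_budget]

    def extend(path: list[str], used: set[str]) -> list[str] | None:
        if len(path) == n:
            return path
        if budget[0] <= 0:
            return None
        budget[0] -= 1
        for w in succ[path[-1]]:
            if w not in used:
                path.append(w)
                used.add(w)
                res = extend(path, used)
                if res is not None:
                    return res
                used.remove(w)
                path.pop()
        return None

    starts = sorted(g.vertices, key=lambda v: (dg.in_degree(v), -dg.out_degree(v)))
    for start in starts:
        res = extend([start], {start})
        if res is not None:
            return res
        if budget[0] <= 0:
            return None
    return None
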