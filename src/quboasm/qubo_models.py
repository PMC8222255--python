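"""QUBO encodings of the Hamiltonian-path problem and Ising conversion.

Two encodings are provided.

Vertex-position encoding (N^2 binary variables x_{v,j}, "vertex v occupies
step j of the path"):

    H = A * sum_v (1 - sum_j x_{v,j})^2          each vertex used once
      + A * sum_j (1 - sum_v x_{v,j})^2          each step holds one vertex
      + A * sum_{(u,v) not in E} sum_j x_{u,j} x_{v,j+1}   forbidden steps

A permutation matrix tracing a Hamiltonian path has energy exactly 0.

Edge-indicator encoding for acyclic graphs (M binary variables x_{u,v},
"edge (u,v) lies on the path"):

    H = A * sum_u (1 - sum_{(u,v) in E} x_{u,v})^2     out-degree penalty
      + A * sum_v (1 - sum_{(u,v) in E} x_{u,v})^2     in-degree penalty

A Hamiltonian path has energy exactly 2A: the sink has no outgoing path
edge and the source no incoming one.  On a DAG the ground energy equals
2A times the minimum path-cover size, so disjoint path covers are
energetically indistinguishable from a single path and must be rejected
at decode time.

QUBO and Ising forms are interchanged via w_i = (sigma_i + 1) / 2, with
constants tracked in the offset so energies agree configuration by
configuration.  Quadratic forms here use a symmetric coefficient matrix Q
with linear terms on the diagonal: energy(x) = x^T Q x + offset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Hashable

import numpy as np

from .olc_graph import OLCGraph, is_acyclic

__all__ = [
    "QUBOProblem",
    "IsingProblem",
    "qubo_vertex_position",
    "qubo_edge_indicator",
    "energy",
    "qubo_to_ising",
    "ising_to_qubo",
    "rescale_for_hardware",
]


@dataclass
class QUBOProblem:
    """Symmetric quadratic form over binary variables.

    ``var_map[i]`` gives the semantic label of variable i: a ``(vertex,
    position)`` pair for the vertex-position encoding or a ``(u, v)`` edge
    for the edge-indicator encoding.
    """

    Q: np.ndarray
    offset: float = 0.0
    A: float = 1.0
    var_map: list[Hashable] = field(default_factory=list)
    encoding: str = "generic"  # vertex_position | edge_indicator | generic

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != self.Q.shape[1]:
            raise ValueError("Q must be a square matrix")
        if not np.allclose(self.Q, self.Q.T):
            raise ValueError("Q must be symmetric")
        if not self.var_map:
            self.var_map = list(range(self.n))

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def energy(self, x: np.ndarray) -> float | np.ndarray:
        return energy(self, x)

    # -- serialisation ----------------------------------------------------
    def to_qbsolv(self, path: str | Path) -> None:
        """qbsolv-style text format: 'p qubo' header, node and coupler
        lines.  Off-diagonal coefficients are written once per unordered
        pair as Q_ij + Q_ji."""
        iu, ju = np.triu_indices(self.n, k=1)
        mask = ~np.isclose(self.Q[iu, ju], 0.0)
        couplers = list(zip(iu[mask], ju[mask]))
        diag = np.diag(self.Q)
        nodes = [i for i in range(self.n) if not np.isclose(diag[i], 0.0)]
        lines = [
            "c quboasm export",
            f"c offset {self.offset!r}",
            f"p qubo 0 {self.n} {len(nodes)} {len(couplers)}",
        ]
        lines += [f"{i} {i} {float(diag[i])!r}" for i in nodes]
        lines += [f"{i} {j} {float(2 * self.Q[i, j])!r}" for i, j in couplers]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_coo_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["i", "j", "value"])
            for i in range(self.n):
                for j in range(i, self.n):
                    if not np.isclose(self.Q[i, j], 0.0):
                        w.writerow([i, j, repr(float(self.Q[i, j]))])

    def var_map_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "encoding": self.encoding,
                    "A": self.A,
                    "offset": self.offset,
                    "variables": [list(v) if isinstance(v, tuple) else v for v in self.var_map],
                },
                indent=2,
            )
            + "\n"
        )


@dataclass
class IsingProblem:
    """Spin problem: energy(sigma) = sum_i h_i sigma_i
    + sum_{i<j} J_ij sigma_i sigma_j + offset, sigma_i in {-1, +1}.

    ``J`` is stored as a full symmetric zero-diagonal matrix holding the
    per-pair coupling in both triangles; the quadratic form is halved
    accordingly when evaluating.
    """

    h: np.ndarray
    J: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (self.h.size, self.h.size):
            raise ValueError("J must be n x n for n = len(h)")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal")

    @property
    def n(self) -> int:
        return self.h.size

    def energy(self, sigma: np.ndarray) -> float | np.ndarray:
        s = np.asarray(sigma, dtype=float)
        single = s.ndim == 1
        s2 = np.atleast_2d(s)
        e = s2 @ self.h + 0.5 * np.einsum("bi,ij,bj->b", s2, self.J, s2) + self.offset
        return float(e[0]) if single else e

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"h": self.h.tolist(), "J": self.J.tolist(), "offset": self.offset},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IsingProblem":
        d = json.loads(Path(path).read_text())
        return cls(h=np.array(d["h"]), J=np.array(d["J"]), offset=d["offset"])


def energy(q: QUBOProblem, x: np.ndarray) -> float | np.ndarray:
    """x^T Q x + offset for one binary vector or a batch (rows)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xs = np.atleast_2d(x)
    if xs.shape[1] != q.n:
        raise ValueError(f"expected {q.n} variables, got {xs.shape[1]}")
    e = np.einsum("bi,ij,bj->b", xs, q.Q, xs) + q.offset
    return float(e[0]) if single else e


def qubo_vertex_position(g: OLCGraph, A: float = 1.0) -> QUBOProblem:
    """Vertex-position Hamiltonian-path QUBO (N^2 variables).

    Variable (v, j) is indexed v*N + j (vertex-major).  The non-edge
    penalty runs over ordered pairs of distinct vertices (u, v) not in E:
    same-vertex pairs are omitted because placing a vertex at consecutive
    steps is already doubly penalised by the uniqueness terms, and the
    redundant couplings only steepen the energy landscape the annealers
    must traverse.  Ground states are identical either way: a permutation
    matrix never occupies one vertex at two steps.
    """
    if A <= 0:
        raise ValueError("penalty coefficient A must be positive")
    N = g.N
    if N < 1:
        raise ValueError("graph must have at least one vertex")
    labels = g.vertices
    n = N * N
    Q = np.zeros((n, n))
    offset = 2.0 * N * A  # constant 1 from each of the N row and N column terms

    def idx(v: int, j: int) -> int:
        return v * N + j

    # (1 - sum_j x_{v,j})^2 and (1 - sum_v x_{v,j})^2, expanded with
    # x^2 = x: -A on the diagonal per term, +2A per unordered pair, split
    # symmetrically (+A in each triangle)
    for v in range(N):
        for j in range(N):
            Q[idx(v, j), idx(v, j)] += -2.0 * A  # -A from row term, -A from column term
            for j2 in range(j + 1, N):
                Q[idx(v, j), idx(v, j2)] += A
                Q[idx(v, j2), idx(v, j)] += A
            for v2 in range(v + 1, N):
                Q[idx(v, j), idx(v2, j)] += A
                Q[idx(v2, j), idx(v, j)] += A
    adj = g.adjacency_matrix()
    for u in range(N):
        for v in range(N):
            if u == v or adj[u, v]:
                continue
            for j in range(N - 1):
                Q[idx(u, j), idx(v, j + 1)] += A / 2.0
                Q[idx(v, j + 1), idx(u, j)] += A / 2.0
    var_map = [(labels[v], j) for v in range(N) for j in range(N)]
    return QUBOProblem(Q=Q, offset=offset, A=A, var_map=var_map, encoding="vertex_position")


def qubo_edge_indicator(g: OLCGraph, A: float = 1.0) -> QUBOProblem:
    """Edge-indicator Hamiltonian-path QUBO for acyclic graphs (M variables).

    Each vertex contributes an out-degree and an in-degree penalty term
    (1 - sum of incident selected edges)^2; vertices with no incident
    edge in a direction contribute the constant A through the offset.
    """
    if A <= 0:
        raise ValueError("penalty coefficient A must be positive")
    acyclic, _ = is_acyclic(g)
    if not acyclic:
        raise ValueError("edge-indicator encoding requires an acyclic graph")
    edges = g.edges
    M = len(edges)
    if M < 1:
        raise ValueError("graph must have at least one edge")
    Q = np.zeros((M, M))
    offset = 0.0
    eidx = {e: i for i, e in enumerate(edges)}
    for vertex in g.vertices:
        for incident in (
            [eidx[(vertex, w)] for w in g.successors(vertex)],
            [eidx[(w, vertex)] for w in g.predecessors(vertex)],
        ):
            # (1 - sum x)^2 = 1 - sum x + 2 sum_{pairs} x x
            offset += A
            for a in incident:
                Q[a, a] += -A
                for b in incident:
                    if b > a:
                        Q[a, b] += A
                        Q[b, a] += A
    return QUBOProblem(Q=Q, offset=offset, A=A, var_map=list(edges), encoding="edge_indicator")


def qubo_to_ising(q: QUBOProblem) -> IsingProblem:
    """Substitute x_i = (sigma_i + 1)/2; energies agree state by state."""
    Q = q.Q
    h = Q.sum(axis=1) / 2.0
    J = Q / 2.0
    J = J - np.diag(np.diag(J))
    offset = q.offset + Q.sum() / 4.0 + np.trace(Q) / 4.0
    return IsingProblem(h=h, J=J, offset=offset)


def ising_to_qubo(p: IsingProblem) -> QUBOProblem:
    """Substitute sigma_i = 2 x_i - 1; inverse of :func:`qubo_to_ising`
    up to offset bookkeeping."""
    # sum_{i<j} J_ij (2x_i-1)(2x_j-1) = sum_{i<j} J_ij (4 x_i x_j - 2x_i - 2x_j + 1)
    J = p.J
    Q = 2.0 * J  # off-diagonal: 4 J_ij split over both triangles
    rowsum = J.sum(axis=1)
    diag = 2.0 * p.h - 2.0 * rowsum  # linear terms on the diagonal
    Q = Q - np.diag(np.diag(Q)) + np.diag(diag)
    offset = p.offset - p.h.sum() + J.sum() / 2.0
    return QUBOProblem(Q=Q, offset=offset, encoding="generic")


def rescale_for_hardware(p: IsingProblem) -> IsingProblem:
    """Scale h and J uniformly into [-1, 1] (hardware input range).

    The whole energy, offset included, is divided by the same factor, so
    the ground-state set is unchanged.  Problems already in range are
    returned as-is.
    """
    scale = max(
        np.max(np.abs(p.h), initial=0.0), np.max(np.abs(p.J), initial=0.0)
    )
    if scale <= 1.0:
        return replace(p, h=p.h.copy(), J=p.J.copy())
    return IsingProblem(h=p.h / scale, J=p.J / scale, offset=p.offset / scale)
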