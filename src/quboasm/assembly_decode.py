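"""Decode solver samples into paths and reconstruct assembled sequences.

A sample from either QUBO encoding is interpreted back into a vertex
order, validated for Hamiltonicity against the source graph, and merged
into a contig by overlap-aware concatenation.  :func:`assemble` runs the
whole pipeline: graph build -> encoding choice -> solve -> decode ->
reconstruct.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .olc_graph import (
    OLCGraph,
    build_olc_graph,
    find_hamiltonian_path,
    is_acyclic,
)
from .qubo_models import (
    QUBOProblem,
    qubo_edge_indicator,
    qubo_vertex_position,
)
from .solvers import (
    BRUTE_FORCE_CAP,
    AnnealResult,
    SimCIMParams,
    brute_force_solve,
    simulated_annealing_solve,
    solve_qubo_simcim,
)
from .synthetic_data import SequenceRecord

__all__ = [
    "PathStatus",
    "PathSolution",
    "decode_vertex_position",
    "decode_edge_indicator",
    "reconstruct_sequence",
    "collapse_circular",
    "encode_path",
    "assemble",
]


class PathStatus(str, enum.Enum):
    HAMILTONIAN = "hamiltonian"
    DISJOINT_PATHS = "disjoint_paths"
    MALFORMED = "malformed"


@dataclass
class PathSolution:
    """Decoded vertex order with validity status and assembled sequence."""

    order: list[str]
    valid: PathStatus
    energy: float
    sequence: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_hamiltonian(self) -> bool:
        return self.valid is PathStatus.HAMILTONIAN

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "order": self.order,
                    "valid": self.valid.value,
                    "energy": self.energy,
                    "sequence": self.sequence,
                    "diagnostics": self.diagnostics,
                },
                indent=2,
                default=str,
            )
            + "\n"
        )


def decode_vertex_position(x: np.ndarray, q: QUBOProblem, g: OLCGraph) -> PathSolution:
    """Read a vertex order from an N x N permutation-matrix sample.

    Malformed when any row or column sum differs from 1; a well-formed
    permutation whose consecutive step uses a non-edge is reported
    malformed too, with the offending steps in the diagnostics.
    """
    if q.encoding != "vertex_position":
        raise ValueError("expected a vertex_position QUBO")
    x = np.asarray(x).reshape(-1)
    N = g.N
    if x.size != N * N:
        raise ValueError(f"expected {N * N} variables, got {x.size}")
    e = float(q.energy(x))
    mat = x.reshape(N, N)
    if not (np.all(mat.sum(axis=0) == 1) and np.all(mat.sum(axis=1) == 1)):
        return PathSolution([], PathStatus.MALFORMED, e, diagnostics={"reason": "not a permutation matrix"})
    labels = g.vertices
    order = [labels[int(np.argmax(mat[:, j]))] for j in range(N)]
    bad_steps = [
        (u, v) for u, v in zip(order, order[1:]) if not g.has_edge(u, v)
    ]
    if bad_steps:
        return PathSolution(
            order, PathStatus.MALFORMED, e, diagnostics={"reason": "non-edge steps", "steps": bad_steps}
        )
    return PathSolution(order, PathStatus.HAMILTONIAN, e)


def decode_edge_indicator(x: np.ndarray, q: QUBOProblem, g: OLCGraph) -> PathSolution:
    """Read the selected-edge subgraph from an M-variable sample.

    Hamiltonian when the selected edges form a single path through every
    vertex; ``disjoint_paths`` when all degrees are <= 1 but the cover
    has more than one component; malformed otherwise (branching).
    """
    if q.encoding != "edge_indicator":
        raise ValueError("expected an edge_indicator QUBO")
    x = np.asarray(x).reshape(-1)
    if x.size != len(q.var_map):
        raise ValueError(f"expected {len(q.var_map)} variables, got {x.size}")
    e = float(q.energy(x))
    selected = [q.var_map[i] for i in range(x.size) if x[i]]
    out_deg: dict[str, int] = {v: 0 for v in g.vertices}
    in_deg: dict[str, int] = {v: 0 for v in g.vertices}
    nxt: dict[str, str] = {}
    for u, v in selected:
        out_deg[u] += 1
        in_deg[v] += 1
        nxt[u] = v
    if any(d > 1 for d in out_deg.values()) or any(d > 1 for d in in_deg.values()):
        return PathSolution([], PathStatus.MALFORMED, e, diagnostics={"reason": "branching vertex"})
    starts = [v for v in g.vertices if in_deg[v] == 0]
    # all degrees <= 1: the cover is a disjoint union of simple paths
    # (cycles are impossible on the acyclic graphs this encoding accepts)
    n_components = len(starts)
    order: list[str] = []
    v = starts[0] if starts else None
    while v is not None:
        order.append(v)
        v = nxt.get(v)
    if n_components == 1 and len(order) == g.N:
        return PathSolution(order, PathStatus.HAMILTONIAN, e)
    return PathSolution(
        order,
        PathStatus.DISJOINT_PATHS,
        e,
        diagnostics={"path_cover_size": n_components},
    )


def reconstruct_sequence(path: PathSolution | Sequence[str], g: OLCGraph) -> str:
    """Merge a Hamiltonian path left to right: append each vertex string
    minus its overlap-length prefix."""
    if isinstance(path, PathSolution):
        if not path.is_hamiltonian:
            raise ValueError(f"cannot reconstruct from a {path.valid.value} path")
        order = path.order
    else:
        order = list(path)
    if not order:
        raise ValueError("empty path")
    seq = g.seq(order[0])
    for u, v in zip(order, order[1:]):
        seq += g.seq(v)[g.overlap(u, v) :]
    return seq


def collapse_circular(contig: str, min_overlap: int) -> str:
    """Trim the terminal self-overlap of a contig assembled from a
    circular genome: when the contig's suffix equals its prefix over at
    least ``min_overlap`` characters, the duplicated wrap is removed."""
    for L in range(len(contig) - 1, min_overlap - 1, -1):
        if contig[:L] == contig[-L:]:
            return contig[: len(contig) - L]
    return contig


def encode_path(order: Sequence[str], q: QUBOProblem, g: OLCGraph) -> np.ndarray:
    """Bit vector representing a vertex order under either encoding."""
    if q.encoding == "vertex_position":
        N = g.N
        labels = {v: i for i, v in enumerate(g.vertices)}
        x = np.zeros(N * N, dtype=np.int8)
        for j, v in enumerate(order):
            x[labels[v] * N + j] = 1
        return x
    if q.encoding == "edge_indicator":
        eidx = {e: i for i, e in enumerate(q.var_map)}
        x = np.zeros(len(q.var_map), dtype=np.int8)
        for u, v in zip(order, order[1:]):
            x[eidx[(u, v)]] = 1
        return x
    raise ValueError(f"unknown encoding {q.encoding!r}")


def _exact_sample(q: QUBOProblem, g: OLCGraph) -> tuple[np.ndarray, AnnealResult | None, str]:
    """Exact route: exhaustive QUBO enumeration when it fits under the
    brute-force cap, otherwise direct backtracking path search encoded
    back into the QUBO variables."""
    if q.n <= BRUTE_FORCE_CAP:
        res = brute_force_solve(q)
        return res.best, res, "brute"
    path = find_hamiltonian_path(g)
    if path is None:
        # no Hamiltonian path: report the empty selection as best effort
        return np.zeros(q.n, dtype=np.int8), None, "path_search"
    return encode_path(path, q, g), None, "path_search"


def assemble(
    fragments: Sequence[SequenceRecord],
    k: int | None = None,
    min_overlap: int | None = None,
    solver: str = "exact",
    A: float = 1.0,
    simcim_params: SimCIMParams | None = None,
    sa_sweeps: int = 200,
    seed: int = 0,
    collapse_duplicates: bool = True,
) -> PathSolution:
    """End-to-end assembly of a fragment set.

    The overlap threshold is ``min_overlap`` or, for k-mer input, k - 1.
    The edge-indicator encoding is used when the overlap graph is
    acyclic (fewer variables), the vertex-position encoding otherwise.
    ``solver`` is "exact" (exhaustive oracle, falling back to direct
    path search above the variable cap), "simcim" or "sa".  Failures are
    reported in the returned status and diagnostics, not raised.
    """
    if min_overlap is None:
        if k is None:
            raise ValueError("provide k or min_overlap")
        min_overlap = k - 1
    g = build_olc_graph(fragments, min_overlap=min_overlap, collapse_duplicates=collapse_duplicates)
    diagnostics: dict = {"N": g.N, "M": g.M, "min_overlap": min_overlap, "solver": solver, "seed": seed}
    if g.M == 0:
        return PathSolution([], PathStatus.MALFORMED, float("nan"), diagnostics={**diagnostics, "reason": "no overlaps between fragments"})
    acyclic, _ = is_acyclic(g)
    if acyclic:
        q = qubo_edge_indicator(g, A=A)
    else:
        q = qubo_vertex_position(g, A=A)
    diagnostics["encoding"] = q.encoding
    diagnostics["n_variables"] = q.n

    if solver == "exact":
        best, res, route = _exact_sample(q, g)
        diagnostics["exact_route"] = route
        if res is not None and res.ground_states is not None:
            # how many distinct ground configurations (candidate paths) exist
            diagnostics["n_ground_states"] = int(len(res.ground_states))
    elif solver == "simcim":
        params = simcim_params or SimCIMParams(seed=seed)
        res = solve_qubo_simcim(q, params)
        best = res.best
        diagnostics["best_energy"] = res.best_energy
        diagnostics["n_runs"] = res.n_runs
    elif solver == "sa":
        res = simulated_annealing_solve(q, sweeps=sa_sweeps, seed=seed)
        best = res.best
        diagnostics["best_energy"] = res.best_energy
        diagnostics["n_runs"] = res.n_runs
    else:
        raise ValueError(f"unknown solver {solver!r}")

    if q.encoding == "edge_indicator":
        sol = decode_edge_indicator(best, q, g)
    else:
        sol = decode_vertex_position(best, q, g)
    sol.diagnostics = {**diagnostics, **sol.diagnostics}
    if sol.is_hamiltonian:
        sol.sequence = reconstruct_sequence(sol, g)
    return sol
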