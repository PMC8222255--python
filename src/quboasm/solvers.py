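"""QUBO/Ising solvers and hardware-topology modelling.

Three minimisers share the :class:`AnnealResult` contract:

* :func:`simcim_solve` — SimCIM, a quantum-inspired annealer that evolves
  continuous spin amplitudes s_i in [-1, 1] by mean-field gradients plus
  Gaussian noise under a pump ramp, then discretises by sign;
* :func:`brute_force_solve` — exhaustive enumeration, the exact oracle
  (hard-capped at 24 variables);
* :func:`simulated_annealing_solve` — single-flip Metropolis with
  geometric cooling, the classical baseline.

The hardware model covers the Chimera topology (an m x m grid of K4,4
unit cells, max qubit degree 6) and a deterministic triangular clique
embedding that represents each logical variable by a chain of
ferromagnetically tied physical qubits.

SimCIM sign convention: each iteration computes the mean field

    Phi_i = sum_{j != i} C_ij s_j + b_i,

then updates s_i <- phi(s_i + p_t s_i + zeta Phi_i + N(0, sigma)) with
phi clipping to [-1, 1].  The dynamics align each spin with its mean
field, so to *minimise* an Ising energy h.sigma + sum J sigma sigma the
gain matrix and bias are the negated problem coefficients: C = -J,
b = -h.  :func:`simcim_solve` applies that negation internally;
:func:`simcim_step` takes (C, b) literally.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

from .qubo_models import IsingProblem, QUBOProblem, qubo_to_ising

__all__ = [
    "SimCIMParams",
    "SimCIMState",
    "AnnealResult",
    "ChimeraGraph",
    "Embedding",
    "linear_pump",
    "tanh_pump",
    "simcim_step",
    "simcim_solve",
    "solve_qubo_simcim",
    "brute_force_solve",
    "simulated_annealing_solve",
    "chimera_graph",
    "embed_clique",
    "embed_ising",
    "unembed_samples",
]

BRUTE_FORCE_CAP = 24


# ---------------------------------------------------------------------------
# Result container


@dataclass
class AnnealResult:
    """Batch of sampled configurations with energies.

    ``samples`` rows are spin (+-1) or binary (0/1) vectors depending on
    ``kind``; ``energies`` are recomputed from the samples by the solver
    that produced them.  ``n_ground_hits`` is filled when the ground
    energy is known (brute force knows it; stochastic solvers accept it
    via ``ground_energy``).
    """

    samples: np.ndarray
    energies: np.ndarray
    kind: str  # "spin" | "binary"
    n_runs: int
    n_ground_hits: int | None = None
    ground_energy: float | None = None
    ground_states: np.ndarray | None = None
    solver: str = ""
    seed: int | None = None
    wall_time_s: float = 0.0

    @property
    def best_energy(self) -> float:
        return float(np.min(self.energies))

    @property
    def best(self) -> np.ndarray:
        return self.samples[int(np.argmin(self.energies))]

    def count_ground_hits(self, ground_energy: float, atol: float = 1e-9) -> int:
        """Count samples attaining the given ground energy and store it."""
        hits = int(np.sum(self.energies <= ground_energy + atol))
        self.ground_energy = float(ground_energy)
        self.n_ground_hits = hits
        return hits

    def to_dict(self) -> dict:
        """JSON-ready summary with run-length-encoded samples."""
        flat = self.samples.astype(int).reshape(self.n_runs, -1)
        rle = []
        for row in flat:
            vals, runs = [], []
            for v in row:
                if vals and vals[-1] == int(v):
                    runs[-1] += 1
                else:
                    vals.append(int(v))
                    runs.append(1)
            rle.append([vals, runs])
        return {
            "solver": self.solver,
            "kind": self.kind,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "energies": [float(e) for e in self.energies],
            "best_energy": self.best_energy,
            "n_ground_hits": self.n_ground_hits,
            "ground_energy": self.ground_energy,
            "samples_rle": rle,
            "wall_time_s": self.wall_time_s,
        }


# ---------------------------------------------------------------------------
# SimCIM


def linear_pump(p_start: float = -1.0, p_end: float = 1.0) -> Callable[[int, int], float]:
    """Pump ramp p_t rising linearly from p_start to p_end."""

    def schedule(t: int, iterations: int) -> float:
        frac = t / max(iterations - 1, 1)
        return p_start + (p_end - p_start) * frac

    return schedule


def tanh_pump(p_start: float = -1.0, p_end: float = 1.0, sharpness: float = 3.0) -> Callable[[int, int], float]:
    """Pump ramp following a tanh profile between the same endpoints."""

    def schedule(t: int, iterations: int) -> float:
        frac = t / max(iterations - 1, 1)
        w = (math.tanh(sharpness * (2 * frac - 1)) / math.tanh(sharpness) + 1) / 2
        return p_start + (p_end - p_start) * w

    return schedule


@dataclass
class SimCIMParams:
    """Annealing control parameters for SimCIM.

    ``pump_schedule`` maps (iteration t, total iterations) to p_t; the
    default is a linear ramp from -0.5 to 0, which together with the
    relatively large noise scale keeps the dynamics in a
    thermal-annealing-like regime where trajectories can leave the local
    minima of penalty QUBOs before the pump freezes them out.
    """

    iterations: int = 24000
    batch: int = 100
    zeta: float = 0.5
    noise_sigma: float = 0.4
    pump_schedule: Callable[[int, int], float] = field(
        default_factory=lambda: linear_pump(-0.5, 0.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SimCIMState:
    """Continuous spin amplitudes with the latest mean field."""

    s: np.ndarray
    Phi: np.ndarray | None = None


def simcim_step(
    state: SimCIMState,
    coupling: np.ndarray,
    bias: np.ndarray,
    p_t: float,
    params: SimCIMParams,
    rng: np.random.Generator | None = None,
) -> SimCIMState:
    """One SimCIM update on a state (or batch of states).

    Computes Phi_i = sum_{j != i} coupling_ij s_j + bias_i, the gradient
    ds_i = p_t s_i + zeta Phi_i + N(0, sigma), and applies the clipping
    activation.  With zero coupling, bias, pump and noise the map is the
    identity.
    """
    s = np.asarray(state.s, dtype=float)
    Phi = s @ coupling + bias
    ds = p_t * s + params.zeta * Phi
    if params.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        ds = ds + rng.normal(0.0, params.noise_sigma, size=s.shape)
    s_new = np.clip(s + ds, -1.0, 1.0)
    return SimCIMState(s=s_new, Phi=Phi)


def simcim_solve(problem: IsingProblem, params: SimCIMParams | None = None) -> AnnealResult:
    """Run a batch of SimCIM anneals on an Ising problem.

    Each attempt starts from s = 0 (noise breaks the symmetry), runs
    ``iterations`` steps, and reads out sigma_i = sign(s_i) with ties
    mapped to +1.
    """
    params = params or SimCIMParams()
    rng = np.random.default_rng(params.seed)
    n = problem.n
    coupling = -problem.J  # align-with-mean-field dynamics minimise the energy
    bias = -problem.h
    t0 = time.perf_counter()
    state = SimCIMState(s=np.zeros((params.batch, n)))
    for t in range(params.iterations):
        p_t = params.pump_schedule(t, params.iterations)
        state = simcim_step(state, coupling, bias, p_t, params, rng)
    sigma = np.where(state.s >= 0, 1, -1).astype(np.int8)
    energies = problem.energy(sigma)
    return AnnealResult(
        samples=sigma,
        energies=np.asarray(energies, dtype=float),
        kind="spin",
        n_runs=params.batch,
        solver="simcim",
        seed=params.seed,
        wall_time_s=time.perf_counter() - t0,
    )


def solve_qubo_simcim(q: QUBOProblem, params: SimCIMParams | None = None) -> AnnealResult:
    """SimCIM on a QUBO: convert to Ising, anneal, map samples back to
    binary and report QUBO energies."""
    ising = qubo_to_ising(q)
    res = simcim_solve(ising, params)
    x = ((res.samples + 1) // 2).astype(np.int8)
    energies = np.asarray(q.energy(x), dtype=float)
    return AnnealResult(
        samples=x,
        energies=energies,
        kind="binary",
        n_runs=res.n_runs,
        solver="simcim",
        seed=res.seed,
        wall_time_s=res.wall_time_s,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle


def _binary_states(n: int, lo: int, hi: int) -> np.ndarray:
    """Rows lo..hi-1 of the 2^n x n binary state table."""
    ints = np.arange(lo, hi, dtype=np.int64)
    return ((ints[:, None] >> np.arange(n)) & 1).astype(np.int8)


def brute_force_solve(q: QUBOProblem, chunk: int = 1 << 18) -> AnnealResult:
    """Exact ground energy and all ground states by full enumeration.

    Capped at 24 variables; a 0-variable problem returns its offset.
    """
    n = q.n
    if n > BRUTE_FORCE_CAP:
        raise ValueError(f"brute force capped at {BRUTE_FORCE_CAP} variables, got {n}")
    t0 = time.perf_counter()
    if n == 0:
        empty = np.zeros((1, 0), dtype=np.int8)
        e = np.array([q.offset], dtype=float)
        return AnnealResult(
            samples=empty, energies=e, kind="binary", n_runs=1, n_ground_hits=1,
            ground_energy=float(q.offset), ground_states=empty, solver="brute",
            wall_time_s=time.perf_counter() - t0,
        )
    best = np.inf
    ground: list[np.ndarray] = []
    total = 1 << n
    for lo in range(0, total, chunk):
        X = _binary_states(n, lo, min(lo + chunk, total))
        e = np.einsum("bi,ij,bj->b", X, q.Q, X) + q.offset
        emin = e.min()
        if emin < best - 1e-12:
            best = emin
            ground = [X[np.isclose(e, emin, atol=1e-9)]]
        elif np.isclose(emin, best, atol=1e-9):
            ground.append(X[np.isclose(e, best, atol=1e-9)])
    states = np.vstack(ground)
    return AnnealResult(
        samples=states,
        energies=np.full(len(states), best, dtype=float),
        kind="binary",
        n_runs=1,
        n_ground_hits=1,  # deterministic: every run finds the ground state
        ground_energy=float(best),
        ground_states=states,
        solver="brute",
        wall_time_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# Simulated-annealing baseline


def simulated_annealing_solve(
    q: QUBOProblem,
    sweeps: int = 200,
    t_start: float = 2.0,
    t_end: float = 0.01,
    n_restarts: int = 100,
    seed: int = 0,
) -> AnnealResult:
    """Single-flip Metropolis with geometric cooling, batched restarts.

    Each restart draws a random initial state; one sweep proposes n
    single-bit flips.  Returns the best-so-far state per restart, whose
    energy is non-increasing over sweeps by construction.  ``sweeps=0``
    returns the random initial states unchanged.
    """
    rng = np.random.default_rng(seed)
    n = q.n
    t0 = time.perf_counter()
    X = rng.integers(0, 2, size=(n_restarts, n)).astype(np.int8)
    E = np.asarray(q.energy(X), dtype=float)
    bestX, bestE = X.copy(), E.copy()
    if sweeps > 0 and n > 0:
        temps = t_start * (t_end / t_start) ** (np.arange(sweeps) / max(sweeps - 1, 1))
        rows = np.arange(n_restarts)
        Q2 = 2.0 * q.Q
        for T in temps:
            for _ in range(n):
                i = rng.integers(0, n, size=n_restarts)
                # dE for flipping bit i: (1-2x_i) * (Q_ii + 2 sum_{j!=i} Q_ij x_j)
                xi = X[rows, i]
                interact = np.einsum("bj,bj->b", X.astype(float), Q2[i]) - Q2[rows * 0 + i, i] * xi
                dE = (1 - 2 * xi) * (np.diag(q.Q)[i] + interact)
                accept = (dE <= 0) | (rng.random(n_restarts) < np.exp(-np.clip(dE, 0, 700) / T))
                X[rows[accept], i[accept]] ^= 1
                E[accept] += dE[accept]
            improved = E < bestE
            bestE[improved] = E[improved]
            bestX[improved] = X[improved]
    return AnnealResult(
        samples=bestX,
        energies=bestE,
        kind="binary",
        n_runs=n_restarts,
        solver="sa",
        seed=seed,
        wall_time_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# Chimera topology and clique embedding


@dataclass
class ChimeraGraph:
    """Chimera C_m: an m x m grid of 8-qubit K4,4 unit cells.

    Qubits are labelled (row, col, side, k) with side 0 the vertical
    half and side 1 the horizontal half of the cell, k in 0..3.  In-cell
    couplers connect every side-0 qubit to every side-1 qubit; side-0
    qubits couple to the same position in the cell above/below, side-1 to
    the cell left/right.  Closed forms: 8 m^2 qubits and
    16 m^2 + 8 m (m - 1) couplers; max degree 6.
    """

    m: int
    graph: nx.Graph

    @property
    def n_qubits(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_couplers(self) -> int:
        return self.graph.number_of_edges()

    @property
    def clique_capacity(self) -> int:
        """Largest clique the triangular embedding scheme supports."""
        return 4 * self.m


def chimera_graph(m: int) -> ChimeraGraph:
    """Build the Chimera C_m topology graph."""
    if m < 1:
        raise ValueError("m must be >= 1")
    g = nx.Graph()
    for i in range(m):
        for j in range(m):
            for k in range(4):
                for k2 in range(4):
                    g.add_edge((i, j, 0, k), (i, j, 1, k2))
            if i + 1 < m:
                for k in range(4):
                    g.add_edge((i, j, 0, k), (i + 1, j, 0, k))
            if j + 1 < m:
                for k in range(4):
                    g.add_edge((i, j, 1, k), (i, j + 1, 1, k))
    return ChimeraGraph(m=m, graph=g)


@dataclass
class Embedding:
    """Minor embedding: disjoint connected chains of physical qubits per
    logical variable, plus one chosen physical coupler per logical pair."""

    chains: dict[int, list[tuple]]
    chain_strength: float
    coupler_map: dict[tuple[int, int], tuple[tuple, tuple]] = field(default_factory=dict)

    @property
    def n_logical(self) -> int:
        return len(self.chains)

    def qubit_index(self) -> dict[tuple, int]:
        """Dense physical-qubit indexing in chain order."""
        out: dict[tuple, int] = {}
        for i in sorted(self.chains):
            for qb in self.chains[i]:
                out[qb] = len(out)
        return out


def _triangular_chain(t: int, r: int, m: int) -> list[tuple]:
    """L-shaped chain for logical variable 4t + r on C_m: the vertical
    qubits of column t in rows 0..t joined at the diagonal cell to the
    horizontal qubits of row t in columns t..m-1."""
    vert = [(row, t, 0, r) for row in range(t + 1)]
    horiz = [(t, col, 1, r) for col in range(t, m)]
    return vert + horiz


def embed_clique(n_logical: int, target: ChimeraGraph, chain_strength: float = 1.0) -> Embedding:
    """Deterministic triangular clique embedding of K_n into Chimera.

    Logical variable i = 4t + r occupies an L-shaped chain meeting every
    other chain in exactly one unit cell, where an in-cell K4,4 coupler
    realises the logical coupling.  Chains are pruned to the contiguous
    span actually used by couplings, so small cliques get short chains.
    Capacity is 4m; exceeding it raises with the maximum embeddable size.
    """
    if n_logical < 1:
        raise ValueError("n_logical must be >= 1")
    if chain_strength <= 0:
        raise ValueError("chain_strength must be positive")
    m = target.m
    if n_logical > 4 * m:
        raise ValueError(
            f"clique capacity of C_{m} is {4 * m} logical variables, "
            f"requested {n_logical}"
        )
    full_chains = {i: _triangular_chain(i // 4, i % 4, m) for i in range(n_logical)}
    coupler_map: dict[tuple[int, int], tuple[tuple, tuple]] = {}
    used: dict[int, set[int]] = {i: set() for i in range(n_logical)}
    for i in range(n_logical):
        ti, ri = i // 4, i % 4
        for j in range(i + 1, n_logical):
            tj, rj = j // 4, j % 4
            # chains i and j intersect in cell (min(t), max(t)); i's qubit
            # there is horizontal iff its diagonal index is the smaller one
            if ti == tj:
                qi = (ti, ti, 0, ri)
                qj = (tj, tj, 1, rj)
            elif ti < tj:
                qi = (ti, tj, 1, ri)  # horizontal run of chain i
                qj = (ti, tj, 0, rj)  # vertical run of chain j
            else:
                qi = (tj, ti, 0, ri)
                qj = (tj, ti, 1, rj)
            if not target.graph.has_edge(qi, qj):  # pragma: no cover - scheme guarantee
                raise RuntimeError(f"no physical coupler between {qi} and {qj}")
            coupler_map[(i, j)] = (qi, qj)
            used[i].add(full_chains[i].index(qi))
            used[j].add(full_chains[j].index(qj))
    chains: dict[int, list[tuple]] = {}
    for i, chain in full_chains.items():
        if used[i]:
            lo, hi = min(used[i]), max(used[i])
            chains[i] = chain[lo : hi + 1]
        else:
            chains[i] = chain[:1]
    return Embedding(chains=chains, chain_strength=chain_strength, coupler_map=coupler_map)


def embed_ising(p: IsingProblem, embedding: Embedding, target: ChimeraGraph) -> tuple[IsingProblem, dict[tuple, int]]:
    """Map a logical Ising problem onto physical qubits.

    Each logical field h_i is spread evenly over the qubits of chain i;
    each logical coupling J_ij sits on the chosen physical coupler; chain
    edges get a ferromagnetic coupling of -chain_strength so aligned
    chains are energetically favoured.  The returned offset compensates
    the chain couplings, so chain-consistent physical states have exactly
    the logical energy.
    """
    if p.n != embedding.n_logical:
        raise ValueError("embedding size does not match problem size")
    qidx = embedding.qubit_index()
    nq = len(qidx)
    h = np.zeros(nq)
    J = np.zeros((nq, nq))
    n_chain_edges = 0
    for i, chain in embedding.chains.items():
        share = p.h[i] / len(chain)
        for qb in chain:
            h[qidx[qb]] += share
        for qa, qb in zip(chain, chain[1:]):
            if not target.graph.has_edge(qa, qb):  # pragma: no cover
                raise RuntimeError(f"chain edge {qa}-{qb} missing from topology")
            a, b = qidx[qa], qidx[qb]
            J[a, b] += -embedding.chain_strength
            J[b, a] += -embedding.chain_strength
            n_chain_edges += 1
    for (i, j), (qa, qb) in embedding.coupler_map.items():
        if abs(p.J[i, j]) > 0:
            a, b = qidx[qa], qidx[qb]
            J[a, b] += p.J[i, j]
            J[b, a] += p.J[i, j]
    # aligned chains contribute -chain_strength per chain edge; cancel it
    offset = p.offset + embedding.chain_strength * n_chain_edges
    return IsingProblem(h=h, J=J, offset=offset), qidx


def unembed_samples(
    samples: np.ndarray, embedding: Embedding, qidx: dict[tuple, int]
) -> tuple[np.ndarray, int]:
    """Map physical spin samples back to logical ones.

    Samples with any broken chain (qubits of one chain disagreeing) are
    discarded, not majority-voted; the count of discarded samples is
    returned alongside the surviving logical samples.
    """
    samples = np.atleast_2d(samples)
    logical_vars = sorted(embedding.chains)
    out = []
    broken = 0
    for row in samples:
        spins = []
        ok = True
        for i in logical_vars:
            vals = {int(row[qidx[qb]]) for qb in embedding.chains[i]}
            if len(vals) != 1:
                ok = False
                break
            spins.append(vals.pop())
        if ok:
            out.append(spins)
        else:
            broken += 1
    if out:
        return np.array(out, dtype=np.int8), broken
    return np.zeros((0, len(logical_vars)), dtype=np.int8), broken
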