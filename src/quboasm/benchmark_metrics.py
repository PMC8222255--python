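"""Solver figures of merit: success probability, R99 and time-to-solution.

For a stochastic solver with per-run success probability theta, the
number of runs needed to see the ground state at least once with 99%
confidence follows from the binomial distribution:

    R99 = log(1 - 0.99) / log(1 - theta),

clamped to 1 for theta >= 0.99 (runs are integers >= 1) and infinite for
theta = 0.  Time-to-solution is TTS = t_a * R99 with t_a the per-run
annealing time in microseconds.  theta is estimated as the empirical
ground-hit fraction over runs, with a Wilson score interval reported
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .qubo_models import QUBOProblem, qubo_edge_indicator, qubo_vertex_position
from .olc_graph import build_olc_graph, is_acyclic
from .solvers import (
    BRUTE_FORCE_CAP,
    SimCIMParams,
    brute_force_solve,
    simulated_annealing_solve,
    solve_qubo_simcim,
)
from .synthetic_data import SyntheticProblemSet

__all__ = [
    "BenchmarkRecord",
    "r99",
    "tts",
    "wilson_interval",
    "benchmark_suite",
    "summarize_by_length",
    "plot_tts",
]


def r99(theta: float) -> float:
    """Runs to reach the ground state at least once with probability 0.99."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    if theta == 0.0:
        return math.inf
    if theta >= 0.99:
        return 1.0
    return math.log(1.0 - 0.99) / math.log(1.0 - theta)


def tts(theta: float, t_a: float) -> float:
    """Time-to-solution in the units of t_a (per-run annealing time)."""
    if t_a <= 0:
        raise ValueError(f"t_a must be positive, got {t_a}")
    return t_a * r99(theta)


def wilson_interval(hits: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = hits / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass
class BenchmarkRecord:
    """One (problem, solver) benchmark row."""

    problem_id: str
    sequence_length: int
    solver: str
    n_variables: int
    encoding: str
    n_runs: int
    n_ground_hits: int
    theta: float
    theta_lo: float
    theta_hi: float
    r99: float
    t_a_us: float
    tts_us: float
    ground_energy: float
    best_energy: float


def _problem_qubo(problem, A: float = 1.0) -> tuple[QUBOProblem, object]:
    g = build_olc_graph(list(problem.reads), min_overlap=problem.k - 1)
    acyclic, _ = is_acyclic(g)
    q = qubo_edge_indicator(g, A=A) if acyclic else qubo_vertex_position(g, A=A)
    return q, g


def benchmark_suite(
    problems: SyntheticProblemSet,
    solvers: Iterable[str] = ("simcim", "sa", "brute"),
    n_runs: int = 100,
    seed: int = 0,
    t_a_us: Mapping[str, float] | None = None,
    simcim_params: SimCIMParams | None = None,
    sa_sweeps: int = 200,
    A: float = 1.0,
) -> pd.DataFrame:
    """Benchmark each solver on each problem of a synthetic set.

    Ground energies come from the exhaustive oracle; problems whose QUBO
    exceeds the oracle cap are excluded with a notice column in the
    returned frame's ``attrs``.  ``t_a_us`` optionally fixes the nominal
    per-run time per solver (microseconds); otherwise the measured
    wall-clock per attempt is used.  The brute-force oracle is
    deterministic: theta = 1 by definition.
    """
    t_a_us = dict(t_a_us or {})
    records: list[BenchmarkRecord] = []
    skipped: list[str] = []
    for pi, problem in enumerate(problems.problems):
        q, _g = _problem_qubo(problem, A=A)
        if q.n > BRUTE_FORCE_CAP:
            skipped.append(problem.source.id)
            continue
        oracle = brute_force_solve(q)
        ground = oracle.ground_energy
        for solver in solvers:
            run_seed = seed + 7919 * pi  # distinct, reproducible per problem
            if solver == "brute":
                res = oracle
                hits, runs = 1, 1
                wall_per_run = oracle.wall_time_s
            elif solver == "simcim":
                params = simcim_params or SimCIMParams()
                params = SimCIMParams(
                    iterations=params.iterations,
                    batch=n_runs,
                    zeta=params.zeta,
                    noise_sigma=params.noise_sigma,
                    pump_schedule=params.pump_schedule,
                    seed=run_seed,
                )
                res = solve_qubo_simcim(q, params)
                hits = res.count_ground_hits(ground)
                runs = res.n_runs
                wall_per_run = res.wall_time_s / runs
            elif solver == "sa":
                res = simulated_annealing_solve(q, sweeps=sa_sweeps, n_restarts=n_runs, seed=run_seed)
                hits = res.count_ground_hits(ground)
                runs = res.n_runs
                wall_per_run = res.wall_time_s / runs
            else:
                raise ValueError(f"unknown solver {solver!r}")
            theta = hits / runs
            lo, hi = wilson_interval(hits, runs)
            t_a = t_a_us.get(solver, wall_per_run * 1e6)
            records.append(
                BenchmarkRecord(
                    problem_id=problem.source.id,
                    sequence_length=len(problem.source),
                    solver=solver,
                    n_variables=q.n,
                    encoding=q.encoding,
                    n_runs=runs,
                    n_ground_hits=hits,
                    theta=theta,
                    theta_lo=lo,
                    theta_hi=hi,
                    r99=r99(theta),
                    t_a_us=t_a,
                    tts_us=tts(theta, t_a),
                    ground_energy=float(ground),
                    best_energy=res.best_energy,
                )
            )
    df = pd.DataFrame([asdict(r) for r in records])
    df.attrs["skipped_oracle_infeasible"] = skipped
    return df


def plot_tts(df: pd.DataFrame, path: str, log_scale: bool = True) -> None:
    """Mean TTS versus sequence length per solver (SVG/PNG by extension).

    Requires matplotlib (the ``plot`` extra); infinite TTS rows are
    dropped with the count noted in the legend.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for solver, grp in df.groupby("solver"):
        finite = grp[np.isfinite(grp["tts_us"])]
        dropped = len(grp) - len(finite)
        agg = finite.groupby("sequence_length")["tts_us"].mean()
        label = solver if not dropped else f"{solver} ({dropped} unsolved dropped)"
        ax.plot(agg.index, agg.values, marker="o", label=label)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("sequence length (nt)")
    ax.set_ylabel("TTS (µs)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def summarize_by_length(df: pd.DataFrame, column: str = "tts_us") -> pd.DataFrame:
    """Per (solver, sequence length) summary: mean, min, max and 90th
    percentile over problem instances."""
    finite = df[np.isfinite(df[column])]
    out = (
        finite.groupby(["solver", "sequence_length"])[column]
        .agg(
            mean="mean",
            min="min",
            max="max",
            p90=lambda s: float(np.percentile(s, 90)),
            n="count",
        )
        .reset_index()
    )
    return out
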