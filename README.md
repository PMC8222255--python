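# quboasm

A toy *de novo* genome assembler that solves the read-ordering problem the
way annealing hardware does: by minimising a quadratic unconstrained binary
optimisation (QUBO) problem.

In overlap–layout–consensus (OLC) assembly, every read (or k-mer) is a
vertex of a directed graph and an edge u → v records an exact suffix–prefix
overlap.  A Hamiltonian path — a path visiting every vertex exactly once —
orders the fragments into the genome.  `quboasm` encodes that path problem
as a QUBO, minimises it with a quantum-inspired annealer (SimCIM), a
classical simulated-annealing baseline or an exhaustive oracle, decodes the
best sample back into a fragment order, and merges the overlaps into a
contig.  It also models the hardware side of the story: the Chimera qubit
topology of a 2048-qubit annealer and the deterministic clique embedding
that maps logical variables onto chains of physical qubits.

The package is aimed at people studying annealing formulations of
combinatorial bioinformatics problems.  It is deliberately small-scale:
error-free fragments, exact overlaps, graphs of tens of vertices.

## The encodings

For a directed overlap graph G = (V, E) with N = |V| and M = |E|:

**Vertex–position encoding** (N² binary variables, works on any graph).
x_{v,j} = 1 means vertex v is the j-th step of the path:

    H = A Σ_v (1 − Σ_j x_{v,j})²        each vertex appears once
      + A Σ_j (1 − Σ_v x_{v,j})²        each step holds one vertex
      + A Σ_{(u,v)∉E, u≠v} Σ_j x_{u,j} x_{v,j+1}    non-edge steps forbidden

A permutation matrix tracing a Hamiltonian path has energy exactly 0.

**Edge-indicator encoding** (M binary variables, acyclic graphs only).
x_{u,v} = 1 means edge (u, v) lies on the path:

    H = A Σ_u (1 − Σ_{(u,v)∈E} x_{u,v})² + A Σ_v (1 − Σ_{(u,v)∈E} x_{u,v})²

A Hamiltonian path has energy exactly 2A (the source misses an incoming
edge and the sink an outgoing one); more generally the ground energy is
2A × (minimum path-cover size), so decoding must reject disjoint covers.

QUBO and Ising forms are interchanged by w = (σ + 1)/2.  SimCIM evolves
continuous spin amplitudes s_i ∈ [−1, 1] by

    Δs_i = p_t s_i + ζ Φ_i + N(0, σ),    Φ_i = Σ_{j≠i} C_ij s_j + b_i,

clips after every step and reads out σ_i = sign(s_i).  Solver quality is
summarised by the per-run success probability θ, the 99%-confidence
run count R99 = log(0.01)/log(1 − θ), and the time-to-solution
TTS = t_a · R99.

## Worked example

Assemble the 3-mers of `ATGCA` from the shell:

```
$ python -c "from quboasm.synthetic_data import *; \
    write_fasta([SequenceRecord(f'k{i}', s) for i, s in enumerate(kmerize('ATGCA', 3))], 'kmers.fasta')"
$ quboasm assemble kmers.fasta --solver exact -o asm
hamiltonian path found; contig length 5
```

The JSON report (`asm.report.json`) shows what happened:

```json
{
  "order": ["ATG", "TGC", "GCA"],
  "valid": "hamiltonian",
  "energy": 2.0,
  "sequence": "ATGCA",
  "diagnostics": { "N": 3, "M": 2, "encoding": "edge_indicator",
                   "n_variables": 2, "exact_route": "brute",
                   "n_ground_states": 1 }
}
```

The overlap graph of the three 3-mers is acyclic, so the compact
edge-indicator encoding was chosen (2 variables instead of 9); the ground
energy 2.0 is exactly 2A for A = 1, certifying a Hamiltonian path; the
unique ground state decodes to the order ATG → TGC → GCA, which merges,
two overlapping characters at a time, back into `ATGCA`.

The same pipeline is available in Python:

```python
from quboasm import SequenceRecord, assemble, kmerize

reads = [SequenceRecord(f"k{i}", s) for i, s in enumerate(kmerize("ATGCA", 3))]
sol = assemble(reads, k=3, solver="simcim", seed=17)
print(sol.valid.value, sol.sequence)   # hamiltonian ATGCA
```

Benchmarking solvers on a freshly generated synthetic problem set
(10 screened random sequences per length, fragmented into 3-mers):

```
$ quboasm benchmark --lengths 5,6 --per-length 2 --solvers simcim,sa,brute \
      --runs 50 --seed 1 -o bench.csv
solver  sequence_length      mean  min       max       p90  n
 brute                5 20.000000 20.0 20.000000 20.000000  2
    sa                5 20.000000 20.0 20.000000 20.000000  2
simcim                5 21.771838 20.0 23.543676 23.189309  2
...
```

Each row summarises TTS in microseconds (at the nominal 20 µs per run)
over the problem instances of one sequence length: a TTS of 20 means every
run hit the ground state (θ = 1, R99 = 1); SimCIM's 23.5 on one length-5
instance means θ ≈ 0.98 there, so R99 ≈ 1.18 runs are needed for 99%
confidence.

Other subcommands expose the intermediate stages: `generate` (screened
synthetic problem sets as FASTA + manifest), `build-graph` (TSV/CSV/DOT
exports of the overlap graph), `build-qubo` (qbsolv-style `.qubo`, COO CSV
and Ising JSON), `solve` (any solver on an exported QUBO).

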