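# Methods

## Problem model

`quboasm` treats *de novo* assembly in its classical overlap–layout–
consensus form.  Fragments (reads, or the k-mers of a read) are vertices
of a directed graph; an edge u → v exists when the suffix of u's string
matches the prefix of v's string exactly over at least `min_overlap`
characters, and carries the longest such match length.  Containment (one
fragment inside another) yields no edge — a contained fragment adds no
ordering information — and is reported as a warning.  Because all inputs
here are error-free, exact matching is the faithful overlap model; there
is no alignment scoring, no reverse-complement handling, and no repeat
resolution.  Reconstructing the genome means finding a Hamiltonian path
and merging each consecutive pair minus its overlap.

## QUBO encodings

Two penalty Hamiltonians encode the Hamiltonian-path problem over binary
variables; both are pure constraint penalties (there is no objective
term), so the penalty weight A > 0 only scales the spectrum and every
A gives the same minimisers.  A is kept explicit (default 1) because the
hardware-range rescaling step interacts with it.

* **Vertex–position** (N² variables x_{v,j}, any graph): row- and
  column-uniqueness squares plus a penalty A for every ordered pair of
  *distinct* non-adjacent vertices occupying consecutive steps.  Energy 0
  is attained exactly by permutation matrices tracing a path along edges.
  The same-vertex pairs (v at step j and j+1) admitted by a fully literal
  reading of the non-edge sum are omitted: such configurations are
  already penalised twice by the uniqueness terms, the ground-state set
  is provably identical, and the redundant couplings measurably flatten
  annealer success rates.  Quadratic expansion is symbolic — linear terms
  on the diagonal, pair couplings split symmetrically, constants tracked
  in an offset — so reported energies equal the Hamiltonian literally.
* **Edge-indicator** (M variables x_{u,v}, acyclic graphs only; cyclic
  input is rejected): per-vertex out-degree and in-degree squares.  On a
  DAG the ground energy equals 2A × (minimum path-cover size); a
  Hamiltonian path exists iff that is 2A.  The encoding cannot
  distinguish a single path from a disjoint cover of the same size
  energetically, so the decoder, not the energy, rejects disjoint covers
  (reported with their cover size).

Variable order is reproducible: (v, j) ↦ v·N + j for the vertex–position
form, lexicographic edge order for the edge-indicator form.  QUBO ↔ Ising
conversion substitutes w = (σ + 1)/2 with offsets absorbing constants, so
energies agree configuration by configuration; `rescale_for_hardware`
divides h, J (and the offset, preserving argmins) uniformly when any
coefficient exceeds the hardware input range [−1, 1].

## Solvers

**Exhaustive oracle.**  Vectorised enumeration of all 2ⁿ assignments,
hard-capped at 24 variables; returns the exact ground energy and *all*
ground states.  It anchors every benchmark (θ is defined against its
ground energy) and the encoding-equivalence tests.

**SimCIM.**  Each spin is a continuous amplitude s_i ∈ [−1, 1], started
at 0.  One iteration computes the mean field Φ_i = Σ_{j≠i} C_ij s_j + b_i,
the increment Δs_i = p_t s_i + ζ Φ_i + N(0, σ), and clips s_i + Δs_i to
[−1, 1]; after the last iteration σ_i = sign(s_i), ties mapped to +1.
To minimise an Ising energy h·σ + Σ_{i<j} J_ij σ_i σ_j the gain matrix
and bias are the negated coefficients (C = −J, b = −h), i.e. the update
follows the anti-gradient.  The pump p_t is configurable (linear or tanh
ramp); defaults are a linear ramp from −0.5 to 0 over 24 000 iterations
with ζ = 0.5 and σ = 0.4, batch 100.  These values were chosen by
deliberate engineering against the package's own study problem class
(penalty QUBOs of 2–64 variables): the large noise scale keeps the
dynamics in a thermal-annealing-like regime able to leave the dense
low-lying local minima of the vertex–position form (single-violation
states sit only A above a sometimes unique ground state), and ending the
pump at 0 keeps the mean field relevant until readout instead of freezing
early trajectories at the rails.  Small-ζ, small-σ, fast-ramp settings
converge an order of magnitude faster but drop the per-attempt
ground-state rate on 16–25-variable instances from ≳0.9 to as low as
0.15.  Seeds are mandatory; identical seeds give identical samples.

**Simulated annealing.**  Single-flip Metropolis with geometric cooling
(defaults: 200 sweeps, T from 2.0 to 0.01), batched restarts, incremental
ΔE updates.  Zero sweeps returns the random initial states; the reported
per-restart state is best-so-far, hence non-increasing in energy.

**Exact assembly route.**  `assemble(..., solver="exact")` uses the
exhaustive oracle when the encoding fits under the 24-variable cap.
Cyclic graphs of 5+ vertices exceed it (N² ≥ 25), so the exact route
falls back to direct backtracking path search on the graph (successors
tried longest-overlap-first, low-in-degree start vertices first, node
budget 5·10⁶), and encodes the found path back into the QUBO variables.
Both routes are exact for deciding Hamiltonicity.

## Hardware model

The Chimera topology C_m is an m × m grid of 8-qubit K4,4 unit cells:
side-0 ("vertical") qubits couple to the same position in the cells above
and below, side-1 ("horizontal") qubits to the cells left and right.
Closed forms: 8m² qubits, 16m² + 8m(m−1) couplers, degree ≤ 6; C16 gives
2048 qubits and 6016 couplers.  The deterministic triangular clique
embedding assigns logical variable i = 4t + r an L-shaped chain (column t
up to the diagonal, row t rightwards), so any two chains meet in exactly
one unit cell where a K4,4 coupler realises their logical coupling;
capacity is 4m logical variables, and chains are pruned to the span their
couplings actually use.  Embedding a problem spreads h_i evenly over the
chain, places J_ij on the chosen physical coupler, and ties chain
neighbours ferromagnetically at −chain_strength (default 2 × max |J|),
with the offset compensated so chain-consistent states keep the logical
energy.  Samples with broken chains are discarded and counted, not
majority-voted.

## Benchmark metrics

θ is the empirical fraction of runs attaining the oracle ground energy
(a Wilson 95% interval is reported alongside).  R99 = log(0.01)/log(1−θ):
the number of runs needed to see the ground state at least once with 99%
probability; θ = 0 gives ∞ and θ ≥ 0.99 is clamped to 1 because runs are
integers.  TTS = t_a · R99 with t_a the per-run time in microseconds —
measured wall clock by default, overridable with a nominal value (the CLI
defaults to a nominal 20 µs) so that tables are hardware-independent and
reruns byte-identical.  Summaries report mean, min, max and the 90th
percentile over the instances of each sequence length.

## Synthetic data

The generator emulates two study designs.  (1) Short random sequences
(lengths 5–10, uniform i.i.d. nucleotides, 10 retained per length, k = 3)
fragmented into k-mers: a candidate is retained only if its k-mer
multiset is duplicate-free (which guarantees a Hamiltonian path through
the k-mer graph by construction), its overlap graph is not a bare chain
(edge count N−1 means nothing to optimise), and its sorted k-mer list is
new (graph de-duplication).  Sampling retries up to 1000 candidates per
length and reports a flagged partial set on exhaustion.  (2) Error-free
fixed-length reads from a reference (50 reads of 600 bp in the
phage-scale benchmark) at uniform random start positions, forward strand
only, with optional wrap-around on circular references; contigs from
circular references are trimmed by the terminal prefix/suffix
self-overlap.  What the generator does *not* emulate — sequencing errors,
strand ambiguity, repeats, non-uniform coverage, contaminants — bounds
what passing tests show: they certify the encodings, solvers and decoding
on clean instances, not robustness to real sequencing artefacts.

## Numerical choices and degenerate inputs

Energy comparisons use an absolute tolerance of 1e-9 (all study energies
are integer multiples of A).  Sign readout ties (s_i = 0) go to +1.
Fragments that are all identical collapse to a degenerate single-vertex
graph (warned); graphs with no overlaps at all fail assembly with an
explicit status rather than an exception; a 0-variable QUBO returns its
offset.  Multiple Hamiltonian paths are legitimate degeneracies: the
decoder reports the path of the best sample plus the count of distinct
ground states seen, and the round-trip guarantee is correspondingly
conditional — the reconstruction equals the source sequence exactly when
the path is unique, otherwise it matches its length and k-mer multiset.

## Known limitations

Exhaustive components (oracle, partitioning, path enumeration) are toy
scale by design.  The single-edge-cut partitioner searches recursively
over all candidate cut edges rather than reimplementing a graph
partitioning library.  SimCIM is CPU/NumPy batched; no GPU path.  The
edge-indicator encoding is undefined on cyclic graphs, which therefore
always pay the N² variable cost.  Wall-clock-based TTS values depend on
the host and are never asserted in tests.
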