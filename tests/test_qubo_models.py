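"""QUBO encodings: hand-derived energies, exhaustive invariants, transforms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quboasm import (
    IsingProblem,
    QUBOProblem,
    build_olc_graph,
    energy,
    ising_to_qubo,
    qubo_edge_indicator,
    qubo_to_ising,
    qubo_vertex_position,
    rescale_for_hardware,
    SequenceRecord,
)
from quboasm.assembly_decode import encode_path
from quboasm.solvers import _binary_states


def frags(*seqs):
    return [SequenceRecord(f"f{i}", s) for i, s in enumerate(seqs)]


class TestVertexPositionEncoding:
    def test_hand_derived_energies(self, chain3):
        A = 1.0
        q = qubo_vertex_position(chain3, A=A)
        assert q.n == 9  # N^2 variables
        valid = encode_path(["ATG", "TGC", "GCA"], q, chain3)
        assert q.energy(valid) == pytest.approx(0.0)
        # empty assignment: each of 3 rows and 3 columns contributes A
        assert q.energy(np.zeros(9)) == pytest.approx(6 * A)
        # order (a, c, b): two non-edge steps
        bad = encode_path(["ATG", "GCA", "TGC"], q, chain3)
        assert q.energy(bad) == pytest.approx(2 * A)

    def test_penalty_scales_linearly_and_argmin_invariant(self, chain3):
        q1 = qubo_vertex_position(chain3, A=1.0)
        q5 = qubo_vertex_position(chain3, A=5.0)
        X = _binary_states(9, 0, 2**9)
        e1 = np.asarray(q1.energy(X))
        e5 = np.asarray(q5.energy(X))
        np.testing.assert_allclose(e5, 5.0 * e1, atol=1e-9)
        np.testing.assert_array_equal(e1 == e1.min(), e5 == e5.min())

    def test_zero_energy_iff_hamiltonian_permutation(self):
        """Exhaustive over all digraphs on 3 vertices and all 2^9 states:
        the encoding vanishes exactly on permutation matrices tracing a
        path along graph edges."""
        X = _binary_states(9, 0, 2**9)
        pairs = [(u, v) for u in range(3) for v in range(3) if u != v]
        for mask in range(2 ** len(pairs)):
            edges = [p for i, p in enumerate(pairs) if mask >> i & 1]
            g = _abstract_graph(3, edges)
            q = qubo_vertex_position(g, A=1.0)
            e = np.asarray(q.energy(X))
            zero_states = X[np.isclose(e, 0.0)]
            expected = {
                tuple(encode_path([f"v{i}" for i in perm], q, g))
                for perm in itertools.permutations(range(3))
                if all((a, b) in edges for a, b in zip(perm, perm[1:]))
            }
            assert {tuple(row) for row in zero_states} == expected


def _abstract_graph(n, edges):
    from quboasm.olc_graph import OLCGraph

    g = OLCGraph()
    for i in range(n):
        g.add_vertex(f"v{i}", "A")
    for u, v in edges:
        g.add_edge(f"v{u}", f"v{v}", 1)
    return g


class TestEdgeIndicatorEncoding:
    def test_hand_derived_energies(self, chain3):
        A = 1.0
        q = qubo_edge_indicator(chain3, A=A)
        assert q.n == 2  # M variables
        assert q.energy(np.ones(2)) == pytest.approx(2 * A)  # source + sink terms
        assert q.energy(np.zeros(2)) == pytest.approx(6 * A)  # all six vertex terms

    def test_branching_vertex_contributes_quadratic_penalty(self):
        # a -> b, a -> c: selecting both outgoing edges costs (1-2)^2 = 1
        g = _abstract_graph(3, [(0, 1), (0, 2)])
        q = qubo_edge_indicator(g, A=1.0)
        both = np.ones(2)
        # a: (1-2)^2=1; b,c incoming satisfied; b,c outgoing miss (1 each);
        # a incoming misses (1)
        assert q.energy(both) == pytest.approx(1 + 1 + 1 + 1)

    def test_cyclic_graph_rejected(self):
        g = build_olc_graph(frags("ATA", "TAT"), min_overlap=2)
        with pytest.raises(ValueError, match="acyclic"):
            qubo_edge_indicator(g)

    def test_hamiltonian_selection_is_ground_at_2A(self, chain3):
        from quboasm.solvers import brute_force_solve

        q = qubo_edge_indicator(chain3, A=1.0)
        res = brute_force_solve(q)
        assert res.ground_energy == pytest.approx(2.0)
        np.testing.assert_array_equal(res.ground_states, [[1, 1]])


class TestEnergyEvaluation:
    def test_trivial_forms(self):
        q = QUBOProblem(Q=np.zeros((3, 3)))
        assert energy(q, np.array([1, 0, 1])) == 0.0
        q = QUBOProblem(Q=np.eye(4))
        assert energy(q, np.ones(4)) == 4.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        Q = rng.normal(size=(n, n))
        Q = (Q + Q.T) / 2
        off = float(rng.normal())
        q = QUBOProblem(Q=Q, offset=off)
        x = rng.integers(0, 2, size=n)
        expected = off + sum(Q[i, j] * x[i] * x[j] for i in range(n) for j in range(n))
        assert energy(q, x) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            energy(QUBOProblem(Q=np.eye(2)), np.ones(3))


class TestQuboIsingTransform:
    def test_spin_binary_correspondence(self):
        # sigma = +1 <-> w = 1 and sigma = -1 <-> w = 0 by construction
        q = QUBOProblem(Q=np.array([[3.0]]))
        p = qubo_to_ising(q)
        assert p.h[0] == pytest.approx(1.5)
        assert p.offset == pytest.approx(1.5)
        assert p.energy(np.array([1])) == pytest.approx(q.energy(np.array([1])))
        assert p.energy(np.array([-1])) == pytest.approx(q.energy(np.array([0])))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_energies_agree_on_all_states(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        Q = rng.normal(size=(n, n))
        q = QUBOProblem(Q=(Q + Q.T) / 2, offset=float(rng.normal()))
        p = qubo_to_ising(q)
        X = _binary_states(n, 0, 2**n)
        np.testing.assert_allclose(q.energy(X), p.energy(2 * X - 1), atol=1e-8)
        # round trip preserves energies as well
        q2 = ising_to_qubo(p)
        np.testing.assert_allclose(q.energy(X), q2.energy(X), atol=1e-8)

    def test_round_trip_structure(self):
        p = IsingProblem(h=np.array([0.5, -1.0]), J=np.array([[0, 0.3], [0.3, 0]]), offset=2.0)
        p2 = qubo_to_ising(ising_to_qubo(p))
        np.testing.assert_allclose(p.h, p2.h, atol=1e-12)
        np.testing.assert_allclose(p.J, p2.J, atol=1e-12)
        assert p.offset == pytest.approx(p2.offset)


class TestHardwareRescaling:
    def test_divides_by_max_coefficient(self):
        p = IsingProblem(h=np.array([2.0, -4.0]), J=np.zeros((2, 2)))
        scaled = rescale_for_hardware(p)
        np.testing.assert_allclose(scaled.h, [0.5, -1.0])

    def test_in_range_problem_unchanged(self):
        p = IsingProblem(h=np.array([0.5]), J=np.zeros((1, 1)), offset=1.0)
        scaled = rescale_for_hardware(p)
        np.testing.assert_allclose(scaled.h, p.h)
        assert scaled.offset == p.offset

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_ground_states_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        J = rng.normal(scale=3, size=(n, n))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0.0)
        p = IsingProblem(h=rng.normal(scale=3, size=n), J=J)
        scaled = rescale_for_hardware(p)
        S = 2 * _binary_states(n, 0, 2**n) - 1
        e0 = np.asarray(p.energy(S))
        e1 = np.asarray(scaled.energy(S))
        np.testing.assert_array_equal(e0 == e0.min(), e1 == e1.min())
        assert max(np.abs(scaled.h).max(initial=0), np.abs(scaled.J).max(initial=0)) <= 1 + 1e-12


class TestSerialisation:
    def test_qbsolv_and_coo_export(self, chain3, tmp_path):
        q = qubo_edge_indicator(chain3)
        q.to_qbsolv(tmp_path / "p.qubo")
        text = (tmp_path / "p.qubo").read_text()
        assert "p qubo" in text
        q.to_coo_csv(tmp_path / "p.csv")
        q.var_map_json(tmp_path / "p.json")
        ising = qubo_to_ising(q)
        ising.to_json(tmp_path / "p.ising.json")
        back = IsingProblem.from_json(tmp_path / "p.ising.json")
        np.testing.assert_allclose(back.h, ising.h)
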