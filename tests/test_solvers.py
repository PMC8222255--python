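"""SimCIM dynamics, oracle and baseline solvers, Chimera model, embedding."""

import numpy as np
import pytest

from quboasm import (
    IsingProblem,
    QUBOProblem,
    SimCIMParams,
    brute_force_solve,
    chimera_graph,
    embed_clique,
    embed_ising,
    ising_to_qubo,
    qubo_edge_indicator,
    qubo_vertex_position,
    simcim_solve,
    simcim_step,
    simulated_annealing_solve,
    solve_qubo_simcim,
    unembed_samples,
)
from quboasm.solvers import SimCIMState, linear_pump, tanh_pump
from quboasm.assembly_decode import encode_path


class TestSimCIMStep:
    def test_zero_dynamics_is_identity(self):
        params = SimCIMParams(noise_sigma=0.0)
        s0 = np.array([0.3, -0.7])
        state = simcim_step(SimCIMState(s=s0.copy()), np.zeros((2, 2)), np.zeros(2), 0.0, params)
        np.testing.assert_allclose(state.s, s0)

    def test_activation_clips_to_unit_interval(self):
        # s = 0.9 with gradient 0.5 saturates at the +1 rail
        params = SimCIMParams(noise_sigma=0.0, zeta=1.0)
        state = simcim_step(
            SimCIMState(s=np.array([0.9])), np.zeros((1, 1)), np.array([0.5]), 0.0, params
        )
        assert state.s[0] == pytest.approx(1.0)

    def test_mean_field_single_coupling(self):
        # literal mean field: Phi_1 = C_12 s_2, Phi_2 = C_12 s_1
        C = np.array([[0.0, -1.0], [-1.0, 0.0]])
        s = np.array([0.4, -0.2])
        params = SimCIMParams(noise_sigma=0.0, zeta=1.0)
        state = simcim_step(SimCIMState(s=s.copy()), C, np.zeros(2), 0.0, params)
        np.testing.assert_allclose(state.Phi, [-s[1], -s[0]])

    def test_clipping_invariant_through_a_whole_anneal(self):
        """|s_i| <= 1 after every one of the iterations, on a batch."""
        rng = np.random.default_rng(3)
        n = 6
        J = rng.normal(size=(n, n))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0)
        params = SimCIMParams(iterations=300, batch=16, seed=3)
        state = SimCIMState(s=np.zeros((params.batch, n)))
        step_rng = np.random.default_rng(params.seed)
        for t in range(params.iterations):
            p_t = params.pump_schedule(t, params.iterations)
            state = simcim_step(state, -J, np.zeros(n), p_t, params, step_rng)
            assert np.max(np.abs(state.s)) <= 1.0 + 1e-12


class TestSimCIMSolve:
    def test_single_spin_field_recovered(self):
        # E = -sigma: ground state sigma = +1
        p = IsingProblem(h=np.array([-1.0]), J=np.zeros((1, 1)))
        res = simcim_solve(p, SimCIMParams(batch=100, seed=2))
        assert np.mean(res.samples[:, 0] == 1) >= 0.99

    def test_two_spin_ferromagnet_aligned(self):
        J = np.array([[0.0, -1.0], [-1.0, 0.0]])
        p = IsingProblem(h=np.zeros(2), J=J)
        res = simcim_solve(p, SimCIMParams(batch=50, seed=4))
        assert tuple(res.best) in {(1, 1), (-1, -1)}
        assert res.best_energy == pytest.approx(-1.0)

    def test_finds_ground_state_of_path_qubo(self, chain3):
        q = qubo_vertex_position(chain3)
        res = solve_qubo_simcim(q, SimCIMParams(batch=50, seed=5))
        assert res.best_energy == pytest.approx(0.0)
        assert res.kind == "binary"

    def test_seed_determinism(self):
        p = IsingProblem(h=np.array([0.3, -0.2]), J=np.array([[0, 0.5], [0.5, 0]]))
        r1 = simcim_solve(p, SimCIMParams(iterations=500, batch=8, seed=9))
        r2 = simcim_solve(p, SimCIMParams(iterations=500, batch=8, seed=9))
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_pump_schedules_cover_endpoints(self):
        lin = linear_pump(-1, 1)
        assert lin(0, 100) == pytest.approx(-1)
        assert lin(99, 100) == pytest.approx(1)
        th = tanh_pump(-1, 1)
        assert th(0, 100) == pytest.approx(-1)
        assert th(99, 100) == pytest.approx(1)


class TestBruteForce:
    def test_vertex_position_chain_ground(self, chain3):
        q = qubo_vertex_position(chain3)
        res = brute_force_solve(q)
        assert res.ground_energy == pytest.approx(0.0)
        expected = encode_path(["ATG", "TGC", "GCA"], q, chain3)
        np.testing.assert_array_equal(res.ground_states, [expected])

    def test_zero_variable_problem_returns_offset(self):
        res = brute_force_solve(QUBOProblem(Q=np.zeros((0, 0)), offset=3.5))
        assert res.ground_energy == pytest.approx(3.5)

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="capped"):
            brute_force_solve(QUBOProblem(Q=np.zeros((25, 25))))

    def test_theta_is_one_by_definition(self, chain3):
        res = brute_force_solve(qubo_edge_indicator(chain3))
        assert res.n_ground_hits == res.n_runs == 1


class TestSimulatedAnnealing:
    def test_zero_sweeps_returns_initial_states(self, chain3):
        q = qubo_vertex_position(chain3)
        res = simulated_annealing_solve(q, sweeps=0, n_restarts=10, seed=1)
        assert res.n_runs == 10
        np.testing.assert_allclose(np.asarray(q.energy(res.samples)), res.energies)

    def test_reaches_ground_on_chain(self, chain3):
        q = qubo_vertex_position(chain3)
        res = simulated_annealing_solve(q, sweeps=200, n_restarts=20, seed=1)
        assert res.best_energy == pytest.approx(0.0)

    def test_best_so_far_never_worse_than_start(self, chain3):
        q = qubo_vertex_position(chain3)
        start = simulated_annealing_solve(q, sweeps=0, n_restarts=30, seed=8)
        end = simulated_annealing_solve(q, sweeps=100, n_restarts=30, seed=8)
        assert np.all(end.energies <= start.energies + 1e-9)


class TestChimera:
    @pytest.mark.parametrize("m,qubits,couplers", [(1, 8, 16), (2, 32, 80), (16, 2048, 6016)])
    def test_known_sizes(self, m, qubits, couplers):
        c = chimera_graph(m)
        assert c.n_qubits == qubits
        assert c.n_couplers == couplers

    @pytest.mark.parametrize("m", range(1, 17))
    def test_closed_forms_and_degree_bound(self, m):
        c = chimera_graph(m)
        assert c.n_qubits == 8 * m * m
        assert c.n_couplers == 16 * m * m + 8 * m * (m - 1)
        assert max(d for _, d in c.graph.degree) <= 6


class TestCliqueEmbedding:
    def test_single_variable_single_qubit(self):
        emb = embed_clique(1, chimera_graph(3))
        assert len(emb.chains) == 1
        assert len(emb.chains[0]) == 1

    def test_k4_in_one_cell(self):
        target = chimera_graph(1)
        emb = embed_clique(4, target, chain_strength=2.0)
        all_qubits = [qb for ch in emb.chains.values() for qb in ch]
        assert len(all_qubits) == len(set(all_qubits))  # disjoint chains
        # every one of the 6 logical pairs realised by a physical coupler
        assert len(emb.coupler_map) == 6
        for qa, qb in emb.coupler_map.values():
            assert target.graph.has_edge(qa, qb)

    def test_chains_are_connected_subgraphs(self):
        target = chimera_graph(3)
        emb = embed_clique(10, target)
        import networkx as nx

        for chain in emb.chains.values():
            assert nx.is_connected(target.graph.subgraph(chain))

    def test_capacity_error_reports_maximum(self):
        with pytest.raises(ValueError, match="capacity .* is 4"):
            embed_clique(5, chimera_graph(1))

    def test_embedding_round_trip_preserves_ground_state(self):
        """Brute force over the physical qubits of an embedded two-spin
        ferromagnet: chain-consistent minima map back to the logical
        ground states."""
        logical = IsingProblem(h=np.zeros(2), J=np.array([[0, -1.0], [-1.0, 0]]))
        target = chimera_graph(1)
        emb = embed_clique(2, target, chain_strength=2.0)
        physical, qidx = embed_ising(logical, emb, target)
        res = brute_force_solve(ising_to_qubo(physical))
        spins = 2 * res.ground_states - 1
        unembedded, broken = unembed_samples(spins, emb, qidx)
        assert broken == 0
        logical_ground = {(1, 1), (-1, -1)}
        assert {tuple(r) for r in unembedded} <= logical_ground
        for row in unembedded:
            assert logical.energy(row) == pytest.approx(-1.0)

    def test_broken_chains_discarded_and_counted(self):
        # 5 logical variables on C_2 force at least one multi-qubit chain
        emb = embed_clique(5, chimera_graph(2), chain_strength=2.0)
        qidx = emb.qubit_index()
        good = np.ones(len(qidx), dtype=np.int8)
        bad = good.copy()
        chain = next(c for c in emb.chains.values() if len(c) > 1)
        bad[qidx[chain[0]]] = -1  # break one chain
        out, broken = unembed_samples(np.vstack([good, bad]), emb, qidx)
        assert len(out) == 1 and broken == 1
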