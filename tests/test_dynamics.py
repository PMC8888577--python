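import numpy as np
import pytest

from conftest import brute_force_can_change, make_state
from coordgames.dynamics import (
    DegenerateGameError,
    SimulationConfig,
    accumulate_payoff,
    br_update,
    coordination_rate,
    initialize_state,
    interface_density,
    is_frozen,
    rd_phi,
    rd_update,
    run_simulation,
    ui_update,
)
from coordgames.games import GCGParams, PayoffMatrix, pcg_matrix
from coordgames.networks import Network, complete_graph, random_regular_graph

PCG = pcg_matrix()


class TestInitialization:
    def test_coordinated_pair_payoffs(self, pair_net):
        st = make_state(pair_net, PCG, "AA")
        assert st.payoffs.tolist() == [1.0, 1.0]

    def test_discoordinated_pair_payoffs(self, pair_net):
        # both nodes of a mismatched pair earn the same (zero) payoff
        st = make_state(pair_net, PCG, "AB")
        assert st.payoffs.tolist() == [0.0, 0.0]

    def test_isolated_node_zero_payoff(self):
        net = Network.from_edges(3, [(0, 1)])
        st = make_state(net, PCG, "AAB")
        assert st.payoffs[2] == 0.0

    def test_wrong_length_rejected(self, pair_net):
        cfg = SimulationConfig(rule="BR", initial_strategies=[0, 1, 0])
        with pytest.raises(ValueError):
            initialize_state(pair_net, PCG, cfg)

    def test_random_init_balanced(self):
        net = random_regular_graph(2000, 4, seed=0)
        st = initialize_state(net, PCG, SimulationConfig(rule="RD", seed=5))
        assert abs(coordination_rate(st) - 0.5) < 0.05


class TestAccumulatePayoff:
    def test_three_matching_neighbours(self):
        net = Network.from_edges(4, [(0, 1), (0, 2), (0, 3)])
        st = make_state(net, PCG, "AAAA")
        assert accumulate_payoff(st, net, PCG, 0) == 3.0

    def test_gcg_mixed_neighbourhood(self):
        # B focal with 2 A- and 2 B-neighbours earns 2T in the GCG
        g = GCGParams(S=-2.0, T=0.4)
        net = Network.from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        st = make_state(net, g, "BAABB")
        assert accumulate_payoff(st, net, g, 0) == pytest.approx(2 * 0.4)

    def test_does_not_modify_state(self):
        net = Network.from_edges(2, [(0, 1)])
        st = make_state(net, PCG, "AB")
        before = st.payoffs.copy()
        accumulate_payoff(st, net, PCG, 0)
        assert np.array_equal(st.payoffs, before)


class TestRdPhi:
    def test_pcg_regular(self):
        assert rd_phi(PCG, random_regular_graph(50, 4, seed=0)) == 4.0

    def test_gcg_regular(self):
        assert rd_phi(GCGParams(S=-3, T=-1), random_regular_graph(48, 8, seed=0)) == 32.0

    def test_complete(self):
        assert rd_phi(PCG, complete_graph(100)) == 99.0

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateGameError):
            rd_phi(PayoffMatrix(1, 1, 1, 1), complete_graph(3))


class TestRdUpdate:
    def test_equal_payoff_pair_never_changes(self, pair_net):
        st = make_state(pair_net, PCG, "AB")
        for _ in range(200):
            assert not rd_update(st, pair_net, PCG, 0)
        assert st.strategies.tolist() == [0, 1]

    def test_adoption_probability_matches_payoff_gap(self):
        # focal refreshed payoff 0, neighbour stored payoff 2, phi = 4:
        # imitation fires with probability 1/2
        net = Network.from_edges(5, [(0, 1), (1, 2), (1, 3), (1, 4)])
        adopted = 0
        trials = 2000
        for t in range(trials):
            st = make_state(net, PCG, "ABBBB", rng_seed=t)
            st.payoffs[1] = 2.0
            if rd_update(st, net, PCG, 0):
                adopted += 1
        p = adopted / trials
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / trials)

    def test_no_adoption_when_neighbour_not_better(self, pair_net):
        st = make_state(pair_net, PCG, "AB")
        st.payoffs[1] = -1.0
        assert not rd_update(st, pair_net, PCG, 0)


class TestBrUpdate:
    def test_pair_coordinates(self, pair_net):
        st = make_state(pair_net, PCG, "AB")
        assert br_update(st, pair_net, PCG, 0)
        assert st.strategies[0] == 1

    def test_majority_followed(self):
        net = Network.from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        st = make_state(net, PCG, "BAAAB")
        assert br_update(st, net, PCG, 0)
        assert st.strategies[0] == 0

    def test_tie_broken_at_random(self):
        # 2 A / 2 B neighbours on the PCG: both outcomes occur ~equally
        net = Network.from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        outcomes = []
        for t in range(400):
            st = make_state(net, PCG, "AAABB", rng_seed=t)
            br_update(st, net, PCG, 0)
            outcomes.append(int(st.strategies[0]))
        frac_b = np.mean(outcomes)
        assert 0.4 < frac_b < 0.6

    def test_stored_payoff_becomes_chosen_payoff(self, pair_net):
        st = make_state(pair_net, PCG, "AB")
        br_update(st, pair_net, PCG, 0)
        assert st.payoffs[0] == 1.0  # realised payoff of the adopted strategy


class TestUiUpdate:
    def test_equal_payoff_pair_frozen(self, pair_net):
        st = make_state(pair_net, PCG, "AB")
        assert not ui_update(st, pair_net, PCG, 0)
        assert is_frozen(st, pair_net, PCG, "UI")

    def test_copies_best_neighbour(self, path3_net):
        st = make_state(path3_net, PCG, "ABB")
        st.payoffs[1] = 5.0
        assert ui_update(st, path3_net, PCG, 0)
        assert st.strategies[0] == 1

    def test_equal_payoff_no_copy(self, path3_net):
        # best neighbour's stored payoff equals the focal's refreshed
        # payoff: strictly-larger is required, so no imitation
        st = make_state(path3_net, PCG, "AAB")
        st.payoffs[1] = 1.0
        assert not ui_update(st, path3_net, PCG, 0)
        assert st.strategies[0] == 0


class TestFrozen:
    @pytest.mark.parametrize("rule", ["RD", "BR", "UI"])
    def test_uniform_state_frozen(self, rule):
        net = random_regular_graph(20, 3, seed=0)
        st = make_state(net, PCG, "A" * 20)
        assert is_frozen(st, net, PCG, rule)

    def test_pair_frozen_under_ui_not_br(self, pair_net):
        st = make_state(pair_net, PCG, "AB")
        assert is_frozen(st, pair_net, PCG, "UI")
        assert is_frozen(st, pair_net, PCG, "RD")
        assert not is_frozen(st, pair_net, PCG, "BR")

    @pytest.mark.parametrize("rule", ["RD", "BR", "UI"])
    def test_matches_brute_force_oracle(self, rule):
        # consistent states on small random graphs: the kernel's verdict
        # equals direct enumeration of single-activation outcomes
        rng = np.random.default_rng(123)
        games = [PCG, GCGParams(S=-2, T=-1).to_matrix(), GCGParams(S=-0.5, T=0.4).to_matrix()]
        checked = 0
        for trial in range(150):
            N = int(rng.integers(2, 9))
            p = rng.uniform(0.2, 0.9)
            edges = [
                (i, j) for i in range(N) for j in range(i + 1, N) if rng.random() < p
            ]
            if not edges:
                continue
            net = Network.from_edges(N, edges)
            m = games[trial % len(games)]
            strat = rng.integers(0, 2, size=N)
            st = make_state(net, m, strat)
            assert is_frozen(st, net, m, rule) == (not brute_force_can_change(st, net, m, rule))
            checked += 1
        assert checked > 100


class TestRunSimulation:
    def test_uniform_initial_state_freezes_immediately(self):
        net = random_regular_graph(30, 4, seed=1)
        cfg = SimulationConfig(rule="RD", seed=0, initial_strategies=[0] * 30)
        rec = run_simulation(net, PCG, cfg)
        assert rec.tau == 0 and rec.frozen
        assert rec.final_alpha == 1.0 and rec.rho_series[-1] == 0.0

    def test_pair_matching_br_always_coordinates(self):
        for seed in range(10):
            net = random_regular_graph(100, 1, seed=seed)
            rec = run_simulation(net, PCG, SimulationConfig(rule="BR", seed=seed))
            assert rec.frozen and rec.rho_series[-1] == 0.0

    def test_pair_matching_rd_keeps_half_interfaces(self):
        rhos = []
        for seed in range(100):
            net = random_regular_graph(50, 1, seed=seed)
            rec = run_simulation(net, PCG, SimulationConfig(rule="RD", seed=seed))
            assert rec.frozen
            rhos.append(rec.rho_series[-1])
        assert abs(np.mean(rhos) - 0.5) < 0.05

    def test_reproducible_from_seed(self):
        net = random_regular_graph(100, 4, seed=3)
        cfg = SimulationConfig(rule="UI", seed=99, record_every=1)
        a = run_simulation(net, PCG, cfg)
        b = run_simulation(net, PCG, cfg)
        assert np.array_equal(a.alpha_series, b.alpha_series)
        assert np.array_equal(a.final_state.strategies, b.final_state.strategies)
        assert a.tau == b.tau

    def test_cap_reached_marks_not_frozen(self):
        net = random_regular_graph(200, 4, seed=4)
        rec = run_simulation(net, PCG, SimulationConfig(rule="RD", seed=1, max_mc_steps=2))
        if not rec.frozen:
            assert rec.tau == 2

    def test_alpha_series_steps_are_quantised(self):
        net = random_regular_graph(60, 4, seed=5)
        rec = run_simulation(
            net, PCG, SimulationConfig(rule="RD", seed=2, record_every=1, max_mc_steps=500)
        )
        counts = rec.alpha_series * 60
        assert np.allclose(counts, np.round(counts))
        assert np.all((rec.rho_series >= 0) & (rec.rho_series <= 1))

    def test_trajectory_serialization(self, tmp_path):
        net = random_regular_graph(40, 4, seed=6)
        rec = run_simulation(net, PCG, SimulationConfig(rule="BR", seed=3, record_every=1))
        rec.save(tmp_path / "traj")
        import json

        lines = (tmp_path / "traj.csv").read_text().strip().splitlines()
        assert lines[0] == "mc_step,alpha,rho"
        sidecar = json.loads((tmp_path / "traj.json").read_text())
        assert sidecar["tau"] == rec.tau and sidecar["rule"] == "BR"


class TestObservables:
    def test_coordination_rate(self):
        net = Network.from_edges(10, [(0, 1)])
        st = make_state(net, PCG, "AAAAABBBBB")
        assert coordination_rate(st) == 0.5

    def test_interface_density_alternating_cycle(self):
        net = Network.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        st = make_state(net, PCG, "ABAB")
        assert interface_density(st, net) == 1.0

    def test_interface_density_uniform(self):
        net = Network.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        st = make_state(net, PCG, "AAAA")
        assert interface_density(st, net) == 0.0

    def test_no_edges_undefined(self):
        net = Network.from_edges(3, [])
        st = make_state(net, PCG, "AAB")
        with pytest.raises(ValueError):
            interface_density(st, net)

    def test_random_strategies_give_half_density(self):
        net = random_regular_graph(1000, 8, seed=7)
        st = initialize_state(net, PCG, SimulationConfig(rule="RD", seed=8))
        assert abs(interface_density(st, net) - 0.5) < 0.03
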