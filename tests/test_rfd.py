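import math

import numpy as np
import pytest

import swarmrec as sr
from swarmrec.rfd import IsolatedNodeError, MissingEdgeError

from conftest import random_environment


def two_node_env() -> sr.REnvironment:
    return sr.REnvironment(adjacency={"s": {"g": 1.0}, "g": {}},
                           goal="g", source="s")


def fork_env() -> sr.REnvironment:
    """One decision node with four neighbors matching the worked example:
    downhill gradients {3, 1}, one flat, one uphill gradient -2."""
    env = sr.REnvironment(
        adjacency={"i": {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0},
                   "a": {}, "b": {}, "c": {}, "d": {}, "g": {}},
        goal="g")
    env.altitude = {"i": 10.0, "a": 7.0, "b": 9.0, "c": 10.0, "d": 12.0,
                    "g": 0.0}
    return env


class TestGradient:
    def test_worked_example(self):
        env = sr.REnvironment(adjacency={"x": {"y": 2.0}, "y": {}, "g": {}},
                              goal="g")
        env.altitude = {"x": 10.0, "y": 4.0, "g": 0.0}
        assert sr.gradient(env, "x", "y") == pytest.approx(3.0)

    def test_equal_altitudes_zero(self):
        env = sr.REnvironment(adjacency={"x": {"y": 5.0}, "y": {}, "g": {}},
                              goal="g")
        env.altitude = {"x": 7.0, "y": 7.0, "g": 0.0}
        assert sr.gradient(env, "x", "y") == 0.0

    def test_antisymmetry_unit_distance(self):
        env = sr.REnvironment(
            adjacency={"x": {"y": 1.0}, "y": {"x": 1.0}, "g": {}}, goal="g")
        env.altitude = {"x": 12.0, "y": 5.0, "g": 0.0}
        assert sr.gradient(env, "x", "y") == -sr.gradient(env, "y", "x")

    def test_missing_edge(self):
        env = sr.REnvironment(adjacency={"x": {}, "g": {}}, goal="g")
        env.altitude = {"x": 1.0, "g": 0.0}
        with pytest.raises(MissingEdgeError):
            sr.gradient(env, "x", "g")


class TestTransitionProbabilities:
    def test_worked_example(self):
        part = sr.transition_probabilities(
            fork_env(), "i", sr.RFDParams(omega=0.5, delta=1.0))
        assert part.total == pytest.approx(5.25)
        p = part.probabilities
        assert p["a"] == pytest.approx(0.5714, abs=1e-4)
        assert p["b"] == pytest.approx(0.1905, abs=1e-4)
        assert p["c"] == pytest.approx(0.1905, abs=1e-4)
        assert p["d"] == pytest.approx(0.0476, abs=1e-4)
        assert set(part.downhill) == {"a", "b"}
        assert part.flat == ["c"]
        assert part.uphill == ["d"]

    def test_single_downhill_neighbor(self):
        env = two_node_env()
        env.reset_altitudes(10.0)
        part = sr.transition_probabilities(env, "s", sr.RFDParams())
        assert part.probabilities == {"g": pytest.approx(1.0)}

    def test_all_flat_uniform(self):
        env = sr.REnvironment(
            adjacency={"i": {"a": 1.0, "b": 1.0, "c": 1.0},
                       "a": {}, "b": {}, "c": {}, "g": {}}, goal="g")
        env.altitude = {"i": 5.0, "a": 5.0, "b": 5.0, "c": 5.0, "g": 0.0}
        part = sr.transition_probabilities(env, "i", sr.RFDParams())
        for p in part.probabilities.values():
            assert p == pytest.approx(1.0 / 3.0)

    def test_isolated_node_raises(self):
        env = sr.REnvironment(adjacency={"i": {}, "g": {}}, goal="g")
        env.altitude = {"i": 5.0, "g": 0.0}
        with pytest.raises(IsolatedNodeError):
            sr.transition_probabilities(env, "i", sr.RFDParams())

    def test_normalization_random_envs(self, rng):
        params = sr.RFDParams()
        for _ in range(100):
            env = random_environment(rng)
            for node in env.nodes:
                if not env.neighbors(node):
                    continue
                part = sr.transition_probabilities(env, node, params)
                assert sum(part.probabilities.values()) == pytest.approx(
                    1.0, abs=1e-9)
                groups = (set(part.downhill) | set(part.uphill)
                          | set(part.flat))
                assert groups == set(env.neighbors(node))


class TestMoveDrop:
    def test_start_at_goal(self, rng):
        env = two_node_env()
        env.reset_altitudes(10.0)
        path = sr.move_drop(env, "g", sr.RFDParams(), rng)
        assert path.nodes == ["g"] and path.reached_goal

    def test_decreasing_chain_deterministic(self, chain_env, rng):
        path = sr.move_drop(chain_env, "a", sr.RFDParams(), rng)
        assert path.nodes == ["a", "b", "c", "g"]
        assert path.reached_goal

    def test_length_bound(self, rng):
        for _ in range(20):
            env = random_environment(rng)
            path = sr.move_drop(env, env.source, sr.RFDParams(), rng)
            assert len(path.nodes) <= env.n_nodes
            for a, b in path.edges():
                assert b in env.neighbors(a)

    def test_fork_frequencies_match_probabilities(self):
        """1000 seeded single-step walks on a 2-choice fork land within
        3 binomial standard errors of the computed probability."""
        env = sr.REnvironment(
            adjacency={"i": {"a": 1.0, "b": 1.0}, "a": {}, "b": {}, "g": {}},
            goal="g")
        env.altitude = {"i": 10.0, "a": 4.0, "b": 8.0, "g": 0.0}
        params = sr.RFDParams()
        part = sr.transition_probabilities(env, "i", params)
        p_a = part.probabilities["a"]  # 6 / (6 + 2) = 0.75
        assert p_a == pytest.approx(0.75)
        rng = np.random.default_rng(2024)
        n = 1000
        hits = sum(
            sr.move_drop(env, "i", params, rng).nodes[1] == "a"
            for _ in range(n))
        se = math.sqrt(p_a * (1 - p_a) / n)
        assert abs(hits / n - p_a) <= 3 * se


class TestErode:
    def test_worked_decrement(self):
        env = sr.REnvironment(
            adjacency={n: {} for n in "abcdg"} | {"a": {"b": 1.0}},
            goal="g")
        env.altitude = {"a": 10.0, "b": 8.0, "c": 5.0, "d": 5.0, "g": 0.0}
        # E=4, N=5, D=2, gradient 2 -> decrement 1.0
        params = sr.RFDParams(erosion=4.0, n_drops=2)
        produced = sr.erode(env, [sr.DropPath(["a", "b"], True)], params)
        assert env.altitude["a"] == pytest.approx(9.0)
        assert produced == pytest.approx(1.0)

    def test_empty_paths_no_change(self):
        env = two_node_env()
        env.reset_altitudes(10.0)
        before = dict(env.altitude)
        assert sr.erode(env, [], sr.RFDParams()) == 0.0
        assert env.altitude == before

    def test_uphill_step_raises_altitude(self):
        env = sr.REnvironment(
            adjacency={"a": {"b": 1.0}, "b": {}, "c": {}, "g": {}}, goal="g")
        env.altitude = {"a": 5.0, "b": 9.0, "c": 1.0, "g": 0.0}
        sr.erode(env, [sr.DropPath(["a", "b"], False)], sr.RFDParams())
        assert env.altitude["a"] > 5.0


class TestDepositSediment:
    def test_worked_conservation(self):
        env = sr.REnvironment(
            adjacency={"a": {}, "b": {}, "c": {}, "g": {}}, goal="g")
        env.altitude = {"a": 1.0, "b": 2.0, "c": 3.0, "g": 0.0}
        sr.deposit_sediment(env, 6.0)
        assert env.altitude["a"] == pytest.approx(3.0)
        assert env.altitude["b"] == pytest.approx(4.0)
        assert env.altitude["c"] == pytest.approx(5.0)

    def test_zero_is_noop_and_goal_pinned(self):
        env = sr.REnvironment(adjacency={"a": {}, "g": {}}, goal="g")
        env.altitude = {"a": 4.0, "g": 0.0}
        sr.deposit_sediment(env, 0.0)
        assert env.altitude == {"a": 4.0, "g": 0.0}
        sr.deposit_sediment(env, 10.0)
        assert env.altitude["g"] == 0.0

    def test_conservation_random(self, rng):
        for _ in range(50):
            env = random_environment(rng)
            produced = float(rng.uniform(0.0, 20.0))
            before = sum(v for k, v in env.altitude.items() if k != env.goal)
            sr.deposit_sediment(env, produced)
            after = sum(v for k, v in env.altitude.items() if k != env.goal)
            assert after - before == pytest.approx(produced, abs=1e-9)


class TestRunRFD:
    def test_two_node_graph(self):
        env = two_node_env()
        res = sr.run_rfd(env, sr.RFDParams(max_iter=5), rng=0)
        assert res.best_path == ["s", "g"]
        assert res.reached_goal and res.best_cost == pytest.approx(1.0)

    def test_determinism(self):
        p = sr.RFDParams(n_drops=5, max_iter=30)
        r1 = sr.run_rfd(sr.grid_environment(4), p, rng=42)
        r2 = sr.run_rfd(sr.grid_environment(4), p, rng=42)
        assert r1.best_path == r2.best_path
        assert r1.best_cost == r2.best_cost
        assert r1.history == r2.history

    def test_no_solution_reported(self):
        env = sr.REnvironment(
            adjacency={"s": {"x": 1.0}, "x": {"s": 1.0}, "g": {}},
            goal="g", source="s")
        res = sr.run_rfd(env, sr.RFDParams(max_iter=5), rng=0)
        assert not res.reached_goal and res.best_path is None
        assert res.best_cost == np.inf

    def test_grid_route_quality(self):
        """Corner-to-corner 6x6 grid: within 1.2x of the BFS shortest path
        (10 edges) in at least 90% of 20 seeded runs."""
        import networkx as nx

        env0 = sr.grid_environment(6)
        g = nx.Graph()
        for i, nbrs in env0.adjacency.items():
            for j in nbrs:
                g.add_edge(i, j)
        oracle = nx.shortest_path_length(g, (0, 0), (5, 5))
        assert oracle == 10
        params = sr.RFDParams(erosion=8.0, n_drops=10, max_iter=150,
                              patience=50)
        ok = 0
        for seed in range(20):
            res = sr.run_rfd(env0.copy(), params, rng=seed)
            if res.reached_goal and res.best_cost <= 1.2 * oracle:
                ok += 1
        assert ok >= 18

    def test_altitudes_stay_positive(self, rng):
        env = sr.grid_environment(4)
        res = sr.run_rfd(env, sr.RFDParams(n_drops=5, max_iter=40), rng=7)
        for node, alt in res.env.altitude.items():
            if node == env.goal:
                assert alt == 0.0
            else:
                assert alt > 0.0
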