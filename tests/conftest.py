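import numpy as np
import pytest

import swarmrec as sr


@pytest.fixture
def small_db() -> sr.TransactionDB:
    """The five-transaction database used by the worked mining examples."""
    return sr.TransactionDB(
        [{"a", "b"}, {"a", "b", "c"}, {"a", "c"}, {"b"}, {"a", "b", "c"}])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_db(rng: np.random.Generator, max_items: int = 8,
              max_transactions: int = 25) -> sr.TransactionDB:
    """Small random transaction database for oracle-equivalence checks."""
    n_items = int(rng.integers(1, max_items + 1))
    n_trans = int(rng.integers(1, max_transactions + 1))
    items = [chr(ord("a") + k) for k in range(n_items)]
    transactions = []
    for _ in range(n_trans):
        p = rng.uniform(0.1, 0.7)
        t = {it for it in items if rng.random() < p}
        transactions.append(t)
    return sr.TransactionDB(transactions)


@pytest.fixture
def chain_env() -> sr.REnvironment:
    """Four-node chain with strictly decreasing altitudes toward the goal."""
    env = sr.REnvironment(
        adjacency={"a": {"b": 1.0}, "b": {"c": 1.0}, "c": {"g": 1.0},
                   "g": {}},
        goal="g", source="a")
    env.altitude = {"a": 30.0, "b": 20.0, "c": 10.0, "g": 0.0}
    return env


def random_environment(rng: np.random.Generator,
                       n_nodes: int = 8) -> sr.REnvironment:
    """Connected random digraph with random positive altitudes/distances."""
    nodes = list(range(n_nodes))
    adj: dict = {n: {} for n in nodes}
    for i in nodes[:-1]:
        adj[i][i + 1] = float(rng.uniform(0.5, 2.0))  # spine keeps it connected
    for i in nodes:
        for j in nodes:
            if i != j and rng.random() < 0.3:
                adj[i][j] = float(rng.uniform(0.5, 2.0))
    env = sr.REnvironment(adjacency=adj, goal=nodes[-1], source=nodes[0])
    env.altitude = {n: float(rng.uniform(0.0, 50.0)) for n in nodes}
    env.altitude[env.goal] = 0.0
    return env
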