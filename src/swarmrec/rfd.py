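"""River Formation Dynamics on weighted directed graphs.

Agent drops walk from a source toward a goal node of altitude zero,
choosing successors with probability proportional to the downhill
gradient (uphill and flat moves get small fixed weights), eroding the
nodes they traverse and triggering a uniform sediment deposit across the
environment once per iteration. Good paths therefore deepen over time and
attract later drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

Node = Hashable

ALTITUDE_FLOOR = 1e-6  # non-goal altitudes never fall below this


class MissingEdgeError(KeyError):
    pass


class IsolatedNodeError(ValueError):
    pass


@dataclass
class REnvironment:
    """Graph, per-node altitudes and per-edge distances for RFD.

    The goal node's altitude is pinned at zero for the whole run; all other
    nodes start at a common positive altitude.
    """

    adjacency: dict[Node, dict[Node, float]]
    goal: Node
    source: Node | None = None
    altitude: dict[Node, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, nbrs in self.adjacency.items():
            for j, dist in nbrs.items():
                if dist <= 0:
                    raise ValueError(f"distance({i!r},{j!r}) must be > 0")
        if self.goal not in self.adjacency:
            raise ValueError("goal node absent from graph")

    @property
    def nodes(self) -> list[Node]:
        return list(self.adjacency)

    @property
    def n_nodes(self) -> int:
        return len(self.adjacency)

    def reset_altitudes(self, init_altitude: float) -> None:
        """Flat environment: every node at ``init_altitude``, goal at 0."""
        self.altitude = {n: float(init_altitude) for n in self.adjacency}
        self.altitude[self.goal] = 0.0

    def distance(self, i: Node, j: Node) -> float:
        try:
            return self.adjacency[i][j]
        except KeyError as exc:
            raise MissingEdgeError(f"no edge {i!r} -> {j!r}") from exc

    def neighbors(self, i: Node) -> dict[Node, float]:
        return self.adjacency[i]

    def path_cost(self, path: Sequence[Node]) -> float:
        return sum(self.distance(a, b) for a, b in zip(path, path[1:]))

    def copy(self) -> "REnvironment":
        return REnvironment(
            adjacency={i: dict(n) for i, n in self.adjacency.items()},
            goal=self.goal,
            source=self.source,
            altitude=dict(self.altitude),
        )


def grid_environment(side: int, source: Node | None = None,
                     goal: Node | None = None) -> REnvironment:
    """side x side 4-connected grid with unit distances.

    Nodes are (row, col); defaults route from the bottom-left corner to the
    top-right corner.
    """
    adj: dict[Node, dict[Node, float]] = {}
    for r in range(side):
        for c in range(side):
            nbrs: dict[Node, float] = {}
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < side and 0 <= cc < side:
                    nbrs[(rr, cc)] = 1.0
            adj[(r, c)] = nbrs
    return REnvironment(adjacency=adj,
                        goal=goal if goal is not None else (side - 1, side - 1),
                        source=source if source is not None else (0, 0))


@dataclass(frozen=True)
class RFDParams:
    """Coefficients and stopping controls for a run."""

    omega: float = 0.2          # weight of climbing (uphill) moves
    delta: float = 0.1          # weight of flat moves
    erosion: float = 1.0        # E
    n_drops: int = 10           # D
    init_altitude: float = 100.0
    sediment_fraction: float = 0.5  # deposited by a stopped drop
    max_iter: int = 100
    patience: int = 25
    forbid_backtrack: bool = True

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.delta <= 0 or self.erosion <= 0:
            raise ValueError("omega, delta and erosion must be > 0")
        if self.n_drops < 1:
            raise ValueError("n_drops must be >= 1")


def gradient(env: REnvironment, i: Node, j: Node) -> float:
    """Altitude drop from i to j per unit distance."""
    dist = env.distance(i, j)
    return (env.altitude[i] - env.altitude[j]) / dist


@dataclass
class NeighborPartition:
    """Neighbors of a node split by gradient sign, with move probabilities."""

    downhill: list[Node]   # positive gradient (V_k)
    uphill: list[Node]     # negative gradient (U_k)
    flat: list[Node]       # zero gradient (F_k)
    gradients: dict[Node, float]
    total: float
    probabilities: dict[Node, float]


def transition_probabilities(env: REnvironment, i: Node, params: RFDParams,
                             exclude: Node | None = None) -> NeighborPartition:
    """Move probabilities from node ``i``.

    Downhill neighbors weigh their gradient, uphill neighbors weigh
    ``omega / |gradient|`` (absolute value keeps the weight positive), flat
    neighbors weigh ``delta``; probabilities are the weights over their sum.
    """
    nbrs = [j for j in env.neighbors(i) if j != exclude]
    if not nbrs:
        raise IsolatedNodeError(f"node {i!r} has no eligible neighbors")
    downhill: list[Node] = []
    uphill: list[Node] = []
    flat: list[Node] = []
    grads: dict[Node, float] = {}
    weights: dict[Node, float] = {}
    for j in nbrs:
        g = gradient(env, i, j)
        grads[j] = g
        if g > 0:
            downhill.append(j)
            weights[j] = g
        elif g < 0:
            uphill.append(j)
            weights[j] = params.omega / abs(g)
        else:
            flat.append(j)
            weights[j] = params.delta
    total = sum(weights.values())
    probs = {j: w / total for j, w in weights.items()}
    return NeighborPartition(downhill=downhill, uphill=uphill, flat=flat,
                             gradients=grads, total=total,
                             probabilities=probs)


@dataclass
class DropPath:
    """Route taken by one drop in one iteration."""

    nodes: list[Node]
    reached_goal: bool
    carried_sediment: float = 0.0

    def edges(self) -> list[tuple[Node, Node]]:
        return list(zip(self.nodes, self.nodes[1:]))


def move_drop(env: REnvironment, start: Node, params: RFDParams,
              rng: np.random.Generator) -> DropPath:
    """Walk from ``start`` until the goal is reached, the drop is stuck, or
    the visited-node budget (the environment size) is exhausted."""
    path = [start]
    prev: Node | None = None
    current = start
    max_nodes = env.n_nodes
    while current != env.goal and len(path) < max_nodes:
        exclude = prev if params.forbid_backtrack else None
        try:
            part = transition_probabilities(env, current, params, exclude=exclude)
        except IsolatedNodeError:
            return DropPath(nodes=path, reached_goal=False)
        nbrs = list(part.probabilities)
        probs = np.array([part.probabilities[j] for j in nbrs])
        nxt = nbrs[int(rng.choice(len(nbrs), p=probs))]
        path.append(nxt)
        prev, current = current, nxt
    return DropPath(nodes=path, reached_goal=current == env.goal)


def erode(env: REnvironment, paths: Iterable[DropPath],
          params: RFDParams) -> float:
    """Lower the altitude of each traversed node by the gradient-scaled
    erosion term; returns the summed (signed) erosion produced.

    Each drop also accumulates its own erosion as carried sediment. The
    goal altitude is never modified.
    """
    n = env.n_nodes
    d = params.n_drops
    if n < 2:
        return 0.0
    produced = 0.0
    for p in paths:
        carried = 0.0
        for i, j in p.edges():
            if i == env.goal:
                continue
            dec = (params.erosion / ((n - 1) * d)) * gradient(env, i, j)
            env.altitude[i] = max(ALTITUDE_FLOOR, env.altitude[i] - dec)
            produced += dec
            carried += dec
        p.carried_sediment = carried
    return produced


def deposit_sediment(env: REnvironment, erosion_produced: float,
                     params: RFDParams | None = None) -> None:
    """Spread ``erosion_produced`` evenly over all non-goal nodes."""
    n = env.n_nodes
    if n < 2:
        return
    inc = erosion_produced / (n - 1)
    for node in env.adjacency:
        if node != env.goal:
            env.altitude[node] += inc
    env.altitude[env.goal] = 0.0


@dataclass
class RFDResult:
    best_path: list[Node] | None
    best_cost: float
    reached_goal: bool
    n_iterations: int
    env: REnvironment
    history: list[float] = field(default_factory=list)


def run_rfd(env: REnvironment, params: RFDParams,
            rng: np.random.Generator | int | None = None,
            start: Node | None = None) -> RFDResult:
    """Iterate move-all-drops / erode / deposit until convergence.

    A drop that stops short of the goal deposits ``sediment_fraction`` of
    its carried sediment on its final node and evaporates for the rest of
    the iteration. Returns the cheapest goal-reaching path observed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if start is None:
        start = env.source
    if start is None:
        raise ValueError("no start node: set env.source or pass start=")
    env.reset_altitudes(params.init_altitude)

    best_path: list[Node] | None = None
    best_cost = np.inf
    history: list[float] = []
    stale = 0
    it = 0
    for it in range(1, params.max_iter + 1):
        paths = [move_drop(env, start, params, rng)
                 for _ in range(params.n_drops)]
        improved = False
        for p in paths:
            if p.reached_goal:
                cost = env.path_cost(p.nodes)
                if cost < best_cost:
                    best_cost = cost
                    best_path = list(p.nodes)
                    improved = True
        produced = erode(env, paths, params)
        for p in paths:
            if not p.reached_goal and p.nodes:
                last = p.nodes[-1]
                if last != env.goal:
                    env.altitude[last] += params.sediment_fraction * p.carried_sediment
        deposit_sediment(env, max(0.0, produced), params)
        history.append(best_cost)
        stale = 0 if improved else stale + 1
        if best_path is not None and stale >= params.patience:
            break
    return RFDResult(best_path=best_path, best_cost=best_cost,
                     reached_goal=best_path is not None,
                     n_iterations=it, env=env, history=history)
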