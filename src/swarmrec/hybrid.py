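"""Hybrid RFD-PSO wrapper feature selection.

Feature subsets are encoded two ways: as source -> sink paths through an
index-ordered feature graph (the RFD view) and as points in the unit box
(the PSO view, re-binarized at a threshold). The hybrid alternates RFD
exploration — where a path's wrapper fitness drives extra erosion so good
subsets become attractive valleys — with PSO refinement of the best masks
found, and reinforces the global-best path with a small constant erosion
bonus before handing control back to RFD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .pso import PSOParams, run_pso
from .recommend import RatingsMatrix, UserCF, precision_recall_at_n, split_ratings
from .rfd import (ALTITUDE_FLOOR, REnvironment, RFDParams, deposit_sediment,
                  erode, move_drop)

SOURCE = "source"
SINK = "sink"

Evaluator = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class FeatureSubset:
    mask: tuple[int, ...]
    fitness: float
    provenance: str  # rfd | pso | hybrid

    @property
    def n_selected(self) -> int:
        return int(sum(self.mask))

    def indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.mask))


def feature_graph(n_features: int) -> REnvironment:
    """Source/sink DAG whose source->sink paths are exactly the strictly
    increasing feature index sequences (one path per mask)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    adj: dict = {SOURCE: {}, SINK: {}}
    adj[SOURCE][SINK] = 1.0
    for i in range(n_features):
        adj[SOURCE][i] = 1.0
        adj[i] = {SINK: 1.0}
        for j in range(i + 1, n_features):
            adj[i][j] = 1.0
    return REnvironment(adjacency=adj, goal=SINK, source=SOURCE)


def path_to_mask(path: Sequence, n_features: int) -> np.ndarray:
    """Binary mask with 1 at each feature node the path visits."""
    if len(path) < 2 or path[0] != SOURCE or path[-1] != SINK:
        raise ValueError("path must run source -> sink")
    mask = np.zeros(n_features, dtype=int)
    prev = -1
    for node in path[1:-1]:
        if not isinstance(node, (int, np.integer)) or not 0 <= node < n_features:
            raise ValueError(f"illegal path node {node!r}")
        if node <= prev:
            raise ValueError("path features must be strictly increasing")
        mask[node] = 1
        prev = node
    return mask


def mask_to_path(mask: np.ndarray) -> list:
    return [SOURCE] + [int(i) for i in np.flatnonzero(np.asarray(mask))] + [SINK]


# ---------------------------------------------------------------------------
# wrapper fitness evaluators


class KnnFitness:
    """1 minus held-out k-NN accuracy on the masked columns.

    The train/test split is fixed at construction, so a (mask, seed) pair
    always reproduces the same score. Evaluations are cached by mask.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_neighbors: int = 3,
                 test_fraction: float = 0.25, seed: int = 0,
                 penalty: float = 0.0):
        from sklearn.neighbors import KNeighborsClassifier  # local: heavy import

        self._knn_cls = KNeighborsClassifier
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.n_neighbors = n_neighbors
        self.penalty = penalty
        rng = np.random.default_rng(seed)
        n = len(self.y)
        order = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n)))
        self.test_idx = order[:n_test]
        self.train_idx = order[n_test:]
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        if not mask.any():
            warnings.warn("empty feature mask scored at worst fitness")
            score = 1.0
        else:
            cols = np.flatnonzero(mask)
            clf = self._knn_cls(n_neighbors=self.n_neighbors)
            clf.fit(self.X[np.ix_(self.train_idx, cols)], self.y[self.train_idx])
            acc = clf.score(self.X[np.ix_(self.test_idx, cols)],
                            self.y[self.test_idx])
            score = 1.0 - float(acc) + self.penalty * mask.sum() / mask.size
            self.n_evaluations += 1
        self._cache[key] = score
        return score


class CFFitness:
    """1 minus held-out precision@N of a CF recommender restricted to items
    covered by the selected item features."""

    def __init__(self, ratings: RatingsMatrix, item_features: np.ndarray,
                 at_n: int = 10, seed: int = 0, k_neighbors: int = 20,
                 penalty: float = 0.0):
        self.ratings = ratings
        self.item_features = np.asarray(item_features, dtype=float)
        if self.item_features.shape[0] != ratings.n_items:
            raise ValueError("item_features rows must match n_items")
        self.at_n = at_n
        self.seed = seed
        self.k_neighbors = k_neighbors
        self.penalty = penalty
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        if not mask.any():
            warnings.warn("empty feature mask scored at worst fitness")
            score = 1.0
        else:
            covered = np.flatnonzero(self.item_features[:, mask].sum(axis=1) > 0)
            if covered.size < 2 * self.at_n:
                score = 1.0
            else:
                sub = self.ratings.restrict_items(covered)
                try:
                    train, test = split_ratings(sub, seed=self.seed)
                    model = UserCF(k_neighbors=self.k_neighbors).fit(train)
                    res = precision_recall_at_n(model, test, n_grid=(self.at_n,))
                    score = 1.0 - res.precision[self.at_n]
                except ValueError:
                    score = 1.0
            score += self.penalty * mask.sum() / mask.size
            self.n_evaluations += 1
        self._cache[key] = score
        return score


# ---------------------------------------------------------------------------
# selection drivers


@dataclass(frozen=True)
class HybridParams:
    """Schedule knobs for the alternating RFD / PSO phases."""

    n_phases: int = 3
    rfd_iters: int = 8
    pso_iters: int = 12
    top_k: int = 8
    threshold: float = 0.5
    quality_erosion: float = 5.0   # extra erosion scale for good paths
    gbest_bonus: float = 0.5       # small constant bonus, times erosion coeff
    n_init_masks: int = 10
    pso_jitter: float = 0.4        # relaxation noise around seeded masks
    pso_extra_particles: int = 8   # random particles added to each swarm
    polish_iters: int = 12         # final PSO refinement after the phases

    def __post_init__(self) -> None:
        if self.n_phases < 0:
            raise ValueError("n_phases must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class SelectionResult:
    best: FeatureSubset
    trace: list[tuple[str, float]] = field(default_factory=list)
    n_evaluations: int = 0


def _binarize(x: np.ndarray, threshold: float) -> np.ndarray:
    return (np.asarray(x) >= threshold).astype(int)


def _random_masks(n: int, n_features: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    masks = []
    for _ in range(n):
        mask = (rng.random(n_features) < 0.5).astype(int)
        if not mask.any():
            mask[int(rng.integers(n_features))] = 1
        masks.append(mask)
    return masks


class _Tracker:
    """Best-so-far bookkeeping plus a registry of every distinct mask."""

    def __init__(self, evaluator: Evaluator, provenance: str):
        self.evaluator = evaluator
        self.provenance = provenance
        self.best_mask: np.ndarray | None = None
        self.best_f = np.inf
        self.trace: list[tuple[str, float]] = []
        self.registry: dict[bytes, float] = {}
        self.n_evaluations = 0

    def score(self, mask: np.ndarray, stage: str) -> float:
        mask = np.asarray(mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = self.evaluator(mask)
        self.n_evaluations += 1
        if mask.any():
            self.registry[np.packbits(mask.astype(bool)).tobytes()] = f
            if f < self.best_f:
                self.best_f = f
                self.best_mask = mask.copy()
        self.trace.append((stage, self.best_f))
        return f

    def top_masks(self, k: int, n_features: int) -> list[np.ndarray]:
        ranked = sorted(self.registry.items(), key=lambda kv: kv[1])
        return [np.unpackbits(np.frombuffer(key, dtype=np.uint8),
                              count=n_features).astype(int)
                for key, _ in ranked[:k]]

    def result(self) -> SelectionResult:
        if self.best_mask is None:
            raise RuntimeError("no non-empty mask was ever evaluated")
        best = FeatureSubset(mask=tuple(int(b) for b in self.best_mask),
                             fitness=float(self.best_f),
                             provenance=self.provenance)
        return SelectionResult(best=best, trace=self.trace,
                               n_evaluations=self.n_evaluations)


def _rfd_explore(env: REnvironment, tracker: _Tracker, n_features: int,
                 params: RFDParams, n_iters: int, quality_scale: float,
                 rng: np.random.Generator, stage: str) -> None:
    """RFD iterations where wrapper fitness adds quality-scaled erosion."""
    for _ in range(n_iters):
        paths = [move_drop(env, SOURCE, params, rng)
                 for _ in range(params.n_drops)]
        produced = erode(env, paths, params)
        for p in paths:
            if not p.reached_goal:
                continue
            mask = path_to_mask(p.nodes, n_features)
            if not mask.any():
                continue
            f = tracker.score(mask, stage)
            # carve good paths deeper in proportion to their quality
            bonus = params.erosion * quality_scale * (1.0 - f)
            for node in p.nodes[1:-1]:
                env.altitude[node] = max(ALTITUDE_FLOOR,
                                         env.altitude[node] - bonus)
        deposit_sediment(env, max(0.0, produced), params)


def run_rfd_select(evaluator: Evaluator, n_features: int,
                   rfd_params: RFDParams | None = None,
                   hybrid_params: HybridParams | None = None,
                   seed: int = 0) -> SelectionResult:
    """Pure-RFD feature selection on the feature graph (same total budget
    of iterations as the hybrid schedule)."""
    hp = hybrid_params or HybridParams()
    rp = rfd_params or RFDParams(n_drops=8, init_altitude=10.0)
    rng = np.random.default_rng(seed)
    tracker = _Tracker(evaluator, "rfd")
    for mask in _random_masks(hp.n_init_masks, n_features, rng):
        tracker.score(mask, "init")
    env = feature_graph(n_features)
    env.reset_altitudes(rp.init_altitude)
    total_iters = hp.n_phases * (hp.rfd_iters + hp.pso_iters)
    _rfd_explore(env, tracker, n_features, rp, total_iters,
                 hp.quality_erosion, rng, "rfd")
    return tracker.result()


def run_pso_select(evaluator: Evaluator, n_features: int,
                   pso_params: PSOParams | None = None,
                   hybrid_params: HybridParams | None = None,
                   seed: int = 0) -> SelectionResult:
    """Pure-PSO feature selection in the relaxed unit box."""
    hp = hybrid_params or HybridParams()
    pp = pso_params or PSOParams(
        bounds=((0.0, 1.0),) * n_features, swarm_size=hp.top_k,
        max_iter=hp.n_phases * (hp.rfd_iters + hp.pso_iters))
    tracker = _Tracker(evaluator, "pso")
    rng = np.random.default_rng(seed)
    for mask in _random_masks(hp.n_init_masks, n_features, rng):
        tracker.score(mask, "init")

    def objective(x: np.ndarray) -> float:
        return tracker.score(_binarize(x, hp.threshold), "pso")

    run_pso(objective, pp, rng=rng)
    return tracker.result()


def run_rfd_pso(evaluator: Evaluator, n_features: int,
                rfd_params: RFDParams | None = None,
                pso_params: PSOParams | None = None,
                hybrid_params: HybridParams | None = None,
                seed: int = 0) -> SelectionResult:
    """Alternate RFD exploration and PSO refinement of the best masks.

    Each phase: (1) RFD drops carve the feature graph, with wrapper fitness
    adding quality-scaled erosion along traversed paths; (2) the top-k
    distinct masks seen so far — relaxed with jitter and topped up with
    random particles — seed a PSO swarm in [0,1]^D whose objective is the
    fitness of the thresholded mask; (3) the global-best mask's path gets a
    small constant erosion bonus before RFD resumes. A final PSO polish
    refines the overall top masks once the phases are done.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features to select from")
    hp = hybrid_params or HybridParams()
    rp = rfd_params or RFDParams(n_drops=8, init_altitude=10.0)
    rng = np.random.default_rng(seed)
    tracker = _Tracker(evaluator, "hybrid")

    for mask in _random_masks(hp.n_init_masks, n_features, rng):
        tracker.score(mask, "init")

    env = feature_graph(n_features)
    env.reset_altitudes(rp.init_altitude)

    def pso_refine(n_iters: int, stage: str) -> None:
        top = tracker.top_masks(hp.top_k, n_features)

        def objective(x: np.ndarray) -> float:
            return tracker.score(_binarize(x, hp.threshold), stage)

        init = [m + rng.uniform(-hp.pso_jitter, hp.pso_jitter,
                                size=n_features) for m in top]
        pp = pso_params or PSOParams(
            bounds=((0.0, 1.0),) * n_features,
            swarm_size=max(len(init) + hp.pso_extra_particles, 2),
            max_iter=n_iters)
        run_pso(objective, pp, rng=rng, init_positions=init)

    for phase in range(hp.n_phases):
        _rfd_explore(env, tracker, n_features, rp, hp.rfd_iters,
                     hp.quality_erosion, rng, f"rfd:{phase}")
        pso_refine(hp.pso_iters, f"pso:{phase}")

        if tracker.best_mask is not None:
            for node in mask_to_path(tracker.best_mask)[1:-1]:
                env.altitude[node] = max(
                    ALTITUDE_FLOOR,
                    env.altitude[node] - hp.gbest_bonus * rp.erosion)

    if hp.n_phases > 0 and hp.polish_iters > 0:
        pso_refine(hp.polish_iters, "polish")

    return tracker.result()
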