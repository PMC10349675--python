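"""User-based collaborative filtering and top-N precision/recall evaluation.

Ratings live in a dense user x item array with NaN marking unobserved
cells (synthetic workloads here are small). Similarities are computed over
co-rated items only; predictions are the user's mean plus a
similarity-weighted average of mean-centred neighbor deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class RatingsMatrix:
    """Sparse-in-spirit ratings with a relevance threshold."""

    values: np.ndarray                      # (n_users, n_items), NaN = missing
    user_ids: list[str]
    item_ids: list[str]
    scale: tuple[float, float] = (1.0, 5.0)
    relevance_threshold: float = 4.0
    timestamps: np.ndarray | None = None    # same shape, NaN = missing
    ground_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.user_ids), len(self.item_ids)):
            raise ValueError("values shape does not match id lists")
        obs = self.values[~np.isnan(self.values)]
        lo, hi = self.scale
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValueError("observed ratings fall outside the scale")

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def observed_items(self, user: int) -> np.ndarray:
        return np.flatnonzero(self.mask[user])

    def relevant_items(self, user: int) -> np.ndarray:
        row = self.values[user]
        return np.flatnonzero(~np.isnan(row) & (row >= self.relevance_threshold))

    def global_mean(self) -> float:
        obs = self.values[self.mask]
        return float(obs.mean()) if obs.size else 0.5 * sum(self.scale)

    def user_mean(self, user: int) -> float:
        row = self.values[user]
        obs = row[~np.isnan(row)]
        return float(obs.mean()) if obs.size else self.global_mean()

    def restrict_items(self, item_idx: np.ndarray) -> "RatingsMatrix":
        """View of the matrix keeping only the given item columns."""
        item_idx = np.asarray(item_idx, dtype=int)
        return RatingsMatrix(
            values=self.values[:, item_idx].copy(),
            user_ids=list(self.user_ids),
            item_ids=[self.item_ids[j] for j in item_idx],
            scale=self.scale,
            relevance_threshold=self.relevance_threshold,
            timestamps=None if self.timestamps is None
            else self.timestamps[:, item_idx].copy(),
        )


def similarity(u: np.ndarray, v: np.ndarray, method: str = "pearson") -> float:
    """Cosine or Pearson similarity over co-rated positions only.

    Fewer than two co-rated items, or a constant co-rated vector, yields 0.
    """
    if method not in ("cosine", "pearson"):
        raise ValueError(f"unknown similarity method: {method!r}")
    both = ~np.isnan(u) & ~np.isnan(v)
    if both.sum() < 2:
        return 0.0
    a, b = u[both], v[both]
    if method == "pearson":
        a = a - a.mean()
        b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class UserCF:
    """k-nearest-neighbor user-based collaborative filter."""

    k_neighbors: int = 20
    method: str = "pearson"

    def fit(self, train: RatingsMatrix) -> "UserCF":
        self.train_ = train
        n = train.n_users
        sim = np.zeros((n, n))
        for u in range(n):
            for v in range(u + 1, n):
                s = similarity(train.values[u], train.values[v], self.method)
                sim[u, v] = sim[v, u] = s
        self.sim_ = sim
        self.user_means_ = np.array([train.user_mean(u) for u in range(n)])
        return self

    def predict_rating(self, user: int, item: int) -> float:
        """User mean + weighted mean-centred neighbor deviation, clipped to
        the rating scale; falls back to the user mean (then global mean)."""
        lo, hi = self.train_.scale
        return float(np.clip(self._score(user, item), lo, hi))

    def _score(self, user: int, item: int) -> float:
        """Unclipped prediction, used for ranking (clipping would flatten
        distinct strong predictions into ties at the scale ceiling)."""
        train = self.train_
        raters = np.flatnonzero(train.mask[:, item])
        raters = raters[raters != user]
        base = self.user_means_[user]
        if raters.size:
            sims = self.sim_[user, raters]
            keep = sims > 0  # negative similarities discarded
            raters, sims = raters[keep], sims[keep]
        if raters.size:
            order = np.argsort(-sims)[: self.k_neighbors]
            raters, sims = raters[order], sims[order]
            denom = np.abs(sims).sum()
            if denom > 0:
                dev = train.values[raters, item] - self.user_means_[raters]
                base = base + float(sims @ dev) / denom
        return base

    def top_n(self, user: int, n: int,
              candidate_items: Sequence[int] | None = None) -> list[int]:
        """N highest-predicted unseen items; ties broken by item index."""
        train = self.train_
        if candidate_items is None:
            candidate_items = np.flatnonzero(~train.mask[user])
        candidates = np.asarray(candidate_items, dtype=int)
        if candidates.size < n:
            warnings.warn(
                f"user {user}: only {candidates.size} candidates for top-{n}")
        scores = np.array([self._score(user, j) for j in candidates])
        order = np.lexsort((candidates, -scores))  # score desc, index asc
        return [int(candidates[i]) for i in order[:n]]


def split_ratings(matrix: RatingsMatrix, test_fraction: float = 0.2,
                  seed: int = 0, temporal: bool = False
                  ) -> tuple[RatingsMatrix, RatingsMatrix]:
    """Per-user holdout split of observed cells.

    ``temporal=True`` holds out each user's latest ratings (requires
    timestamps); otherwise held-out cells are chosen at random per user.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train = matrix.values.copy()
    test = np.full_like(matrix.values, np.nan)
    for u in range(matrix.n_users):
        obs = matrix.observed_items(u)
        if obs.size < 2:
            continue
        n_test = max(1, int(round(test_fraction * obs.size)))
        n_test = min(n_test, obs.size - 1)  # keep at least one train rating
        if temporal:
            if matrix.timestamps is None:
                raise ValueError("temporal split requires timestamps")
            order = np.argsort(matrix.timestamps[u, obs])
            held = obs[order[-n_test:]]
        else:
            held = rng.choice(obs, size=n_test, replace=False)
        train[u, held] = np.nan
        test[u, held] = matrix.values[u, held]
    mk = dict(user_ids=matrix.user_ids, item_ids=matrix.item_ids,
              scale=matrix.scale,
              relevance_threshold=matrix.relevance_threshold)
    return (RatingsMatrix(values=train, timestamps=matrix.timestamps, **mk),
            RatingsMatrix(values=test, **mk))


DEFAULT_N_GRID = tuple(range(2, 19, 2))  # 2, 4, ..., 18


@dataclass
class EvalResult:
    """Macro-averaged precision/recall over a grid of list lengths."""

    n_grid: tuple[int, ...]
    precision: dict[int, float]
    recall: dict[int, float]
    per_user: dict[int, list[tuple[int, float, float]]]
    n_users_evaluated: int

    def as_rows(self) -> list[tuple[int, float, float]]:
        return [(n, self.precision[n], self.recall[n]) for n in self.n_grid]


def precision_recall_at_n(model: UserCF, test: RatingsMatrix,
                          n_grid: Sequence[int] = DEFAULT_N_GRID
                          ) -> EvalResult:
    """Per-user hits over top-N lists, macro-averaged.

    Relevant = held-out ratings at or above the matrix's relevance
    threshold; users without relevant test items are excluded.
    """
    if test.n_observed == 0:
        raise ValueError("test split contains no observed ratings")
    n_grid = tuple(n_grid)
    n_max = max(n_grid)
    per_user: dict[int, list[tuple[int, float, float]]] = {}
    sums_p = {n: 0.0 for n in n_grid}
    sums_r = {n: 0.0 for n in n_grid}
    evaluated = 0
    for u in range(test.n_users):
        relevant = set(test.relevant_items(u).tolist())
        if not relevant:
            continue
        candidates = np.flatnonzero(~model.train_.mask[u])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = model.top_n(u, n_max, candidates)
        evaluated += 1
        rows = []
        for n in n_grid:
            hits = sum(1 for j in ranked[:n] if j in relevant)
            p = hits / n
            r = hits / len(relevant)
            sums_p[n] += p
            sums_r[n] += r
            rows.append((n, p, r))
        per_user[u] = rows
    if evaluated == 0:
        raise ValueError("no user has relevant items in the test split")
    return EvalResult(
        n_grid=n_grid,
        precision={n: sums_p[n] / evaluated for n in n_grid},
        recall={n: sums_r[n] / evaluated for n in n_grid},
        per_user=per_user,
        n_users_evaluated=evaluated,
    )
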