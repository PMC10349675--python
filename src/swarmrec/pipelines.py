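"""End-to-end pipeline variants for the evaluation grid.

Eight presets: {rfd | rfd-pso} selector x {with | without pattern mining}
x {with | without CF}. Item features are either mined frequent
co-occurrence patterns (binary item x pattern membership) or raw
per-item indicator features; the selector picks a feature subset; items
covered by the subset form the recommendation universe. "With CF" ranks
by the user-based collaborative filter, "without CF" by global item
popularity (mean observed rating). Each variant reports mean
precision/recall over the top-N grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hybrid import CFFitness, HybridParams, run_rfd_pso, run_rfd_select
from .mining import TransactionDB, mine_frequent, patterns_as_item_features
from .recommend import (DEFAULT_N_GRID, RatingsMatrix, UserCF,
                        precision_recall_at_n, split_ratings)


@dataclass
class VariantResult:
    name: str
    precision: dict[int, float]
    recall: dict[int, float]


def _ratings_to_transactions(matrix: RatingsMatrix) -> TransactionDB:
    """One transaction per user: the set of relevantly rated items."""
    transactions = []
    for u in range(matrix.n_users):
        items = matrix.relevant_items(u)
        transactions.append(frozenset(matrix.item_ids[j] for j in items))
    return TransactionDB(transactions)


class _PopularityModel(UserCF):
    """Ranks by global item mean rating; ignores user neighborhoods."""

    def fit(self, train: RatingsMatrix) -> "_PopularityModel":
        self.train_ = train
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.item_means_ = np.nanmean(train.values, axis=0)
        self.item_means_ = np.where(np.isnan(self.item_means_),
                                    train.global_mean(), self.item_means_)
        self.user_means_ = np.array(
            [train.user_mean(u) for u in range(train.n_users)])
        return self

    def _score(self, user: int, item: int) -> float:
        return float(self.item_means_[item])


def evaluate_variants(matrix: RatingsMatrix, seed: int = 0,
                      n_grid: tuple[int, ...] = DEFAULT_N_GRID,
                      min_support_frac: float = 0.1,
                      budget: int = 1) -> pd.DataFrame:
    """Run all eight pipeline variants; rows = N grid, columns = variants."""
    rng_seed = seed
    train, test = split_ratings(matrix, seed=seed)

    raw_features = np.eye(matrix.n_items)
    db = _ratings_to_transactions(train)
    min_support = max(2, int(np.ceil(min_support_frac * len(db))))
    mined = mine_frequent(db, min_support)
    mined = [r for r in mined if len(r.itemset) >= 2]
    mined_features, _ = patterns_as_item_features(mined, matrix.item_ids)

    hp = HybridParams(n_phases=budget, rfd_iters=4, pso_iters=6,
                      n_init_masks=6)
    columns: dict[str, VariantResult] = {}
    for selector, use_fp, use_cf in itertools.product(
            ("rfd", "rfd-pso"), (False, True), (False, True)):
        feats = mined_features if (use_fp and mined_features.shape[1] >= 2) \
            else raw_features
        evaluator = CFFitness(train, feats, seed=rng_seed)
        run = run_rfd_select if selector == "rfd" else run_rfd_pso
        sel = run(evaluator, feats.shape[1], hybrid_params=hp, seed=rng_seed)
        covered = np.flatnonzero(
            feats[:, np.asarray(sel.best.mask, dtype=bool)].sum(axis=1) > 0)
        if covered.size < max(n_grid):
            covered = np.arange(matrix.n_items)
        model_cls = UserCF if use_cf else _PopularityModel
        sub_train = train.restrict_items(covered)
        sub_test = test.restrict_items(covered)
        model = model_cls().fit(sub_train)
        res = precision_recall_at_n(model, sub_test, n_grid=n_grid)
        name = (f"{selector}"
                f"{'+fp' if use_fp else ''}"
                f"{'+cf' if use_cf else ''}")
        columns[name] = VariantResult(name, res.precision, res.recall)

    rows = []
    for n in n_grid:
        row: dict[str, object] = {"N": n}
        for name, vr in columns.items():
            row[f"precision[{name}]"] = vr.precision[n]
            row[f"recall[{name}]"] = vr.recall[n]
        rows.append(row)
    return pd.DataFrame(rows)
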