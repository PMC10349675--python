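import numpy as np
import pytest

import swarmrec as sr


def matrix_from_rows(rows, **kw):
    return sr.RatingsMatrix(
        values=np.array(rows, dtype=float),
        user_ids=[f"u{i}" for i in range(len(rows))],
        item_ids=[f"i{j}" for j in range(len(rows[0]))], **kw)


nan = np.nan


class TestSimilarity:
    def test_identical_vectors_cosine(self):
        u = np.array([4.0, 3.0, 5.0])
        assert sr.similarity(u, u, "cosine") == pytest.approx(1.0)

    def test_single_corated_item_zero(self):
        u = np.array([5.0, nan, nan])
        v = np.array([5.0, 4.0, nan])
        assert sr.similarity(u, v, "cosine") == 0.0
        assert sr.similarity(u, v, "pearson") == 0.0

    def test_worked_pearson(self):
        u = np.array([5.0, 3.0, 1.0])
        v = np.array([1.0, 3.0, 5.0])
        assert sr.similarity(u, v, "pearson") == pytest.approx(-1.0)

    def test_constant_corated_vector_zero(self):
        u = np.array([3.0, 3.0, 3.0])
        v = np.array([1.0, 2.0, 5.0])
        assert sr.similarity(u, v, "pearson") == 0.0

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            sr.similarity(np.zeros(3), np.zeros(3), "jaccard")


class TestPredictRating:
    def test_fallback_to_user_mean(self):
        mat = matrix_from_rows([[4.0, 5.0, nan],
                                [nan, nan, nan]])
        model = sr.UserCF().fit(mat)
        assert model.predict_rating(0, 2) == pytest.approx(4.5)

    def test_single_neighbor_unit_similarity(self):
        # users 0 and 1 agree perfectly on items 0-2; neighbor's deviation
        # on item 3 is +1 over its own mean
        mat = matrix_from_rows([[5.0, 3.0, 1.0, nan],
                                [5.0, 3.0, 1.0, 4.0]])
        model = sr.UserCF().fit(mat)
        user_mean = 3.0
        neighbor_dev = 4.0 - 13.0 / 4.0
        assert model.predict_rating(0, 3) == pytest.approx(
            user_mean + neighbor_dev)

    def test_clipped_to_scale(self):
        mat = matrix_from_rows([[5.0, 5.0, 5.0, nan],
                                [5.0, 5.0, 5.0, 5.0],
                                [1.0, 1.0, 1.0, 1.0]])
        model = sr.UserCF().fit(mat)
        assert 1.0 <= model.predict_rating(0, 3) <= 5.0


class TestTopN:
    def test_top2_of_three(self):
        mat = matrix_from_rows([[nan, nan, nan, 2.0, 4.0],
                                [5.0, 1.0, 3.0, 2.0, 4.0],
                                [5.0, 1.0, 3.0, 2.0, 4.0]])
        model = sr.UserCF().fit(mat)
        # neighbors agree perfectly on the co-rated items and prefer 0 > 2 > 1
        assert model.top_n(0, 2, [0, 1, 2]) == [0, 2]

    def test_ties_broken_by_index(self):
        mat = matrix_from_rows([[nan, nan, nan]])
        model = sr.UserCF().fit(mat)
        # no information at all: every candidate scores the global mean
        assert model.top_n(0, 2, [2, 0, 1]) == [0, 1]

    def test_short_candidate_list_warns(self):
        mat = matrix_from_rows([[nan, nan], [4.0, 4.0]])
        model = sr.UserCF().fit(mat)
        with pytest.warns(UserWarning, match="candidates"):
            got = model.top_n(0, 5, [0, 1])
        assert len(got) == 2


class TestSplitRatings:
    def test_disjoint_and_complete(self):
        mat = sr.gen_ratings(sr.SyntheticSpec(seed=0, n_users=20, n_items=30,
                                              density=0.4))
        train, test = sr.split_ratings(mat, seed=1)
        overlap = train.mask & test.mask
        assert not overlap.any()
        union = train.mask | test.mask
        assert np.array_equal(union, mat.mask)

    def test_temporal_split_holds_out_latest(self):
        values = np.array([[3.0, 4.0, 5.0, 2.0]])
        ts = np.array([[4.0, 3.0, 2.0, 1.0]])
        mat = sr.RatingsMatrix(values=values, user_ids=["u"],
                               item_ids=list("abcd"), timestamps=ts)
        train, test = sr.split_ratings(mat, test_fraction=0.25, seed=0,
                                       temporal=True)
        assert test.mask[0].tolist() == [True, False, False, False]

    def test_bad_fraction(self):
        mat = matrix_from_rows([[1.0, 2.0]])
        with pytest.raises(ValueError):
            sr.split_ratings(mat, test_fraction=0.0)


class TestPrecisionRecallAtN:
    def test_worked_counts(self):
        """3 of 4 recommended relevant, 6 relevant total -> P=0.75, R=0.5."""
        train_vals = np.full((1, 12), nan)
        test_vals = np.array([[5.0, 5.0, 5.0, 1.0, 5.0, 5.0, 5.0,
                               nan, nan, nan, nan, nan]])
        # force the ranking: items 0,1,2 relevant and item 3 not, via a
        # neighbor whose ratings order candidates 0>1>2>3>others
        neighbor = np.array([[5.0, 4.8, 4.6, 4.4, 1.0, 1.1, 1.2,
                              1.0, 1.0, 1.0, 1.0, 1.0]])
        values = np.vstack([train_vals, neighbor])
        train = sr.RatingsMatrix(values=values, user_ids=["u", "v"],
                                 item_ids=[f"i{j}" for j in range(12)])
        test = sr.RatingsMatrix(
            values=np.vstack([test_vals, np.full((1, 12), nan)]),
            user_ids=["u", "v"], item_ids=[f"i{j}" for j in range(12)])
        model = sr.UserCF(k_neighbors=1, method="cosine").fit(train)
        res = sr.precision_recall_at_n(model, test, n_grid=(4,))
        assert res.precision[4] == pytest.approx(0.75)
        assert res.recall[4] == pytest.approx(0.5)

    def test_recall_one_when_n_covers_all_relevant(self):
        mat = sr.gen_ratings(sr.SyntheticSpec(seed=3, n_users=10, n_items=12,
                                              density=0.9))
        train, test = sr.split_ratings(mat, seed=0)
        model = sr.UserCF().fit(train)
        res = sr.precision_recall_at_n(model, test, n_grid=(12,))
        assert res.recall[12] == pytest.approx(1.0)

    def test_empty_test_split_raises(self):
        train = matrix_from_rows([[4.0, nan]])
        empty = matrix_from_rows([[nan, nan]])
        model = sr.UserCF().fit(train)
        with pytest.raises(ValueError):
            sr.precision_recall_at_n(model, empty)

    def test_recall_non_decreasing_hits_non_decreasing(self):
        mat = sr.gen_ratings(sr.SyntheticSpec(seed=4, n_users=30, n_items=40,
                                              density=0.4))
        train, test = sr.split_ratings(mat, seed=2)
        model = sr.UserCF().fit(train)
        res = sr.precision_recall_at_n(model, test)
        rec = [res.recall[n] for n in res.n_grid]
        assert all(a <= b + 1e-12 for a, b in zip(rec, rec[1:]))
        for rows in res.per_user.values():
            hits = [p * n for n, p, _ in rows]
            assert all(a <= b + 1e-9 for a, b in zip(hits, hits[1:]))

    def test_random_recommender_matches_base_rate(self):
        """Random scores: expected precision@N equals the relevance rate of
        the candidate pool (averaged over 20 seeds)."""
        rng = np.random.default_rng(0)
        precisions, base_rates = [], []
        for _ in range(20):
            mat = sr.gen_ratings(sr.SyntheticSpec(
                seed=int(rng.integers(1 << 30)), n_users=30, n_items=60,
                density=0.5))
            train, test = sr.split_ratings(mat,
                                           seed=int(rng.integers(1 << 30)))
            model = sr.UserCF().fit(train)
            shuffler = np.random.default_rng(int(rng.integers(1 << 30)))
            model._score = lambda u, j, _r=shuffler: float(_r.random())
            res = sr.precision_recall_at_n(model, test, n_grid=(10,))
            precisions.append(res.precision[10])
            rates = []
            for u in range(test.n_users):
                cands = np.flatnonzero(~train.mask[u])
                rel = set(test.relevant_items(u))
                if rel:
                    rates.append(len(rel) / len(cands))
            base_rates.append(np.mean(rates))
        assert np.mean(precisions) == pytest.approx(np.mean(base_rates),
                                                    abs=0.02)
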