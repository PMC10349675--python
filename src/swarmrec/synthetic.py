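"""Synthetic input generators with planted, recoverable structure.

Every downstream stage (mining, selection, recommendation, text features,
actigraphy readers) is exercised on data produced here, so each generator
records its ground truth (latent factors, planted itemsets, signal words,
informative columns, group effect) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mining import TransactionDB
from .recommend import RatingsMatrix


class SpecValidationError(ValueError):
    """Raised when a :class:`SyntheticSpec` field is out of range."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Shapes and signal strengths for all generators; seed-deterministic."""

    seed: int = 0
    # ratings
    n_users: int = 50
    n_items: int = 100
    n_factors: int = 4
    noise_sd: float = 0.5
    density: float = 0.2
    # feature table
    n_features: int = 30
    n_informative: int = 5
    # corpus
    n_docs: int = 200
    vocab_size: int = 500
    n_signal: int = 10
    signal_strength: float = 2.0
    # actigraphy
    n_subjects: int = 10
    n_days: int = 3
    group_effect: float = 0.5

    def validate(self) -> None:
        for name in ("n_users", "n_items", "n_factors", "n_features",
                     "n_docs", "vocab_size", "n_subjects", "n_days"):
            if getattr(self, name) < 1:
                raise SpecValidationError(f"{name} must be >= 1")
        if not 0.0 < self.density <= 1.0:
            raise SpecValidationError("density must be in (0, 1]")
        if self.n_informative > self.n_features:
            raise SpecValidationError("n_informative must be <= n_features")
        if self.n_informative < 0:
            raise SpecValidationError("n_informative must be >= 0")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be >= 0")
        if self.vocab_size <= 2 * self.n_signal:
            raise SpecValidationError("vocab_size must exceed 2 * n_signal")
        if not 0.0 <= self.group_effect <= 1.0:
            raise SpecValidationError("group_effect must be in [0, 1]")


# ---------------------------------------------------------------------------
# ratings


def gen_ratings(spec: SyntheticSpec) -> RatingsMatrix:
    """Low-rank user x item ratings observed at ``density`` random cells.

    The full matrix is ``clip(round(u @ v.T + noise), 1, 5)``; latent
    factors are kept on the result as ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(0.6, 0.6, size=(spec.n_users, spec.n_factors))
    v = rng.normal(0.6, 0.6, size=(spec.n_items, spec.n_factors))
    full = u @ v.T
    # centre/scale so the 1..5 clip keeps useful spread
    full = 3.0 + 1.6 * (full - full.mean()) / (full.std() + 1e-12)
    full = full + rng.normal(0.0, spec.noise_sd, size=full.shape)
    full = np.clip(np.round(full), 1.0, 5.0)

    n_cells = spec.n_users * spec.n_items
    n_obs = int(round(spec.density * n_cells))
    chosen = rng.choice(n_cells, size=n_obs, replace=False)
    values = np.full((spec.n_users, spec.n_items), np.nan)
    rows, cols = np.unravel_index(chosen, values.shape)
    values[rows, cols] = full[rows, cols]

    ts = np.full(values.shape, np.nan)
    ts[rows, cols] = rng.integers(1_000_000, 2_000_000, size=n_obs)

    mat = RatingsMatrix(
        values=values,
        user_ids=[f"u{i}" for i in range(spec.n_users)],
        item_ids=[f"i{j}" for j in range(spec.n_items)],
        timestamps=ts,
    )
    mat.ground_truth = {"user_factors": u, "item_factors": v, "full": full}
    return mat


# ---------------------------------------------------------------------------
# transactions


def gen_transactions(
    n_transactions: int,
    planted_patterns: Sequence[tuple[Sequence[str], int]] = (),
    n_noise_items: int = 0,
    seed: int = 0,
    noise_prob: float = 0.3,
) -> TransactionDB:
    """Transactions containing each planted itemset at >= its frequency.

    Each planted ``(itemset, freq)`` is unioned into ``freq`` distinct
    random transactions; noise items are then added independently with
    probability ``noise_prob`` per (transaction, item) pair.
    """
    if n_transactions < 0:
        raise ValueError("n_transactions must be >= 0")
    rng = np.random.default_rng(seed)
    transactions: list[set[str]] = [set() for _ in range(n_transactions)]
    for itemset, freq in planted_patterns:
        if freq > n_transactions:
            raise ValueError(
                f"planted frequency {freq} exceeds n_transactions {n_transactions}"
            )
        slots = rng.choice(n_transactions, size=freq, replace=False)
        for s in slots:
            transactions[int(s)].update(itemset)
    noise_items = [f"noise{k}" for k in range(n_noise_items)]
    for t in transactions:
        for item in noise_items:
            if rng.random() < noise_prob:
                t.add(item)
    return TransactionDB([frozenset(t) for t in transactions])


# ---------------------------------------------------------------------------
# corpus


@dataclass
class LabelledCorpus:
    """Bag-of-words documents with binary labels and known signal words."""

    texts: list[str]
    labels: np.ndarray
    signal_words: list[str]
    vocab: list[str]

    def __len__(self) -> int:
        return len(self.texts)


def gen_corpus(spec: SyntheticSpec, doc_length: int = 60) -> LabelledCorpus:
    """Two balanced document classes from multinomial word distributions.

    The positive class up-weights ``n_signal`` designated words by a factor
    of ``1 + signal_strength``; ``signal_strength = 0`` makes the two
    class-conditional distributions identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = [f"word{k:04d}" for k in range(spec.vocab_size)]
    signal = vocab[: spec.n_signal]
    base = 1.0 / (1.0 + np.arange(spec.vocab_size))  # Zipf-ish tail
    base = base / base.sum()
    pos = base.copy()
    pos[: spec.n_signal] *= 1.0 + spec.signal_strength
    pos = pos / pos.sum()

    n_pos = spec.n_docs // 2
    labels = np.array([1] * n_pos + [0] * (spec.n_docs - n_pos))
    texts: list[str] = []
    for y in labels:
        probs = pos if y == 1 else base
        counts = rng.multinomial(doc_length, probs)
        words: list[str] = []
        for k in np.flatnonzero(counts):
            words.extend([vocab[k]] * int(counts[k]))
        rng.shuffle(words)
        texts.append(" ".join(words))
    return LabelledCorpus(texts=texts, labels=labels, signal_words=signal,
                          vocab=vocab)


# ---------------------------------------------------------------------------
# actigraphy


@dataclass
class ActigraphyBundle:
    """Per-subject minute-resolution activity plus a scores table.

    ``records`` maps subject id -> DataFrame with columns
    (timestamp, date, activity); ``scores`` carries one row per subject.
    """

    records: dict[str, pd.DataFrame]
    scores: pd.DataFrame

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.records if s.startswith("control")]

    @property
    def condition_ids(self) -> list[str]:
        return [s for s in self.records if s.startswith("condition")]


SCORES_COLUMNS = ["number", "days", "gender", "age", "afftype", "melanch",
                  "inpatient", "marriage", "work", "madrs1", "madrs2"]


def gen_actigraphy(spec: SyntheticSpec, amplitude: float = 200.0,
                   noise_sd: float = 10.0) -> ActigraphyBundle:
    """Diurnal sinusoid activity at one-minute resolution, two groups.

    Daytime activity of condition subjects is attenuated by
    ``group_effect``; Gaussian noise is added and values are truncated at
    zero. Half the subjects (rounded up) are controls.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_control = (spec.n_subjects + 1) // 2
    minutes = np.arange(spec.n_days * 1440)
    hour = (minutes % 1440) / 60.0
    # positive half-sinusoid: activity from 06:00 to 18:00, zero at night
    profile = amplitude * np.maximum(0.0, np.sin(2 * np.pi * (hour - 6.0) / 24.0))
    start = pd.Timestamp("2020-01-01 00:00:00")
    stamps = start + pd.to_timedelta(minutes, unit="m")

    records: dict[str, pd.DataFrame] = {}
    score_rows: list[dict] = []
    for s in range(spec.n_subjects):
        is_control = s < n_control
        name = f"control_{s + 1}" if is_control else f"condition_{s + 1 - n_control}"
        scale = 1.0 if is_control else 1.0 - spec.group_effect
        activity = profile * scale + rng.normal(0.0, noise_sd, size=profile.shape)
        activity = np.maximum(0.0, activity)
        records[name] = pd.DataFrame({
            "timestamp": stamps.strftime("%Y-%m-%d %H:%M:%S"),
            "date": stamps.strftime("%Y-%m-%d"),
            "activity": np.round(activity, 3),
        })
        madrs = (0, 0) if is_control else tuple(
            int(x) for x in rng.integers(18, 35, size=2))
        score_rows.append({
            "number": name,
            "days": spec.n_days,
            "gender": int(rng.integers(1, 3)),
            "age": f"{int(rng.integers(2, 7)) * 10}-{int(rng.integers(2, 7)) * 10 + 9}",
            "afftype": 0 if is_control else int(rng.integers(1, 4)),
            "melanch": int(rng.integers(1, 3)),
            "inpatient": int(rng.integers(1, 3)),
            "marriage": int(rng.integers(1, 3)),
            "work": int(rng.integers(1, 3)),
            "madrs1": madrs[0],
            "madrs2": madrs[1],
        })
    scores = pd.DataFrame(score_rows, columns=SCORES_COLUMNS)
    return ActigraphyBundle(records=records, scores=scores)


def daytime_mean(frame: pd.DataFrame, start_hour: int = 8,
                 end_hour: int = 18) -> float:
    """Mean activity between ``start_hour`` and ``end_hour`` local time."""
    hours = pd.to_datetime(frame["timestamp"]).dt.hour
    mask = (hours >= start_hour) & (hours < end_hour)
    return float(frame.loc[mask, "activity"].mean())


# ---------------------------------------------------------------------------
# feature table


@dataclass
class LabelledFeatures:
    """Numeric features with binary labels driven by known columns."""

    X: np.ndarray
    y: np.ndarray
    informative_idx: np.ndarray

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def gen_feature_table(n_samples: int, n_features: int, n_informative: int,
                      seed: int = 0, beta: float = 4.0) -> LabelledFeatures:
    """Standard-normal features; labels logistic in the informative columns.

    ``beta`` scales the coefficient magnitude (larger = cleaner signal);
    informative column indices are drawn at random and recorded.
    """
    if n_informative > n_features:
        raise SpecValidationError("n_informative must be <= n_features")
    if n_samples < 1 or n_features < 1:
        raise SpecValidationError("n_samples and n_features must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_features))
    informative = np.sort(rng.choice(n_features, size=n_informative,
                                     replace=False))
    if n_informative:
        coef = beta * rng.choice([-1.0, 1.0], size=n_informative)
        logits = X[:, informative] @ coef / np.sqrt(n_informative)
    else:
        logits = np.zeros(n_samples)
    y = (rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return LabelledFeatures(X=X, y=y, informative_idx=informative)
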