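"""Readers and writers for every on-disk format the toolkit touches.

Canonical dialects (all plain text, UTF-8):

* ratings       — CSV ``user_id,item_id,rating[,timestamp]``; header
                  autodetected; duplicate (user, item) keeps the last row.
* transactions  — one whitespace-separated itemset per line; duplicates
                  within a line collapse; blank lines are empty itemsets.
* actigraphy    — a directory of per-subject CSVs with columns
                  (timestamp, date, activity) plus ``scores.csv``.
* feature table — CSV of numeric columns ``f0..f{D-1}`` plus ``label``.
* corpus        — CSV with columns (text, label).
* edge list     — TSV ``src<TAB>dst<TAB>distance``.
* term weights  — MatrixMarket sparse matrix plus a terms index file.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .mining import ItemsetResult, TransactionDB
from .recommend import RatingsMatrix
from .synthetic import SCORES_COLUMNS, ActigraphyBundle, LabelledCorpus, LabelledFeatures
from .text import TermWeightMatrix

logger = logging.getLogger("swarmrec")


class FormatError(ValueError):
    """A file violated its column/row contract."""


# ---------------------------------------------------------------------------
# ratings


def read_ratings(path: str | Path, scale: tuple[float, float] = (1.0, 5.0),
                 relevance_threshold: float = 4.0) -> RatingsMatrix:
    path = Path(path)
    rows: list[tuple[str, str, float, float | None]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        lines = [r for r in reader]
    start = 0
    if lines and lines[0]:
        try:
            float(lines[0][2])
        except (ValueError, IndexError):
            start = 1  # header row
    for lineno, row in enumerate(lines[start:], start=start + 1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 fields, got {len(row)}")
        user, item = row[0].strip(), row[1].strip()
        if not user or not item:
            raise FormatError(f"{path}:{lineno}: empty user or item id")
        try:
            rating = float(row[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad rating {row[2]!r}") from exc
        ts = None
        if len(row) > 3 and row[3].strip():
            try:
                ts = float(row[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad timestamp {row[3]!r}") from exc
        rows.append((user, item, rating, ts))
    if not rows:
        warnings.warn(f"{path}: no ratings found; returning empty matrix")
        return RatingsMatrix(values=np.zeros((0, 0)), user_ids=[], item_ids=[],
                             scale=scale, relevance_threshold=relevance_threshold)
    users = sorted({r[0] for r in rows})
    items = sorted({r[1] for r in rows})
    uidx = {u: i for i, u in enumerate(users)}
    iidx = {it: j for j, it in enumerate(items)}
    values = np.full((len(users), len(items)), np.nan)
    stamps = np.full_like(values, np.nan)
    seen: set[tuple[str, str]] = set()
    for user, item, rating, ts in rows:
        if (user, item) in seen:
            warnings.warn(f"{path}: duplicate rating for ({user}, {item}); keeping last")
        seen.add((user, item))
        values[uidx[user], iidx[item]] = rating
        if ts is not None:
            stamps[uidx[user], iidx[item]] = ts
    return RatingsMatrix(values=values, user_ids=users, item_ids=items,
                         scale=scale, relevance_threshold=relevance_threshold,
                         timestamps=stamps)


def write_ratings(matrix: RatingsMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user_id", "item_id", "rating", "timestamp"])
        for u in range(matrix.n_users):
            for j in matrix.observed_items(u):
                ts = ""
                if matrix.timestamps is not None and not np.isnan(matrix.timestamps[u, j]):
                    ts = f"{matrix.timestamps[u, j]:.0f}"
                writer.writerow([matrix.user_ids[u], matrix.item_ids[int(j)],
                                 f"{matrix.values[u, j]:g}", ts])


# ---------------------------------------------------------------------------
# transactions


def read_transactions(path: str | Path) -> TransactionDB:
    path = Path(path)
    transactions = []
    for line in path.read_text().splitlines():
        transactions.append(frozenset(line.split()))
    return TransactionDB(transactions)


def write_transactions(db: TransactionDB, path: str | Path) -> None:
    Path(path).write_text(
        "".join(" ".join(sorted(t)) + "\n" for t in db))


def write_itemsets(results: Sequence[ItemsetResult], path: str | Path) -> None:
    """Mining output as TSV: comma-joined itemset, support."""
    with Path(path).open("w") as fh:
        fh.write("itemset\tsupport\n")
        for r in results:
            fh.write(",".join(sorted(r.itemset)) + f"\t{r.support}\n")


# ---------------------------------------------------------------------------
# actigraphy


ACTIGRAPHY_COLUMNS = ["timestamp", "date", "activity"]


def read_actigraphy(directory: str | Path) -> ActigraphyBundle:
    directory = Path(directory)
    scores_path = directory / "scores.csv"
    if not scores_path.exists():
        raise FormatError(f"missing scores table: {scores_path}")
    scores = pd.read_csv(scores_path)
    missing = [c for c in ("number", "days") if c not in scores.columns]
    if missing:
        raise FormatError(f"{scores_path}: missing required columns {missing}")
    records: dict[str, pd.DataFrame] = {}
    for csv_path in sorted(directory.glob("*.csv")):
        if csv_path.name == "scores.csv":
            continue
        frame = pd.read_csv(csv_path)
        absent = [c for c in ACTIGRAPHY_COLUMNS if c not in frame.columns]
        if absent:
            raise FormatError(f"{csv_path}: missing required columns {absent}")
        records[csv_path.stem] = frame[ACTIGRAPHY_COLUMNS]
    return ActigraphyBundle(records=records, scores=scores)


def write_actigraphy(bundle: ActigraphyBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.records.items():
        frame.to_csv(directory / f"{name}.csv", index=False)
    bundle.scores.to_csv(directory / "scores.csv", index=False)


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path: str | Path) -> LabelledFeatures:
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise FormatError(f"{path}: missing required column ['label']")
    feat_cols = [c for c in frame.columns if c != "label" and c != "informative"]
    informative = np.array([], dtype=int)
    if "informative" in frame.columns:
        flags = frame["informative"].to_numpy()[: len(feat_cols)]
        informative = np.flatnonzero(~pd.isna(flags) & (flags > 0))
    return LabelledFeatures(X=frame[feat_cols].to_numpy(dtype=float),
                            y=frame["label"].to_numpy(dtype=int),
                            informative_idx=informative)


def write_feature_table(data: LabelledFeatures, path: str | Path) -> None:
    frame = pd.DataFrame(data.X, columns=[f"f{j}" for j in range(data.n_features)])
    frame["label"] = data.y
    if len(frame) >= data.n_features:
        # informative flags ride along as a column: row j flags feature j
        flags = np.zeros(len(frame), dtype=int)
        is_inf = np.zeros(data.n_features, dtype=int)
        is_inf[data.informative_idx] = 1
        flags[: data.n_features] = is_inf
        frame["informative"] = flags
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# corpus


def read_corpus(path: str | Path) -> LabelledCorpus:
    frame = pd.read_csv(path, keep_default_na=False)
    for col in ("text", "label"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column ['{col}']")
    texts = [str(t) for t in frame["text"]]
    labels = frame["label"].to_numpy(dtype=int)
    vocab = sorted({w for t in texts for w in t.split()})
    return LabelledCorpus(texts=texts, labels=labels, signal_words=[],
                          vocab=vocab)


def write_corpus(corpus: LabelledCorpus, path: str | Path) -> None:
    pd.DataFrame({"text": corpus.texts, "label": corpus.labels}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# graphs


def read_edgelist(path: str | Path) -> list[tuple[str, str, float]]:
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        edges.append((parts[0], parts[1], float(parts[2])))
    return edges


def write_edgelist(edges: Sequence[tuple[str, str, float]],
                   path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for src, dst, dist in edges:
            fh.write(f"{src}\t{dst}\t{dist:g}\n")


# ---------------------------------------------------------------------------
# term weights


def write_tfidf(matrix: TermWeightMatrix, mtx_path: str | Path,
                terms_path: str | Path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.w))
    Path(terms_path).write_text("".join(t + "\n" for t in matrix.terms))


def read_tfidf(mtx_path: str | Path, terms_path: str | Path
               ) -> tuple[sp.csr_matrix, list[str]]:
    w = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    terms = [t for t in Path(terms_path).read_text().splitlines() if t]
    return w, terms
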