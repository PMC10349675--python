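"""Text preprocessing pipeline and TF-IDF term weighting.

The pipeline applies four operators in order: tokenize (maximal alphabetic
runs), transform case (lowercase), filter stopwords, and Porter-stem.
Term weights are raw count times the base-10 log of corpus size over
document frequency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from ._porter import porter_stem

_TOKEN_RE = re.compile(r"[A-Za-z]+")


def load_default_stopwords() -> frozenset[str]:
    """English stopword list shipped with the package (lowercase tokens)."""
    text = (
        resources.files("swarmrec.data").joinpath("stopwords_en.txt").read_text()
    )
    return frozenset(w for w in text.split() if w)


@dataclass(frozen=True)
class TokenPipelineConfig:
    """Configuration for :func:`preprocess`.

    Stopword filtering is applied after lowercasing (when enabled), so the
    stopword list is matched case-insensitively in the default setup.
    """

    lowercase: bool = True
    stopwords: frozenset[str] = field(default_factory=load_default_stopwords)
    stemmer: str | None = "porter"
    token_pattern: str = r"[A-Za-z]+"

    def __post_init__(self) -> None:
        if self.stemmer not in (None, "porter"):
            raise ValueError(f"unknown stemmer: {self.stemmer!r}")


def preprocess(text: str, config: TokenPipelineConfig | None = None) -> list[str]:
    """Tokenize, lowercase, remove stopwords and stem, preserving order."""
    if config is None:
        config = TokenPipelineConfig()
    pattern = (
        _TOKEN_RE
        if config.token_pattern == _TOKEN_RE.pattern
        else re.compile(config.token_pattern)
    )
    tokens = pattern.findall(text)
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    if config.stopwords:
        tokens = [t for t in tokens if t not in config.stopwords]
    if config.stemmer == "porter":
        tokens = [porter_stem(t) for t in tokens]
        # A stem can collide with a stopword ("doing" -> "do"); drop those
        # too so the pipeline is idempotent on its own output.
        if config.stopwords:
            tokens = [t for t in tokens if t not in config.stopwords]
    return tokens


@dataclass
class TermWeightMatrix:
    """TF-IDF weights with the raw counts they were derived from.

    ``w`` and ``tf`` are term x document sparse matrices; ``df`` holds the
    per-term document frequency and ``n_docs`` the corpus size.
    """

    terms: list[str]
    w: sp.csr_matrix
    tf: sp.csr_matrix
    df: np.ndarray
    n_docs: int

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def weight(self, term: str, doc: int) -> float:
        return float(self.w[self.term_index(term), doc])


def tfidf(corpus: Sequence[Iterable[str]]) -> TermWeightMatrix:
    """Weight each (term, document) pair by ``tf * log10(N / df)``.

    Terms never observed (df = 0) do not enter the vocabulary; a term
    present in every document gets weight 0 everywhere.
    """
    docs = [list(d) for d in corpus]
    if len(docs) == 0:
        raise ValueError("corpus must contain at least one document")
    vocab: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    for j, doc in enumerate(docs):
        for tok in doc:
            idx = vocab.setdefault(tok, len(vocab))
            rows.append(idx)
            cols.append(j)
    n_docs = len(docs)
    n_terms = len(vocab)
    tf = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_terms, n_docs)
    )
    tf.sum_duplicates()
    df = np.asarray((tf > 0).sum(axis=1)).ravel()
    idf = np.log10(n_docs / df) if n_terms else np.zeros(0)
    w = sp.csr_matrix(sp.diags(idf) @ tf) if n_terms else tf.copy()
    terms = [t for t, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
    return TermWeightMatrix(terms=terms, w=w, tf=tf, df=df, n_docs=n_docs)
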