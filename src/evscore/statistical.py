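"""Statistics-based evidence scores: term frequency, word order, TF-IDF.

All three scorers take preprocessed :class:`~evscore.text_prep.TermSequence`
inputs and return a similarity in [0, 1].  Empty inputs score 0 everywhere —
the QA setting never compares empty evidence, so 0 is the safe degenerate
value.

* frequency: multiset term overlap normalised by the longer text.
* order: Smith–Waterman local alignment over term sequences (exact-match
  scoring), normalised by the best attainable score of the shorter text.
* TF-IDF: cosine of smoothed TF-IDF vectors against corpus document
  frequencies.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParseError
from .text_prep import TermSequence, tokenize

__all__ = [
    "CorpusStats",
    "AlignmentParams",
    "frequency_score",
    "order_score",
    "tfidf_score",
    "build_corpus_stats",
]


@dataclass
class CorpusStats:
    """Document-frequency statistics of a background corpus.

    ``n_docs`` defaults to 18000, the corpus size the scoring pipeline is
    normally run against; ``df`` maps term -> number of documents containing
    it.
    """

    n_docs: int = 18000
    df: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        bad = [t for t, v in self.df.items() if v < 0 or v > self.n_docs]
        if bad:
            raise ValueError(f"df out of range for terms {bad[:3]}")

    def idf(self, term: str) -> float:
        """Smoothed inverse document frequency; unseen terms get df = 0."""
        return math.log((self.n_docs + 1) / (self.df.get(term, 0) + 1)) + 1.0

    # -- TSV serialisation: first line "n_docs\t<int>", then term\tdf -------

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"n_docs\t{self.n_docs}\n")
            for term in sorted(self.df):
                fh.write(f"{term}\t{self.df[term]}\n")

    @classmethod
    def from_tsv(cls, path) -> "CorpusStats":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) != 2 or header[0] != "n_docs":
                raise ParseError(f"{path}: expected 'n_docs\\t<int>' header")
            n_docs = int(header[1])
            df = {}
            for line_no, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 2:
                    raise ParseError(f"{path} line {line_no}: expected 2 columns")
                df[cols[0]] = int(cols[1])
        return cls(n_docs=n_docs, df=df)


def build_corpus_stats(corpus_dir, tokenizer_id: str = "whitespace",
                       stopwords=()) -> CorpusStats:
    """Compute document frequencies over a directory of UTF-8 text files."""
    stop = set(stopwords)
    files = sorted(f for f in os.listdir(corpus_dir)
                   if os.path.isfile(os.path.join(corpus_dir, f)))
    if not files:
        raise DataError(f"no documents found in {corpus_dir}")
    df: Counter = Counter()
    n = 0
    for name in files:
        with open(os.path.join(corpus_dir, name), encoding="utf-8") as fh:
            terms = {t.surface for t in tokenize(fh.read(), tokenizer_id)
                     if t.surface not in stop}
        if terms:
            n += 1
            df.update(terms)
    if n == 0:
        raise DataError(f"all documents in {corpus_dir} are empty")
    return CorpusStats(n_docs=n, df=dict(df))


@dataclass(frozen=True)
class AlignmentParams:
    """Local-alignment scoring: positive match, non-positive mismatch/gap."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


def frequency_score(q: TermSequence, p: TermSequence) -> float:
    """Shared-term frequency: multiset overlap over the longer text length."""
    if len(q) == 0 or len(p) == 0:
        return 0.0
    cq, cp = Counter(q.surfaces), Counter(p.surfaces)
    shared = sum((cq & cp).values())
    return shared / max(len(q), len(p))


def order_score(q: TermSequence, p: TermSequence,
                params: AlignmentParams = AlignmentParams()) -> float:
    """Word-order similarity by Smith–Waterman local alignment.

    The raw best local-alignment score (DP with cell floor 0, exact term
    match) is normalised by ``match * min(|q|, |p|)`` — the score of a
    perfect run of the shorter text — and clamped to [0, 1].
    """
    n, m = len(q), len(p)
    if n == 0 or m == 0:
        return 0.0
    a, b = q.surfaces, p.surfaces
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s,
                          H[i - 1, j] + params.gap,
                          H[i, j - 1] + params.gap)
            if H[i, j] > best:
                best = H[i, j]
    return min(1.0, max(0.0, best / (params.match * min(n, m))))


def tfidf_score(q: TermSequence, p: TermSequence, stats: CorpusStats) -> float:
    """Cosine similarity of smoothed TF-IDF vectors.

    tf is the raw within-text count; idf = ln((N+1)/(df+1)) + 1, so unseen
    terms still get a finite (large) weight rather than dividing by zero.
    """
    if len(q) == 0 or len(p) == 0:
        return 0.0
    vocab = sorted(set(q.surfaces) | set(p.surfaces))
    idf = np.array([stats.idf(t) for t in vocab])
    cq, cp = Counter(q.surfaces), Counter(p.surfaces)
    vq = np.array([cq.get(t, 0) for t in vocab], dtype=float) * idf
    vp = np.array([cp.get(t, 0) for t in vocab], dtype=float) * idf
    nq, np_ = np.linalg.norm(vq), np.linalg.norm(vp)
    if nq == 0.0 or np_ == 0.0:
        return 0.0
    return float(np.clip(vq @ vp / (nq * np_), 0.0, 1.0))
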