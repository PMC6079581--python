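"""Embedding-based semantic evidence score.

The semantic scorer maps each term of the proposition Q (length n) and the
passage P (length m) to an l-dimensional word vector, builds the n x m matrix
of pairwise cosine similarities, and greedily extracts min(n, m) maxima:
repeatedly take the global maximum of the matrix, break ties by the smallest
serial-number difference of the matched terms, record the value, and zero
the maximum's whole row and column.  The score is

    score(Q, P) = (sum of extracted maxima) / max(n, m)

which rewards one-to-one semantic matchings (including synonym pairs the
surface scorers miss) and penalises length mismatch.

Cosines are clamped to [0, 1]: the score normalisation assumes non-negative
maxima, and a negative cosine carries no evidence of similarity here.
Out-of-vocabulary terms map to the zero vector and thus similarity 0.

A bundled skip-gram / CBOW trainer with negative sampling
(:func:`train_embeddings`) produces embeddings for desk-scale corpora and is
deterministic under a fixed seed; production tables in the standard
plain-text embedding format (header line ``vocab_size dim``) can be loaded
with :meth:`EmbeddingTable.read_text`.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DimensionError, ParseError
from .text_prep import TermSequence, tokenize

__all__ = [
    "EmbeddingTable",
    "SemanticMatrix",
    "cosine",
    "build_similarity_matrix",
    "greedy_extract",
    "semantic_score",
    "train_embeddings",
]


@dataclass
class EmbeddingTable:
    """Term -> l-dimensional vector map with a fixed dimension."""

    dim: int = 300
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        for term, v in self.vectors.items():
            if len(v) != self.dim:
                raise DimensionError(
                    f"vector for {term!r} has length {len(v)}, expected {self.dim}")

    def vector(self, term: str) -> np.ndarray:
        """Vector for ``term``; out-of-vocabulary terms get the zero vector."""
        v = self.vectors.get(term)
        if v is None:
            return np.zeros(self.dim)
        return v

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    # -- plain-text embedding format (header "vocab_size dim") -------------

    def write_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for term in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[term])
                fh.write(f"{term} {vals}\n")

    @classmethod
    def read_text(cls, path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ParseError(f"{path}: expected 'vocab_size dim' header")
            n, dim = int(header[0]), int(header[1])
            vectors = {}
            for line_no, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ParseError(
                        f"{path} line {line_no}: expected {dim + 1} fields, "
                        f"got {len(parts)}")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != n:
            raise ParseError(f"{path}: header says {n} vectors, found {len(vectors)}")
        return cls(dim=dim, vectors=vectors)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity clamped to [0, 1]; zero-norm inputs score 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(f"vector lengths differ: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


@dataclass
class SemanticMatrix:
    """n x m cosine matrix with the serial numbers of the matched terms."""

    values: np.ndarray
    row_serials: list[int]
    col_serials: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_serials), len(self.col_serials)):
            raise DimensionError("matrix shape does not match serial annotations")


def build_similarity_matrix(q: TermSequence, p: TermSequence,
                            emb: EmbeddingTable) -> SemanticMatrix:
    """Pairwise term-cosine matrix of Q (rows) against P (columns)."""
    if len(q) == 0 or len(p) == 0:
        raise DataError("cannot build similarity matrix for empty text")
    values = np.zeros((len(q), len(p)))
    qvecs = [emb.vector(t.surface) for t in q]
    pvecs = [emb.vector(t.surface) for t in p]
    for i, u in enumerate(qvecs):
        for j, v in enumerate(pvecs):
            values[i, j] = cosine(u, v)
    return SemanticMatrix(values, q.serials, p.serials)


def greedy_extract(m: SemanticMatrix) -> list[float]:
    """Greedy maximum extraction with serial-distance tie-breaking.

    Runs exactly min(n, m) rounds.  Each round finds the global maximum of
    the current matrix; among equal maxima the cell minimising
    ``|row_serial - col_serial|`` wins, with lowest row index then lowest
    column index as final deterministic tie-breaks.  The chosen value is
    recorded and its entire row and column are zeroed.
    """
    vals = m.values.copy()
    n, mm = vals.shape
    rows = np.asarray(m.row_serials)
    cols = np.asarray(m.col_serials)
    out: list[float] = []
    for _ in range(min(n, mm)):
        mx = vals.max()
        ii, jj = np.nonzero(vals == mx)
        diffs = np.abs(rows[ii] - cols[jj])
        k = np.lexsort((jj, ii, diffs))[0]
        i, j = ii[k], jj[k]
        out.append(float(vals[i, j]))
        vals[i, :] = 0.0
        vals[:, j] = 0.0
    return out


def semantic_score(q: TermSequence, p: TermSequence,
                   emb: EmbeddingTable) -> float:
    """Sum of greedily extracted maxima over max(n, m); 0 for empty input."""
    if len(q) == 0 or len(p) == 0:
        return 0.0
    matrix = build_similarity_matrix(q, p, emb)
    maxima = greedy_extract(matrix)
    return min(1.0, sum(maxima) / max(len(q), len(p)))


# --------------------------------------------------------------------------
# bundled embedding trainer (skip-gram / CBOW with negative sampling)

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _read_corpus(corpus_dir, tokenizer_id):
    files = sorted(f for f in os.listdir(corpus_dir)
                   if os.path.isfile(os.path.join(corpus_dir, f)))
    docs = []
    for name in files:
        with open(os.path.join(corpus_dir, name), encoding="utf-8") as fh:
            surfaces = [t.surface for t in tokenize(fh.read(), tokenizer_id)]
        if surfaces:
            docs.append(surfaces)
    if not docs:
        raise DataError(f"no non-empty documents in {corpus_dir}")
    return docs


def train_embeddings(corpus_dir, dim: int = 300, mode: str = "skipgram",
                     window: int = 5, epochs: int = 3, seed: int = 0,
                     negative: int = 5, lr: float = 0.05, min_count: int = 1,
                     tokenizer_id: str = "whitespace") -> EmbeddingTable:
    """Train word vectors on a directory of text documents.

    A minimal single-threaded skip-gram / CBOW trainer with negative
    sampling, intended for desk-scale corpora; deterministic for a fixed
    seed.  Noise words are drawn from the unigram distribution raised to the
    3/4 power.
    """
    if mode not in ("skipgram", "cbow"):
        raise ValueError(f"mode must be 'skipgram' or 'cbow', got {mode!r}")
    docs = _read_corpus(corpus_dir, tokenizer_id)
    counts = Counter(t for doc in docs for t in doc)
    vocab = sorted((t for t, c in counts.items() if c >= min_count),
                   key=lambda t: (-counts[t], t))
    if not vocab:
        raise DataError("corpus has no terms above min_count")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W = (rng.random((V, dim)) - 0.5) / dim   # input vectors
    C = np.zeros((V, dim))                    # output (context) vectors

    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    def draw_negatives(k):
        return np.searchsorted(noise_cdf, rng.random(k))

    for _ in range(epochs):
        for doc in docs:
            ids = [index[t] for t in doc if t in index]
            L = len(ids)
            for pos, center in enumerate(ids):
                lo = max(0, pos - window)
                hi = min(L, pos + window + 1)
                context = [ids[k] for k in range(lo, hi) if k != pos]
                if not context:
                    continue
                if mode == "skipgram":
                    for ctx in context:
                        targets = np.concatenate(([ctx], draw_negatives(negative)))
                        labels = np.zeros(len(targets))
                        labels[0] = 1.0
                        g = lr * (labels - _sigmoid(C[targets] @ W[center]))
                        dW = g @ C[targets]
                        C[targets] += np.outer(g, W[center])
                        W[center] += dW
                else:  # cbow: mean of context predicts the center word
                    h = W[context].mean(axis=0)
                    targets = np.concatenate(([center], draw_negatives(negative)))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    g = lr * (labels - _sigmoid(C[targets] @ h))
                    dh = g @ C[targets]
                    C[targets] += np.outer(g, h)
                    W[context] += dh / len(context)

    return EmbeddingTable(dim=dim, vectors={t: W[index[t]].copy() for t in vocab})
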