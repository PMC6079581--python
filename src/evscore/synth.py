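"""Synthetic corpora, embeddings, QA fixtures and labeled score datasets.

Everything the scoring stack consumes can be generated here with known
statistical structure and no external resources:

* :func:`make_vocabulary` — synonym-cluster vocabularies whose embedding
  table has controllable within-cluster and between-cluster cosine, so the
  semantic scorer's synonym matching can be exercised deterministically.
* :func:`make_corpus` — topic-coherent document collections plus matching
  document-frequency statistics for the TF-IDF scorer.
* :func:`make_qa_fixture` — a proposition Q and four evidence passages
  mirroring the canonical medical example: P4 a near-duplicate of Q, P3 a
  full synonym paraphrase, P2 sharing only the symptom cluster, P1 sharing
  only the topic cluster.  A well-behaved scorer stack must rank
  min{S(Q,P4), S(Q,P3)} above max{S(Q,P2), S(Q,P1)}.
* :func:`make_labeled_dataset` — (feature-vector, score) records labeled by
  a known teacher network, turning the fusion trainer's quality into a
  recoverable parameter-estimation property.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import fusion
from .errors import DataError, GenerationError
from .semantic import EmbeddingTable
from .statistical import CorpusStats
from .syntactic import DependencyTree, DepNode, dependency_to_structure
from .text_prep import TermSequence, Token

__all__ = [
    "SynonymVocabulary",
    "QaFixture",
    "make_vocabulary",
    "make_corpus",
    "make_qa_fixture",
    "make_labeled_dataset",
    "make_calibrated_teacher",
    "make_ablation_dataset",
    "chain_tree",
    "write_fixtures_jsonl",
    "read_fixtures_jsonl",
]


@dataclass
class SynonymVocabulary:
    """Disjoint synonym clusters with an embedding table honouring them."""

    clusters: list[list[str]]
    embedding: EmbeddingTable
    intra_cos: float
    inter_cos: float

    def cluster_of(self, term: str) -> int:
        for k, cl in enumerate(self.clusters):
            if term in cl:
                return k
        raise KeyError(term)


def _cluster_cosines(vectors: list[np.ndarray]) -> np.ndarray:
    M = np.array(vectors)
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    return M @ M.T


def make_vocabulary(n_clusters: int = 12, cluster_size: int = 4,
                    dim: int = 64, intra_cos: float = 0.9,
                    inter_cos: float = 0.1, seed: int = 0,
                    max_tries: int = 100) -> SynonymVocabulary:
    """Build synonym clusters around mutually orthogonal base directions.

    Cluster members are unit vectors ``c*base + s*noise`` with the mixing
    chosen so empirical within-cluster cosine stays >= ``intra_cos`` while
    between-cluster cosine stays <= ``inter_cos``; the construction is
    verified and resampled up to ``max_tries`` times before giving up.
    """
    if not (0.0 <= inter_cos < intra_cos <= 1.0):
        raise ValueError(
            f"need 0 <= inter_cos < intra_cos <= 1, got {inter_cos}, {intra_cos}")
    if dim < n_clusters + 2:
        raise ValueError("dim must exceed n_clusters for orthogonal bases "
                         "plus noise directions")
    rng = np.random.default_rng(seed)
    # mixing: within-cluster cosine concentrates near c^2, kept above target;
    # noise lives orthogonal to every base, bounding cross-cluster cosine
    # by s^2 = (1 - intra)/2, well under any inter target above that
    c2 = min(1.0, (1.0 + intra_cos) / 2.0)
    c, s = np.sqrt(c2), np.sqrt(1.0 - c2)

    for _ in range(max_tries):
        basis, _ = np.linalg.qr(rng.standard_normal((dim, n_clusters)))
        clusters: list[list[str]] = []
        vectors: dict[str, np.ndarray] = {}
        ok = True
        for k in range(n_clusters):
            base = basis[:, k]
            members = []
            for i in range(cluster_size):
                noise = rng.standard_normal(dim)
                noise -= basis @ (basis.T @ noise)
                noise /= np.linalg.norm(noise)
                vec = c * base + s * noise
                term = f"c{k:02d}w{i}"
                members.append(term)
                vectors[term] = vec
            clusters.append(members)
        all_vecs = [vectors[t] for cl in clusters for t in cl]
        G = np.clip(_cluster_cosines(all_vecs), 0.0, 1.0)
        sizes = [len(cl) for cl in clusters]
        offsets = np.cumsum([0] + sizes)
        for k in range(n_clusters):
            a, b = offsets[k], offsets[k + 1]
            block = G[a:b, a:b]
            if block.size > 1 and block[~np.eye(b - a, dtype=bool)].min() < intra_cos:
                ok = False
            G[a:b, a:b] = 0.0
        if ok and (G.max() if n_clusters > 1 else 0.0) <= inter_cos:
            emb = EmbeddingTable(dim=dim, vectors=vectors)
            return SynonymVocabulary(clusters, emb, intra_cos, inter_cos)
        rng = np.random.default_rng(rng.integers(2 ** 31))
    raise GenerationError(
        f"could not satisfy intra_cos={intra_cos}, inter_cos={inter_cos} "
        f"after {max_tries} tries")


def make_corpus(vocab: SynonymVocabulary, n_docs: int = 18000,
                doc_len: int = 30, seed: int = 0,
                out_dir=None) -> tuple[list[list[str]], CorpusStats]:
    """Topic-coherent documents plus matching document-frequency stats.

    Each document picks one cluster as its topic and draws 60% of its terms
    from it, 40% uniformly from the whole vocabulary.  When ``out_dir`` is
    given, documents are additionally written as ``doc_00000.txt`` ...
    (space-separated terms, one doc per file).
    """
    if n_docs < 1:
        raise DataError("n_docs must be >= 1")
    rng = np.random.default_rng(seed)
    all_terms = [t for cl in vocab.clusters for t in cl]
    docs: list[list[str]] = []
    df: dict[str, int] = {}
    for _ in range(n_docs):
        topic = rng.integers(len(vocab.clusters))
        terms = []
        for _ in range(doc_len):
            if rng.random() < 0.6:
                cl = vocab.clusters[topic]
                terms.append(cl[rng.integers(len(cl))])
            else:
                terms.append(all_terms[rng.integers(len(all_terms))])
        docs.append(terms)
        for t in set(terms):
            df[t] = df.get(t, 0) + 1
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i, terms in enumerate(docs):
            with open(os.path.join(out_dir, f"doc_{i:05d}.txt"), "w",
                      encoding="utf-8") as fh:
                fh.write(" ".join(terms) + "\n")
    return docs, CorpusStats(n_docs=n_docs, df=df)


# --------------------------------------------------------------------------
# QA fixtures

def chain_tree(surfaces: list[str], roles: list[str]) -> DependencyTree:
    """Right-headed chain dependency: token i depends on i+1, last is root.

    Relation labels carry the slot roles, so structure trees derived from
    two chains agree exactly where their role sequences agree.
    """
    n = len(surfaces)
    nodes = [DepNode(serial=i + 1, surface=surfaces[i], pos_tag=None,
                     head_serial=(i + 2 if i + 1 < n else 0),
                     relation_label=roles[i])
             for i in range(n)]
    return DependencyTree(nodes)


def _seq(surfaces: list[str], source_id: str) -> TermSequence:
    return TermSequence(tuple(Token(s, i + 1) for i, s in enumerate(surfaces)),
                        source_id=source_id)


@dataclass
class QaFixture:
    """One proposition with four designed evidence passages.

    Passage tags: P1 topic-shared/symptom-changed, P2 symptom-shared/
    topic-changed, P3 full synonym paraphrase, P4 near-duplicate.  P3 and P4
    are the relevant passages; the expected ordering constraint is
    min{S(Q,P4), S(Q,P3)} > max{S(Q,P2), S(Q,P1)}.
    """

    q: TermSequence
    passages: list[TermSequence]            # P1, P2, P3, P4
    tags: list[str] = field(default_factory=lambda: ["P1", "P2", "P3", "P4"])
    q_roles: list[str] = field(default_factory=list)
    passage_roles: list[list[str]] = field(default_factory=list)
    relevant: list[bool] = field(default_factory=lambda: [False, False, True, True])

    @property
    def q_tree(self) -> DependencyTree:
        return chain_tree(self.q.surfaces, self.q_roles)

    def passage_tree(self, idx: int) -> DependencyTree:
        return chain_tree(self.passages[idx].surfaces, self.passage_roles[idx])


def make_qa_fixture(vocab: SynonymVocabulary, seed: int = 0) -> QaFixture:
    """Instantiate the four passage recipes from a synonym vocabulary.

    Content slots (topic, time, symptom, tail) come from four distinct
    clusters; two filler terms act as shared function-word scaffolding in Q
    and every passage.  P1/P2 carry extra distractor terms, making them
    longer and off-topic the way real competing evidence passages are.
    """
    if len(vocab.clusters) < 6:
        raise DataError("make_qa_fixture needs a vocabulary with >= 6 clusters")
    if any(len(cl) < 2 for cl in vocab.clusters[:5]):
        raise DataError("clusters need >= 2 members for synonym paraphrases")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(vocab.clusters))

    def pick_two(cluster_idx):
        cl = vocab.clusters[cluster_idx]
        i, j = rng.choice(len(cl), size=2, replace=False)
        return cl[i], cl[j]

    topic_a, topic_b = pick_two(order[0])
    time_a, time_b = pick_two(order[1])
    symp_a, symp_b = pick_two(order[2])
    tail_a, tail_b = pick_two(order[3])
    fill_cl = vocab.clusters[order[4]]
    f1, f2 = fill_cl[0], fill_cl[1]
    f_ins = fill_cl[2] if len(fill_cl) > 2 else fill_cl[0]

    distract_clusters = [vocab.clusters[k] for k in order[5:]]
    d_iter = iter(
        distract_clusters[i % len(distract_clusters)][
            (i // len(distract_clusters)) % len(distract_clusters[i % len(distract_clusters)])]
        for i in range(64))

    q_surf = [topic_a, time_a, f1, f2, symp_a, tail_a]
    q_roles = ["topic", "time", "fill", "fill", "symp", "tail"]

    p4_surf = [topic_a, time_a, f1, f_ins, f2, symp_a, tail_a]
    p4_roles = ["topic", "time", "fill", "fill", "fill", "symp", "tail"]

    p3_surf = [topic_b, time_b, f1, f2, symp_b, tail_b]
    p3_roles = list(q_roles)

    d = [next(d_iter) for _ in range(10)]
    p1_surf = [topic_a, d[0], f1, f2, d[1], d[2], d[3], d[4]]
    p1_roles = ["topic", "dist", "fill", "fill", "dist", "dist", "dist", "dist"]
    p2_surf = [d[5], d[6], f1, f2, symp_a, d[7], d[8], d[9]]
    p2_roles = ["dist", "dist", "fill", "fill", "symp", "dist", "dist", "dist"]

    return QaFixture(
        q=_seq(q_surf, "Q"),
        passages=[_seq(p1_surf, "P1"), _seq(p2_surf, "P2"),
                  _seq(p3_surf, "P3"), _seq(p4_surf, "P4")],
        q_roles=q_roles,
        passage_roles=[p1_roles, p2_roles, p3_roles, p4_roles],
    )


def write_fixtures_jsonl(fixtures: list[QaFixture], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fx in fixtures:
            rec = {"q": fx.q.surfaces, "q_roles": fx.q_roles,
                   "passages": [p.surfaces for p in fx.passages],
                   "passage_roles": fx.passage_roles,
                   "tags": fx.tags, "relevant": fx.relevant}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_fixtures_jsonl(path) -> list[QaFixture]:
    fixtures = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            fixtures.append(QaFixture(
                q=_seq(rec["q"], "Q"),
                passages=[_seq(s, tag) for s, tag in zip(rec["passages"], rec["tags"])],
                tags=rec["tags"],
                q_roles=rec["q_roles"],
                passage_roles=rec["passage_roles"],
                relevant=rec["relevant"],
            ))
    return fixtures


# --------------------------------------------------------------------------
# labeled score datasets

def make_calibrated_teacher(seed: int = 0,
                            target_range=(0.1, 0.9)) -> fusion.FusionNetwork:
    """A random fusion network whose outputs span roughly ``target_range``.

    Raw random networks centre their outputs near 0, which a [0, 1] label
    scale would clamp away; rescaling the output layer affinely keeps the
    teacher within the label range so labels behave like human similarity
    grades.
    """
    net = build = fusion.build_network(seed)
    rng = np.random.default_rng(seed + 1)
    P = rng.random((2048, 6))
    s = fusion.predict(net, (P, np.zeros(len(P))))
    lo, hi = float(s.min()), float(s.max())
    span = hi - lo if hi > lo else 1.0
    a = (target_range[1] - target_range[0]) / span
    b = target_range[0] - a * lo
    out = net.copy()
    out.lam = net.lam * a
    out.theta_out = float(a * net.theta_out - b)
    return out


def make_labeled_dataset(teacher: fusion.FusionNetwork, n_train: int = 12000,
                         n_test: int = 4000, noise_sd: float = 0.02,
                         seed: int = 0):
    """Teacher-labeled datasets: features uniform on [0,1]^6, labels
    clamp(teacher(features) + N(0, noise_sd), 0, 1).

    Returns ``((P_train, y_train), (P_test, y_test))`` arrays.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    def draw(n):
        P = rng.random((n, 6))
        if n == 0:
            return P, np.zeros(0)
        s = fusion.predict(teacher, (P, np.zeros(n)))
        y = np.clip(s + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else s,
                    0.0, 1.0)
        return P, y

    return draw(n_train), draw(n_test)


def make_ablation_dataset(active, n: int = 3000, noise_sd: float = 0.02,
                          seed: int = 0):
    """Labels = mean of the active features (+ noise), inactive features 0.

    A monotone annotator proxy: the more the active scorers agree that two
    texts match, the higher the labeled score.
    """
    active = np.asarray(active, dtype=bool)
    if active.shape != (6,):
        raise ValueError("active mask must have 6 entries")
    if not active.any():
        raise DataError("at least one feature must be active")
    rng = np.random.default_rng(seed)
    P = rng.random((n, 6))
    P[:, ~active] = 0.0
    y = P[:, active].mean(axis=1)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    return P, np.clip(y, 0.0, 1.0)
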