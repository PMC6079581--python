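"""End-to-end scoring harness: feature extraction, fusion, ablation, P/R/F.

The harness wires the six scorers and the fusion network together behind a
single :class:`ScoringContext`.  Scorers are pure functions, so results are
identical whether they run sequentially or in parallel; the harness runs
them sequentially.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml
from sklearn.metrics import precision_recall_fscore_support

from . import fusion
from .errors import ConfigError, DataError
from .semantic import EmbeddingTable, semantic_score
from .statistical import (AlignmentParams, CorpusStats, frequency_score,
                          order_score, tfidf_score)
from .syntactic import (DependencyTree, dependency_to_structure,
                        structure_score, syntax_score)
from .synth import QaFixture, make_ablation_dataset
from .text_prep import TermSequence, preprocess, tokenize

__all__ = [
    "SCORER_IDS",
    "RunConfig",
    "ScoringContext",
    "compute_features",
    "score_pair",
    "AblationReport",
    "run_ablation",
    "eval_feature_prf",
]

#: fixed feature order p1..p6
SCORER_IDS = ("frequency", "order", "tfidf", "syntax", "structure", "semantic")


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-serialisable)."""

    corpus_stats_path: Optional[str] = None
    embeddings_path: Optional[str] = None
    network_path: Optional[str] = None
    tokenizer_id: str = "whitespace"
    stopwords_path: Optional[str] = None
    toggles: dict = field(default_factory=lambda: {s: True for s in SCORER_IDS})
    alignment: dict = field(default_factory=lambda: {"match": 1.0,
                                                     "mismatch": -1.0,
                                                     "gap": -1.0})
    kernel_decay: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScoringContext:
    """Loaded resources plus scorer toggles for one scoring run."""

    stats: Optional[CorpusStats] = None
    emb: Optional[EmbeddingTable] = None
    network: Optional[fusion.FusionNetwork] = None
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    kernel_decay: float = 0.5
    stopwords: frozenset = frozenset()
    tokenizer_id: str = "whitespace"
    toggles: tuple = (True,) * 6

    def enabled(self, idx: int) -> bool:
        return bool(self.toggles[idx])


def compute_features(ctx: ScoringContext, q: TermSequence, p: TermSequence,
                     q_tree: Optional[DependencyTree] = None,
                     p_tree: Optional[DependencyTree] = None):
    """The six feature scores plus per-scorer provenance flags.

    Disabled scorers contribute 0 and are flagged ``"disabled"``; the two
    syntactic scorers contribute 0 flagged ``"no_parse"`` when either parse
    is missing (the fusion layer learns around absent features).  An enabled
    scorer whose required resource is missing raises :class:`ConfigError`.
    """
    values = np.zeros(6)
    flags = {s: "ok" for s in SCORER_IDS}

    if ctx.enabled(0):
        values[0] = frequency_score(q, p)
    else:
        flags["frequency"] = "disabled"

    if ctx.enabled(1):
        values[1] = order_score(q, p, ctx.alignment)
    else:
        flags["order"] = "disabled"

    if ctx.enabled(2):
        if ctx.stats is None:
            raise ConfigError("tfidf scorer enabled but no corpus stats loaded")
        values[2] = tfidf_score(q, p, ctx.stats)
    else:
        flags["tfidf"] = "disabled"

    for idx, name in ((3, "syntax"), (4, "structure")):
        if not ctx.enabled(idx):
            flags[name] = "disabled"
        elif q_tree is None or p_tree is None:
            flags[name] = "no_parse"
        elif idx == 3:
            values[3] = syntax_score(q_tree, p_tree)
        else:
            values[4] = structure_score(dependency_to_structure(q_tree),
                                        dependency_to_structure(p_tree),
                                        ctx.kernel_decay)

    if ctx.enabled(5):
        if ctx.emb is None:
            raise ConfigError("semantic scorer enabled but no embeddings loaded")
        values[5] = semantic_score(q, p, ctx.emb)
    else:
        flags["semantic"] = "disabled"

    return values, flags


def _fuse(ctx: ScoringContext, values: np.ndarray) -> float:
    """Fusion forward pass; with no trained network, the transparent
    fallback is the mean of the enabled features."""
    if ctx.network is not None:
        return fusion.forward(ctx.network,
                              fusion.FeatureVector.from_array(np.clip(values, 0, 1)))
    active = np.asarray(ctx.toggles, dtype=bool)
    if not active.any():
        return 0.0
    return float(values[active].mean())


def score_pair(ctx: ScoringContext, q_text: str, p_text: str,
               q_tree: Optional[DependencyTree] = None,
               p_tree: Optional[DependencyTree] = None) -> dict:
    """Preprocess, score all enabled features, fuse; returns a JSON-able dict."""
    q = preprocess(tokenize(q_text, ctx.tokenizer_id, "Q"), ctx.stopwords)
    p = preprocess(tokenize(p_text, ctx.tokenizer_id, "P"), ctx.stopwords)
    values, flags = compute_features(ctx, q, p, q_tree, p_tree)
    s = _fuse(ctx, values)
    out = {f"p{i + 1}": float(values[i]) for i in range(6)}
    out["S"] = float(s)
    out["flags"] = flags
    return out


# --------------------------------------------------------------------------
# ablation harness

POINT_LABELS = ("A", "B", "C", "D", "E", "F", "G")


@dataclass
class AblationReport:
    """Top-1 answer-selection accuracy as scorers are cumulatively enabled.

    Point A uses no scorer (random selection, chance = 1/4 on four-passage
    fixtures); B..G add frequency, order, TF-IDF, syntax, structure and
    semantics in that order.
    """

    points: list  # [(label, accuracy), ...] in order A..G

    def as_dict(self) -> dict:
        return {label: acc for label, acc in self.points}


def _fixture_features(ctx: ScoringContext, fx: QaFixture) -> np.ndarray:
    """(4, 6) full feature matrix for one fixture (all scorers on)."""
    full = ScoringContext(stats=ctx.stats, emb=ctx.emb, network=None,
                          alignment=ctx.alignment, kernel_decay=ctx.kernel_decay,
                          toggles=(True,) * 6)
    rows = []
    for i in range(4):
        vals, _ = compute_features(full, fx.q, fx.passages[i],
                                   fx.q_tree, fx.passage_tree(i))
        rows.append(vals)
    return np.array(rows)


def run_ablation(ctx: ScoringContext, fixtures: list[QaFixture],
                 seed: int = 0, n_train: int = 3000, epochs: int = 300,
                 lr: float = 0.5, noise_sd: float = 0.02) -> AblationReport:
    """Cumulative-scorer experiment over a set of QA fixtures.

    For each point B..G the fusion network is retrained on synthetic labels
    restricted to the active features, then each fixture's best-scoring
    passage is selected; accuracy is the fraction of fixtures whose designed
    best passage (P4) ranks first.
    """
    if len(fixtures) < 20:
        raise DataError(f"ablation needs >= 20 fixtures, got {len(fixtures)}")
    rng = np.random.default_rng(seed)
    feats = np.array([_fixture_features(ctx, fx) for fx in fixtures])  # (F,4,6)

    points = []
    # point A: no scorers — random tie-break among the four passages
    picks = rng.integers(0, 4, size=len(fixtures))
    points.append(("A", float(np.mean(picks == 3))))

    for k in range(1, 7):
        active = np.zeros(6, dtype=bool)
        active[:k] = True
        P, y = make_ablation_dataset(active, n=n_train, noise_sd=noise_sd,
                                     seed=seed + k)
        net = fusion.train(fusion.build_network(seed + k), (P, y), lr=lr,
                           epochs=epochs, seed=seed + k, batch_size=256,
                           momentum=0.9)
        masked = feats.copy()
        masked[:, :, ~active] = 0.0
        scores = np.array([
            [fusion.forward(net, fusion.FeatureVector.from_array(
                np.clip(masked[f, i], 0, 1))) for i in range(4)]
            for f in range(len(fixtures))])
        acc = float(np.mean(np.argmax(scores, axis=1) == 3))
        points.append((POINT_LABELS[k], acc))
    return AblationReport(points)


# --------------------------------------------------------------------------
# per-feature precision / recall / F-measure

def eval_feature_prf(ctx: ScoringContext, scorer_id: str,
                     fixtures: list[QaFixture],
                     threshold: float = 0.5) -> tuple[float, float, float]:
    """Treat ``scorer >= threshold`` as a relevance prediction on fixture
    passages (P3/P4 relevant, P1/P2 not) and report precision, recall, F1."""
    if scorer_id not in SCORER_IDS:
        raise ConfigError(f"unknown scorer {scorer_id!r}; known: {SCORER_IDS}")
    idx = SCORER_IDS.index(scorer_id)
    truth, pred = [], []
    for fx in fixtures:
        vals = _fixture_features(ctx, fx)
        for i in range(4):
            truth.append(bool(fx.relevant[i]))
            pred.append(vals[i, idx] >= threshold)
    if not any(truth):
        raise DataError("no relevant passages in fixtures: recall undefined")
    p, r, f, _ = precision_recall_fscore_support(
        truth, pred, average="binary", zero_division=0.0)
    return float(p), float(r), float(f)
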