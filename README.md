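# evscore

Multi-feature evidence scoring for question answering.

In an evidence-based QA system, a *proposition* Q (user question + candidate
answer) is checked against retrieved *evidence passages* P: the more strongly
a passage matches the proposition, the more it supports the candidate
answer.  A single similarity measure handles this badly — surface overlap
misses synonym paraphrases, while purely semantic measures miss word order
and structure.  `evscore` scores each (Q, P) pair with six complementary
text-similarity features and fuses them with a small neural network into one
evidence score S, for ranking candidate answers in medical (and other) QA
pipelines.  Chinese input is supported through a pluggable tokenizer; all
scorers operate on language-agnostic term sequences.

## The six features

For preprocessed term sequences Q = {t₁…tₙ}, P = {s₁…sₘ} (each term keeps
the serial number of its original sentence position):

1. **Frequency** — multiset term overlap, Σₜ min(cnt_Q(t), cnt_P(t)) / max(n, m).
2. **Word order** — Smith–Waterman local alignment over terms
   (match +1, mismatch −1, gap −1, cell floor 0), normalised by the best
   attainable score of the shorter text.
3. **TF-IDF** — cosine of smoothed TF-IDF vectors,
   idf = ln((N+1)/(df+1)) + 1 against a background corpus (default N = 18000).
4. **Syntax** — Jaccard overlap of dependency triples
   (head, relation, dependent) from CoNLL-U parses.
5. **Structure** — normalised convolution tree kernel on relation-labelled
   structure trees: Δ(n₁,n₂) = λ·Π(1 + Δ(childᵢ, childⱼ)) for matching
   productions, decay λ = 0.5.
6. **Semantics** — word-embedding matching: build the n×m matrix
   V[i,j] = cos(vec(tᵢ), vec(sⱼ)) (clamped to [0,1]), greedily extract
   min(n, m) global maxima — ties broken by smallest serial-number
   difference — zeroing the row and column of each pick, then
   score = Σ maxima / max(n, m).  This matches synonyms (e.g. 怀孕/妊娠)
   that every surface feature misses.

## The fusion network

The feature vector {p₁…p₆} feeds a deliberately sparse two-hidden-layer
network: hidden layer H1 has one sigmoid node per non-empty feature subset
(C(6,1)+…+C(6,6) = 63 nodes, each wired only to its subset), H2 has six
sigmoid nodes, one per subset cardinality (node i sees the C(6,i)
cardinality-i nodes), and the output is linear:
S = λ₁A + λ₂B + … + λ₆F − θ.  The network has exactly 70 thresholds and a
few hundred weights, trained by backpropagation on mean squared error with
the connectivity mask enforced.

A bundled skip-gram/CBOW trainer with negative sampling produces word
embeddings (default dimension 300) for desk-scale corpora; standard
plain-text embedding files load directly.  Synthetic generators
(`evscore.synth`) produce synonym-cluster vocabularies with controlled
cosine structure, topic-coherent corpora, teacher-labeled score datasets
(12000 train / 4000 test), and four-passage QA fixtures for end-to-end
evaluation.

## Worked example

Score a proposition against four designed passages (P4 near-duplicate,
P3 synonym paraphrase, P2 shares only the symptom cluster, P1 only the
topic cluster).  Terms like `c08w1` are synthetic vocabulary items; `c08w0`
is a synonym of `c08w1` (same cluster):

```python
from evscore import synth, fusion
from evscore.pipeline import ScoringContext, score_pair

vocab = synth.make_vocabulary(seed=3)
_, stats = synth.make_corpus(vocab, n_docs=300, seed=3)
P, y = synth.make_ablation_dataset([True] * 6, n=3000, seed=11)
net = fusion.train(fusion.build_network(11), (P, y), lr=0.5, epochs=300,
                   seed=11, batch_size=256, momentum=0.9)
ctx = ScoringContext(stats=stats, emb=vocab.embedding, network=net)

fx = synth.make_qa_fixture(vocab, seed=17)
for tag, passage in zip(fx.tags, fx.passages):
    out = score_pair(ctx, " ".join(fx.q.surfaces), " ".join(passage.surfaces),
                     q_tree=fx.q_tree, p_tree=fx.passage_tree(fx.tags.index(tag)))
    print(tag, {k: round(v, 3) for k, v in out.items() if k != "flags"})
```

prints

```
P1 {'p1': 0.375, 'p2': 0.333, 'p3': 0.437, 'p4': 0.091, 'p5': 0.158, 'p6': 0.379, 'S': 0.3}
P2 {'p1': 0.375, 'p2': 0.5,   'p3': 0.425, 'p4': 0.2,   'p5': 0.197, 'p6': 0.378, 'S': 0.35}
P3 {'p1': 0.333, 'p2': 0.333, 'p3': 0.329, 'p4': 0.111, 'p5': 1.0,   'p6': 0.963, 'S': 0.516}
P4 {'p1': 0.857, 'p2': 0.833, 'p3': 0.921, 'p4': 0.571, 'p5': 0.875, 'p6': 0.857, 'S': 0.809}
```

P4 (near-duplicate) wins on every feature; P3 (synonym paraphrase) loses on
every *surface* feature yet its structure (p₅) and semantic (p₆) scores push
its fused score above both distractors, so
min{S(Q,P4), S(Q,P3)} > max{S(Q,P2), S(Q,P1)} — the ordering a sound
evidence scorer must produce.

A CLI wraps the same pipeline: `evscore score`, `evscore train-embeddings`,
`evscore build-stats`, `evscore train-fusion`, `evscore ablate`,
`evscore eval`, `evscore generate` (run `evscore --help`).

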