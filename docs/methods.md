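# Methods

This note documents the models and procedures implemented in `evscore`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Term sequences and serial numbers

All scorers consume the same canonical representation: an ordered sequence
of terms, each carrying the 1-based *serial number* of its position in the
original sentence.  Serials are assigned by linear token position at
tokenisation time.  Stopword filtering removes tokens but never renumbers
survivors, so the serial-distance tie-break in the semantic scorer reflects
true distance in the original sentence rather than distance in the filtered
sequence.  "Word classification" is available as optional POS-based content
filtering but is off by default: with raw text there are usually no tags,
and the scorers behave sensibly without it.

The tokenizer is an interface with a bundled whitespace/punctuation default
(`\w+` matching, which keeps CJK ideographs), so pre-segmented Chinese text
passes through unchanged and external segmenters can be registered without
becoming test dependencies.

## Statistical scorers

* **Frequency.**  score = Σₜ min(cnt_Q(t), cnt_P(t)) / max(|Q|, |P|).
  Multiset intersection (not set) so repeated terms count; normalising by
  the longer text penalises padding a passage with off-topic material.
* **Word order.**  Standard Smith–Waterman local alignment over exact term
  matches with the textbook DP (cell floor 0).  Scoring defaults
  match/mismatch/gap = +1/−1/−1 are configurable; the raw best score is
  divided by `match · min(|Q|, |P|)` — the score of a perfect run of the
  shorter text — and clamped to [0, 1].  No published parameterisation
  exists for this use, so the simplest symmetric scheme was fixed as the
  default.
* **TF-IDF.**  tf = raw within-text count; idf = ln((N+1)/(df+1)) + 1.  The
  add-one smoothing keeps unseen terms finite (df = 0 gives the maximal
  idf), which matters because query/passage vocabulary routinely escapes
  any fixed corpus.  Corpus statistics default to N = 18000 documents, the
  scale the pipeline is normally run against; desk-scale tests use a few
  hundred generated documents.

Empty inputs score 0 in every scorer: an empty passage carries no evidence.

## Syntactic scorers

* **Syntax.**  Jaccard overlap of the dependency-triple sets
  (head surface, relation, dependent surface).  Single-node trees have no
  edges and score 0 — an empty/empty comparison is not evidence of
  similarity.
* **Structure.**  Dependency trees are projected onto ordered structure
  trees labelled by relation label (root = `ROOT`, children ordered by
  serial); bracketed constituent trees can be supplied directly instead,
  keeping the module parser-agnostic.  Similarity is the normalised
  convolution tree kernel with the co-rooted fragment recursion
  Δ(n₁,n₂) = 0 if labels or child-label sequences differ, λ for matching
  leaves, λ·Πᵢ(1+Δ) otherwise; K(T₁,T₂) = Σ Δ over node pairs, normalised
  by √(K(T₁,T₁)·K(T₂,T₂)).  Decay λ = 0.5 by default (the usual mid-range
  choice: large enough that multi-node fragments matter, small enough that
  the kernel is not dominated by the largest common subtree); configurable.

When either text lacks a parse, both syntactic features are 0 and flagged
`no_parse`, so a fusion model trained with such records learns around the
missing evidence rather than treating it as dissimilarity.

## Semantic scorer

Both texts are embedded term-by-term; the n×m matrix of pairwise cosines is
greedily reduced: take the global maximum, record it, zero its whole row
and column, repeat exactly min(n, m) times; score = Σ maxima / max(n, m).
Ties on the maximum are broken by smallest |row serial − column serial|,
then lowest row index, then lowest column index — the serial rule prefers
matches near the same sentence position, and the index rules make the
procedure fully deterministic.

Numerical conventions: cosines are clamped to [0, 1] (a negative cosine is
no evidence of similarity, and the max(n,m) normalisation assumes
non-negative summands); zero-norm and out-of-vocabulary vectors score 0;
extraction runs all min(n, m) rounds even after the matrix is exhausted, so
the procedure's length is input-shape-determined.

The bundled trainer is a minimal single-threaded skip-gram/CBOW
implementation with negative sampling (unigram^0.75 noise distribution,
default window 5, 5 negatives, lr 0.05, 3 epochs, dimension 300).  It is
deterministic under a fixed seed and adequate for desk-scale corpora; for
production embeddings, load a pre-trained table in the standard plain-text
format (header `vocab_size dim`).

## Fusion network

Architecture: 6 inputs → 63 sigmoid subset nodes (one per non-empty feature
subset, wired only to its members) → 6 sigmoid group nodes (one per subset
cardinality i, wired to the C(6,i) cardinality-i nodes) → linear output
S = Σ λₖβₖ − θ.  Threshold census: 63 + 6 + 1 = 70.  The subset layer gives
every feature *combination* its own unit — an explicit feature-subset
selection — while keeping ~330 trainable parameters.

The per-cardinality grouping is the only wiring consistent with having 63
distinct combination nodes; a per-node weighted sum over the node's own
subset members defines the first layer.  The output is linear (an optional
sigmoid would bound S but compresses ranking resolution near the extremes;
scores here are used for ranking, so linear is the default).

Training is plain end-to-end backpropagation on mean squared error —
layerwise pretraining offers nothing at this parameter count.  Full-batch
gradient descent is the default (strictly non-increasing loss at small
learning rates); minibatch mode with momentum (seeded shuffling, hence
deterministic) is used for the larger experiments.  Weight initialisation
is uniform [−0.5, 0.5] on masked entries, thresholds 0.  Gradients of
absent edges are identically zero by construction, verified against central
finite differences.

Accuracy for continuous labels is defined as tolerance-band agreement:
the fraction of pairs with |S − label| ≤ ε, ε = 0.1 by default.

## Synthetic data: what it emulates, and what it does not

* **Vocabularies.**  Synonym clusters are built around mutually orthogonal
  base directions; members are c·base + s·noise with noise confined to the
  orthogonal complement of *all* bases, so within-cluster cosine
  concentrates near c² = (1+intra)/2 ≥ intra and cross-cluster cosine is
  bounded near s² = (1−intra)/2.  Defaults: 12 clusters × 4 terms,
  dimension 64, intra ≥ 0.9, inter ≤ 0.1; the construction is verified
  empirically and resampled (up to 100 draws) before failing.
* **Corpora.**  Each document draws 60% of its terms from one topic cluster
  and 40% uniformly — enough statistical structure to make document
  frequencies meaningful for TF-IDF.
* **QA fixtures.**  One proposition (topic, time, two fillers, symptom,
  tail — six terms) and four passages: P4 = Q with one filler inserted;
  P3 = every content term replaced by a same-cluster synonym (zero content
  surface overlap, full cluster overlap); P1 shares only the topic cluster
  and P2 only the symptom cluster, both lengthened with distractor terms to
  eight tokens.  Filler terms are shared scaffolding, mirroring the
  function words that appear in every natural passage.  Dependency parses
  are right-headed chains labelled by slot role, so P3 reproduces Q's
  structure exactly while P1/P2 do not.
* **Labeled score datasets.**  Features uniform on [0,1]⁶; labels =
  clamp(teacher(features) + N(0, σ), 0, 1) with σ = 0.02 and 12000/4000
  train/test records.  The teacher is a random network whose output layer
  is affinely rescaled so its scores span ≈ [0.1, 0.9] — raw random
  networks centre near 0, and a [0,1] label scale (the scale of human
  similarity grades) would clamp half the labels away, making the target
  unlearnable by construction rather than by any property of the trainer.
* **Ablation labels.**  The cumulative-scorer experiment retrains the
  fusion network per point on labels = mean of the active features + noise,
  a monotone annotator proxy: passages that more scorers rate as similar
  get higher scores.

These generators make the method's *mechanisms* testable: synonym matching,
tie-breaking, connectivity, trainability, ranking.  They do not simulate
clinical language — no morphology, no polysemy, no distribution shift
between corpus and queries, and cluster structure far cleaner than real
embeddings.  Passing these tests shows the algorithms are implemented
correctly and behave as designed under their assumptions, not that the
feature set suffices for real medical text.

## Experiment sizes and determinism

Every experiment is seeded end to end.  Problem sizes were chosen to keep a
full run fast while leaving no statistical ambiguity: oracle equivalence on
200 random matrices (≤ 6×6, including engineered ties), exhaustive
alignment comparison over all 3-letter sequence pairs up to length 3 plus
150 random pairs up to length 6, 50 random tree pairs (≤ 8 nodes) for the
kernel, 100 fixtures for the ordering rate, 200 fixtures × 7 points for the
ablation, and the full 12000/4000 teacher-recovery experiment (minibatch
128, lr 0.5, momentum 0.9, 200 epochs).

## Known limitations

* The word-order scorer uses exact term identity; a synonym swap breaks an
  alignment run (by design — semantics is a separate feature).
* The syntax score compares surfaces, so it is parser- and
  lemmatisation-sensitive.
* The bundled embedding trainer is not performance-engineered; corpora
  beyond a few thousand short documents should use an external trainer and
  the text-format loader.
* The fusion network's accuracy on real annotated similarity data depends
  entirely on the label distribution; the teacher-recovery experiment
  establishes trainability, not field performance.
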