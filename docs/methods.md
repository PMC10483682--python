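# Methods

This note documents the models, the default parameters and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical conventions the implementation commits to.

## Corpus filtering

A post is retained only if it passes every rule, evaluated in a fixed order:
date window (closed interval, compared in UTC), language, medication keyword,
minimum length, retweet/quote exclusion, bot exclusion, and a non-medical-use
gate. A removed post is charged to the *first* failing rule, which makes the
per-rule counts a partition of the removed set and lets `n_in = n_out + Σ
counts` hold exactly. Filtering is idempotent.

Three rules are deliberately open:

- **Language.** Real language identification is a pluggable predicate. The
  default is a cheap heuristic — at least 90 % of non-space characters in the
  Basic Latin block and at least one ASCII letter — which is adequate for the
  synthetic corpora and trivially replaceable for real data.
- **Bot and non-medical-use detection.** Both are upstream classifiers in a
  production deployment; here they are injected predicates defaulting to
  accept-all. The filter fixture ships predicates that flag its planted
  violators so the accounting of all seven exclusion rules can be exercised.
- **Minimum length.** Defaults to 4 word tokens, configurable.

Keyword matching is case-insensitive whole-token matching over the union of
all family terms (generic names, trade names, common misspellings); a
multi-word term contributes its individual words. De-identification replaces
user ids with truncated HMAC-SHA256 digests keyed by a salt: deterministic per
salt, one-way, and collision-checked.

## Preprocessing

Cleaning removes URLs, @-mentions and control characters (each logged with its
raw character span), strips `#` while keeping the hashtag word, lowercases, and
collapses whitespace; it is idempotent. Sentence boundaries are maximal runs of
terminal punctuation `{. ! ? …}` — so ellipses and "?!" runs mark one boundary
— with trailing unpunctuated text forming a final sentence; the resulting spans
cover all non-whitespace text and are disjoint. Tokens are maximal alphanumeric
runs or single other non-space characters (emoji survive as single tokens),
each carrying half-open character offsets into the cleaned text. No stemming,
lemmatization or spelling normalization is performed: misspelling robustness is
the tagger's job, via its character features.

## Embedding providers

Token vectors flow through a provider contract (`token list → n × dim
matrix`) so contextual models can be dropped in; the shipped providers are
context-free. The keyed-hash provider maps each token to a deterministic
unit-norm Gaussian vector keyed by (token, seed) — it carries no semantics, but
gives every distinct token a stable, well-separated representation, which is
exactly what the separable recovery experiments need. The lookup provider is a
seeded uniform(−0.1, 0.1) table with a shared UNK row. Document vectors are the
arithmetic mean of token vectors; with context-free providers this is
permutation-invariant. Default dimension is 32 — large pre-trained models are
hundreds of dimensions, but at synthetic-corpus scale 32 already makes
same-vocabulary documents nearly collinear and different-vocabulary documents
nearly orthogonal.

## The tagger

Architecture, per token: character embeddings (printable ASCII plus UNK,
dimension 16) are convolved with width-3 filters (16 of them), passed through
tanh and max-pooled over positions; the pooled vector is concatenated with the
word embedding; a bidirectional LSTM (hidden size 32 per direction) encodes the
sequence; a linear layer projects each state pair to one score per tag. A
linear-chain CRF adds start/end scores and a tag-transition matrix and defines
the path score

    s(x, y) = start[y1] + Σ_t E[t, yt] + Σ_{t≥2} A[y(t−1), yt] + end[yT].

Training minimizes the mean of `logZ − s(x, y_gold)` over mini-batches; `logZ`
is the log-space forward recursion. With `constrain_transitions` (the default)
the entries for O→I-X, B-X/I-X→I-Y (Y≠X), and I-X at the first position are
−∞ sentinels: decoding can never emit an illegal IOB2 sequence, and the
partition function sums over legal paths only. The sentinels are excluded from
gradient updates.

All gradients are analytic: CRF gradients are forward–backward marginals minus
gold-path indicators; encoder gradients are standard backpropagation through
time for the LSTM, max-pool routing for the CNN, and scatter-add for the
character table. A finite-difference check (central differences, 1e-4 relative
tolerance) covers both the CRF objective and the full network.

Optimization is plain mini-batch SGD, batch size 8, 30 epochs, learning rate
0.3, seeded initialization (uniform ±1/√fan-in). The learning rate was chosen
so that training actually leaves the all-O solution at these dimensions: at
rates an order of magnitude lower the CRF transition scores dominate the early
gradient signal and the encoder never differentiates entity tokens; 0.3 trains
the 200-sentence recovery corpus to held-out F1 1.0 in seconds and remained
stable across seeds. Dropout on the concatenated token features is implemented
(inverted dropout, seeded, training only) but defaults to 0.0: the synthetic
corpora are small and separable, and regularization only slows convergence
there. Word embeddings from the provider are treated as frozen inputs; only
the model's own tensors train.

Ties in Viterbi backtracking break toward the lowest tag index, making decoding
fully deterministic. Start/end score vectors are included but zero-initialized,
so a model that does not need them can leave them near zero.

## Chunking

`iob_to_chunks` emits one span per maximal B-X (I-X)* run and drops O tokens;
`chunks_to_iob` is its exact inverse on legal input (verified by a 1,000-case
round-trip test). Raw model output that is somehow illegal (possible only with
unconstrained transitions) is first repaired with the treat-stray-I-as-begin
convention — the same convention the standard CoNLL evaluation script uses —
which is idempotent.

## Topic modelling

The stage mirrors the cluster-then-describe recipe: reduce document
embeddings, cluster, describe clusters by class-based TF-IDF
`W(t,c) = tf(t,c) · ln(1 + A/f(t))` (natural log; `A` = average token count
per class over non-outlier documents; `W = 0` exactly where `tf = 0`).

The default reducer is centered truncated SVD with a deterministic sign
convention (each component's largest-magnitude loading is positive); the
default clusterer is single-linkage agglomeration cut at a distance threshold,
with components smaller than `min_cluster_size` becoming outliers (label −1)
and surviving clusters renumbered by decreasing size. Both choices are
deliberate: the widely used stochastic alternatives (UMAP, HDBSCAN) fit the
same slots through the `external` hooks, but the defaults must be exactly
reproducible for bit-level pipeline determinism, and at synthetic scale the
deterministic versions separate planted structure perfectly. Outlier documents
are excluded from c-TF-IDF and from topics-over-time.

Topic words are the top-n terms per cluster by descending weight, ties broken
lexicographically (n = 5 by default). Topics-over-time bins documents into
calendar months (ISO weeks optionally) and reports, per (topic, step), the
document count and the time-local c-TF-IDF mass — per-step term frequencies
multiplied by the *global* IDF, so weights across steps are comparable.
Per-step frequencies over topics sum to the step's non-outlier document count.

Coherence is the mean over unordered pairs of a topic's top-k words of
`max(0, cos(v_i, v_j))`, averaged over topics for the headline number. Clipping
negative cosines keeps the score in [0, 1] by construction: identical vectors
give exactly 1, pairwise orthogonal (or opposed) vectors exactly 0. Note that
with the keyed-hash provider coherence is structurally low (random unit vectors
in 32 dimensions are nearly orthogonal), so absolute coherence values are only
meaningful with a semantic embedding provider; the tests assert the bounds and
the exact degenerate values, not a target level. Topics with fewer than two
embeddable words are excluded with a warning.

## Evaluation

Entity scoring is exact-match: a predicted span is a true positive only if
start, end and label all agree with a gold span; each gold span matches at most
once. Micro-averaged P/R/F1 is the headline; per-label figures are also
reported. The 0/0 convention is 0, logged as a warning. The holdout split is
70–15–15 via seeded shuffle and largest-remainder rounding (exact partition);
cross-validation uses seeded near-equal folds and reports mean and *sample*
(n−1) standard deviation per metric. Folds are taken over whichever corpus the
caller passes — whole-set by default.

## Synthetic data

The generators emulate the structure of medication chatter, not its language:

- **Entity corpora** fill short informal templates (≤ 25 tokens) with
  gazetteer terms — the four monitored medications with trade names and
  misspellings, common adverse events (drowsiness, fatigue, pain, nausea,
  headaches, dizziness, hallucinations), symptoms, treatments — at a
  configurable entity rate, recording exact gold spans. Filler vocabulary is
  disjoint from the gazetteers, so the corpora are separable: entity words
  never occur outside planted spans, and a correct tagger can reach F1 ≈ 1.
- **Topic corpora** draw each document's topic from mixing weights and its
  tokens from the topic vocabulary (with probability 1−ε; from the union
  otherwise), timestamps uniform over a five-month window (May 31 – October
  31, 2021 by default).
- **The filter fixture** contains exactly one violator per exclusion rule plus
  one clean record, with the bot/NMU predicates supplied alongside.

Everything is a pure function of (config, seed). What passing tests on these
corpora show is that each algorithm is implemented correctly — inference
matches enumeration, training recovers planted structure, accounting balances.
What they do not show is performance on real chatter, which has ambiguous
entities, context-dependent meaning, class imbalance, and no separability;
real-data performance additionally depends on the embedding provider plugged
in.

## Problem sizes and numerical conventions

The standard experiment sizes are 200 sentences (tagger recovery,
70–15–15 split), 600 documents / 3 topics (topic recovery), 100 random
instances with sequence length ≤ 5 and ≤ 4 tags (CRF enumeration checks), and
1,000 random sequences (chunk round trip); the full pipeline runs at 120–150
records. These sizes are large enough that every recovery experiment has an
unambiguous expected outcome while the entire suite runs in well under a
minute of CPU.

Tolerances: CRF log-partition vs enumeration 1e-8; gradient checks 1e-4
relative with central differences at h = 1e-6; SVD isometry 1e-9; the c-TF-IDF
hand example 1e-12. Log-sum-exp subtracts the per-block maximum and treats
all-(−∞) blocks as −∞ without warnings. Model serialization stores −∞
sentinels as JSON nulls and restores them exactly.

## Known limitations

- The shipped embedding providers carry no semantics; contextual providers
  must be supplied by the user through the provider contract.
- The optimizer is plain SGD; very large corpora would want momentum/Adam and
  mini-batch vectorization across sequences.
- Single-linkage clustering is O(n²) in memory via the condensed distance
  matrix; tens of thousands of documents and beyond call for the external
  clusterer hook.
- The language heuristic is not a language identifier; the bot and NMU gates
  are placeholders for upstream classifiers.
- Coherence with hash embeddings is informative only in its bounds and
  degenerate cases, not as an absolute quality measure.
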