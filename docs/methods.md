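# Methods

This note records the models, defaults and design choices behind
`citylisten`, and what the synthetic-corpus validation does and does not
establish.

## Collection and preprocessing

Collection mimics a keyword + geo-radius scrape. Keyword matching is
case-insensitive substring matching over the raw text — the closest
reproducible contract to a platform keyword search. Geo filtering uses the
haversine great-circle distance with Earth radius 3958.7613 statute miles;
a record is kept when it lies within `radius_miles` (default 20) of its
city's point. Language identification is a pluggable predicate that
defaults to a pass-through, since collection pipelines usually delegate it
upstream.

Cleaning applies, in order: lowercasing; URL deletion (any `scheme://…`
span or bare `t.co/…` shortener, removed before punctuation stripping so
URL fragments cannot leak into tokens); replacement of every character
outside `[a-z0-9']` with whitespace (apostrophes are kept so contractions
like "don't" survive); whitespace tokenization; stopword removal against a
fixed English list shipped in the package (configurable by file path so
runs are reproducible bit-for-bit). Documents left with fewer than three
tokens are dropped. Deduplication is deliberately not performed and the
report says so.

When the pipeline is run on a keyword-collected corpus, the query terms
themselves are added to the stopword list (`--extra-stopwords`). Query
terms occur in essentially every document by construction, so they carry no
discriminative signal for topics and would otherwise dominate every topic's
top-word list.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes: a
Dirichlet-multinomial topic model over a symbolic vocabulary (`w0000`…),
with city and calendar-month metadata and per-document emotion labels.

Per document: a city is drawn from per-city weights (default: proportional
to the four study markets' observed tweet volumes, so one city dominates);
a month from an 18-month window (Jan 2020–Jun 2021) whose default weights
encode a sharp volume surge in Feb 2020, a drop and partial recovery in
spring 2020, a second surge in May 2021 and a fall in June 2021; the topic
mixture θ_d ~ Dirichlet(α·k·prevalence_city) (so uniform prevalence gives
the conventional symmetric Dirichlet(α)); the length from a
negative-binomial distribution (mean 12, shape 5) truncated to ≥ 3;
tokens i.i.d. from Σ_t θ_dt φ_t. Topic-word rows φ_t are "disjoint-leaning":
the vocabulary is partitioned into k blocks and topic t places `block_mass`
(default 0.95) of its probability on its own block via a Dirichlet(β) draw.
Per-city topic prevalence is a mildly Dirichlet-perturbed uniform
(optionally tilted by global topic weights, which is how deliberately tiny
topics are constructed).

Three signal layers are salted in:

- **Junk** — at `noise_rate`, a token is replaced by a draw from a fixed
  junk pool (URLs, punctuation runs, stopwords) constructed so that every
  entry vanishes entirely under default preprocessing. This makes "all
  injected junk removed" an exactly checkable property.
- **Emotion markers** — the last 32 vocabulary words are reserved as four
  disjoint 8-word marker sets; a document is salted with markers of its
  emotion (drawn from the (city, month) emotion mixture) at `marker_rate`.
  Emotion is generated independently of topic given (city, month).
- **The query keyword** — prepended to every document's text so collection
  filters pass; it is then removed as a corpus-specific stopword, leaving
  the ground-truth φ and θ untouched.

Emotion mixtures default to a negative-leaning 2020 regime, a
positivity surge in early 2021 (February for the dominant west-coast
market, April elsewhere) and an anger spike in May 2021.

What the generator does **not** emulate: natural language (tokens are
symbolic, so transformer embeders cannot be meaningfully exercised —
the shipped hashed embedder is the test-time default), word burstiness
within documents, topic-emotion correlation, retweet duplication, and
user-level structure. Passing tests therefore establish that the pipeline
recovers the generating structure of a well-specified topic model corpus;
they do not establish performance on real platform text.

## LDA by collapsed Gibbs sampling

The sampler is the standard collapsed Gibbs chain; the inner loop is
numba-compiled. Randomness is a hand-rolled xorshift64* stream per
document, spawned from the master seed, and documents are canonicalized
(sorted by id) before sampling; together these make the fit a pure function
of (seed, document set) — in particular invariant to the order documents
are supplied, which would not hold for a single shared RNG stream.

Defaults: α = 50/k ("auto"), β = 0.01, 1000 sweeps with 500 burn-in at desk
scale; φ̂ and θ̂ average the smoothed count ratios over every 10th
post-burn-in sweep rather than using one final sample. The coherence sweep
over candidate k uses shorter chains (200 sweeps, 100 burn-in), refitting
from scratch per candidate with a (seed, k)-derived seed; this is the
desk-scale sweep default and recovers the generating k reliably at the
validation sizes. Out-of-vocabulary tokens at inference are skipped; a
document with none in vocabulary folds in as the uniform mixture with a
warning.

`n_restarts > 1` runs independent chains and keeps the one with the highest
mean post-burn-in joint log-likelihood. This matters for corpora with very
unequal topic sizes: single chains can stall in a merged/split mode (a ~3%
topic absorbed into a neighbor while a large topic splits), and the correct
mode is separated by thousands of nats, so likelihood-based restart
selection identifies it reliably. Note also that small-α fits resolve tiny
topics much better than the strong 50/k default, whose smoothing (kα ≫
document length) blurs token shares; the pruning workflow therefore fits
with α = 0.1.

## Coherence, relevance, pruning

NPMI is computed from boolean sliding windows of 110 tokens (documents
shorter than the window count as one window — for tweets this reduces to
document co-occurrence). Conventions: a pair that never co-occurs scores
−1; a word with no occurrences scores 0 with a warning; the self-pair joint
equals the marginal, making NPMI(w, w) = 1; probabilities inside logs are
floored at 1e-12.

Coherence uses the one-set C_V form: for each of a topic's `top_n` words
(default 10, φ-ties broken lexicographically), build its NPMI vector
against the topic's top-word set, take the cosine similarity against the
set-sum vector, and average over words then topics. The one-set form was
chosen over all-pairs averaging as the canonical C_V construction; both
agree on degenerate single-pair corpora.

One practical caveat surfaced during validation: strongly salted emotion
markers (rates ≳ 0.3) create their own co-occurrence structure and can bias
coherence-based k selection upward. Topic-count validation therefore runs
on marker-free corpora; emotion validation uses marked ones.

Relevance ranking is r(w, t) = λ log φ_tw + (1 − λ) log(φ_tw / p_w) with
p_w the empirical corpus word frequency, default λ = 0.6 and top 20 terms;
λ = 1 reduces to probability ordering and λ = 0 to lift ordering, and ties
break lexicographically.

Pruning flags topics whose share falls below `min_share` (default 0.05).
Share is measured on token-level assignments (or any exclusive per-document
labeling with optional weights). Interpretability judgments cannot be
automated; the share threshold is the quantitative half of that decision
and the human override is recorded in configuration. Fusion clustering is
deliberately not used for share measurement: K-Means inflates very small
clusters by absorbing boundary documents, biasing shares upward.

## Fusion clustering

The exclusive assignment follows the concatenate–compress–cluster design:
`[γ · topic block, embedding block]` → dense autoencoder → K-Means with the
same k → Hungarian alignment of clusters to topics (maximizing
Σ_d θ̂_d[topic(cluster(d))]).

**Block scaling.** Both blocks are centered and scaled to unit *total*
variance before γ is applied. Standardizing only per column would leave a
64-column unit-variance embedding block against a k-column topic block,
letting the embedding dominate Euclidean distances roughly dim/k-fold and
destroying the topic signal at γ = 1. With block-energy normalization γ is
a true balance weight: γ = 0 removes the topic block, γ = 1 balances block
energies, large γ makes latent K-Means reproduce argmax-θ̂ labels.

**Autoencoder.** One dense hidden layer (default 32 units, tanh), linear
decoder, full-batch gradient descent on the mean squared reconstruction
error over all matrix entries. Because that mean carries a 1/(n·d) factor,
useful learning rates are of order 1 (default 1.0, 500 epochs) rather than
the 1e-3 familiar from adaptive optimizers. Divergence (non-finite loss)
raises with a pointer to the learning rate. Training is deterministic given
the seed (Glorot-uniform initialization).

**Embedder.** The default sentence embedder is a hashed token-count random
projection: each token hashes (blake2b, keyed by the embedder seed) to a
fixed pseudo-random direction in R^64, and a text embeds as the
L2-normalized sum. It is deterministic, needs no model download, and gives
bag-of-words cosine geometry — appropriate for the symbolic synthetic
corpora. Any transformer sentence encoder can be swapped in behind the same
`embed(text) -> vector` contract.

**K-Means.** scikit-learn's k-means++ with 10 restarts, Lloyd iterations,
tol 1e-6, seeded. k may not exceed the number of distinct rows.

On the fully separable validation fixture the fused latent clustering
reaches ARI ≈ 0.94–0.97 against ground truth, within 0.03 of the plain
argmax-θ̂ labeling — fusion preserves the topic signal while adding the
embedding pathway.

## Emotion baseline

The four-label classifier contract (`joy, optimism, sadness, anger`;
joy/optimism positive, sadness/anger negative) is pluggable. The shipped
baseline is a multinomial naive-count lexicon model: per-label token
likelihoods with add-one smoothing and a uniform class prior, so
classification is driven by token evidence alone. Ties (e.g. empty or
fully out-of-vocabulary documents) resolve to the first label in fixed
alphabetical order. On marker-salted corpora (rate 0.3) hold-out accuracy
exceeds 0.95; with no markers it sits at chance (≈ 0.25), confirming the
baseline learns exactly the salted signal and nothing else. Reproducing any
specific pretrained transformer's predictions is out of scope.

## Trends

Aggregation groups labeled documents by (city, period) — calendar month or
year of the UTC timestamp — and counts by topic or emotion. Every category
level appears in every non-empty group (zero counts are explicit);
percentages are within-group and sum to 100; (city, period) pairs with no
documents are omitted. Pruned topics are excluded from topic tables
(documents removed from both counts and totals) but their documents still
count toward emotion tables. Peak detection flags months whose count
strictly exceeds both neighbors (endpoints compare to their single
neighbor) — a deliberate formalization of "sudden sharp increase"; it is
not a statistical change-point test.

## Validation problem sizes

Topic-count and parameter recovery run on ten corpora of D = 2000
documents, V = 500, k = 4, α = 0.1, 5% junk noise; the k sweep covers 2–8
with 200-sweep chains. The separable clustering fixture uses D = 1000 fully
disjoint-block documents (α = 0.02, mean length 15). Emotion validation
uses D = 1500 with a 50/50 train/test split. These sizes were chosen as the
smallest at which the statistical properties under test are stable across
seeds.

## Known limitations

- Tokens are exchangeable within documents (bag of words); no burstiness
  or word-order structure in generator or model.
- The hashed embedder carries no semantics beyond token overlap; results
  involving it validate the plumbing, not contextual embedding quality.
- Coherence-based selection inherits C_V's sensitivity to strongly
  co-occurring non-topical token sets (see the marker caveat above).
- Peak detection is descriptive; no uncertainty is attached to trends.
- Timezone handling is fixed to UTC calendar months.
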