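# Methods

This note records the models, conventions and numerical choices behind
`painstream`, including the design decisions taken where a published
description of this kind of analysis leaves the details open.

## Corpus model and tokenization

A tweet is an (id, user, text, UTC timestamp, city, lat/lon, optional
sentiment label) record; a corpus is an ordered collection sharing a query
term. **Deduplication** keeps the first occurrence of each text after
case-folding and whitespace collapsing — enough to catch verbatim re-posts
without fuzzy matching, which would risk merging genuinely distinct tweets.

**Tokenization** lower-cases, strips URLs and @-mentions, folds `#pain` into
`pain`, removes punctuation except intra-word apostrophes (contractions such
as `don't` are first-class tokens, as they are among the most frequent terms
in pain discourse), preserves emoticons verbatim, and removes a fixed
~120-word stopword list. The list deliberately excludes every negator (`no`,
`not`, `never`, `don't`, `can't`, ...) because negators are both
high-frequency content words and inputs to the sentiment negation rule. The
query term is removed from token streams used for graph statistics (its
edges would dominate every ranking trivially) but retained for sentiment
scoring, where the lexicon may weight it; `tokenize(keep_query=...)`
switches between the two.

**Timestamp localization** uses fixed per-city UTC offsets (no DST — a
daylight-saving treatment cannot be inferred for a one-month collection
window and would change at most one bin). Local hours map to bins 1..24 with
midnight labeled 24, matching the "at 2400" axis convention of hour-of-day
reporting.

## Synthetic generator

The generator replaces live API collection and defines the conditions every
downstream test runs under. Defaults: 1,500 tweets per search (the per-query
API cap such studies work with), positive-sentiment probability 0.3 (the
median share of positive pain tweets across cities is about 29%), uniform
hour profile, five cities with fixed UTC offsets, three disjoint topic
word-communities. Each tweet is assembled from the query term, 1–2 sentiment
markers drawn from strongly weighted lexicon terms of the true polarity, 2–3
topic words from one community, and neutral fillers, then shuffled.
Positive-marker weights are all ≥ +3 so that a planted marker dominates the
query term's own −2 lexicon weight; topic and filler vocabularies are
disjoint from the lexicon and stopword list so planted token counts survive
tokenization exactly.

**Negation injection**: with configurable probability a positive tweet is
rewritten so that `not` precedes its (single) marker within the 5-token
window, and the truth label flips to negative. The window between `not` and
the marker contains only lexicon-free fillers, keeping ground truth exact.

**Mention corpora** realize a planted directed edge list — star (all spokes
mention the hub), chain, or a planted-partition block model (within-block
edge probability `p_in`, between-block `p_out`, random direction) — with one
tweet per edge opening `RT @target` or `@target`, plus optional mention-free
padding tweets. `p_in ≤ p_out` triggers an "unrecoverable" warning. A
separate timeline-pool builder plants exact whole-token term counts for
frequency-ratio reporting.

All randomness flows from one `random.Random(seed)`; equal configs give
byte-identical corpora. The generator makes no attempt at linguistic realism
(grammar, slang, length distributions); passing tests demonstrate that the
analysis code recovers *statistical* structure, not that it would be
accurate on real language — in particular sarcasm, misspellings and
out-of-lexicon slang are absent by construction, so real-data sentiment
accuracy will be lower than the near-perfect recovery seen here.

## Term graph and Louvain

Co-occurrence uses set semantics: each unordered pair of distinct tokens in
a tweet adds 1 to that edge, at most once per tweet — in 140-character texts
within-tweet multiplicity is noise. Degree centrality is the
distinct-neighbour count (weighted degree is exposed separately); rankings
break ties lexicographically so reports are deterministic.

Modularity is the standard weighted form
`Q = Σ_c [ w_in(c)/W − γ(s(c)/2W)² ]` with resolution γ (default 1, the
conventional "default modularity" setting). The Louvain implementation is
written from scratch: greedy local moves accepting the best positive gain
`Δ Q = (k_{i,in} − k_{i,old})/W − γ k_i (Σ_tot − Σ_old)/(2W²)` above a
tolerance of 1e−7, followed by community aggregation (intra-edges become
self-loops; a self-loop of weight w contributes 2w to its node's degree),
repeated until no level improves Q by more than the tolerance. Node visit
order is shuffled from the seed, so results are deterministic per seed. Q is
asserted non-decreasing across levels at run time, and the reported Q is
recomputed independently from the final assignment on the original graph.
On random benchmark graphs the partition quality tracks networkx's Louvain
within a few hundredths of Q.

## Sentiment

**Rule component.** Each token matching the lexicon contributes its signed
integer weight; emoticons contribute their weights and are never negated. A
negator within the **5 tokens preceding** a keyword reverses its
contribution to ±1 (unit score of opposite sign, not the negated full
weight). The preceding-only window matches English negation order and keeps
scoring linear; "reversal to ±1" reflects that a negated sentiment word
signals weak opposite polarity rather than a mirror-strength one. Polarity
is the sign of the sum; confidence is `min(1, |score|/5)` — 5 being a
strong single-keyword weight — and 0 when nothing matched.

**NB component.** Features are the top-k terms by the smoothed
document-frequency risk ratio (s = 0.5), ranked by `max(RR, 1/RR)` so both
positive and negative markers rank high; k defaults to 2000 and clamps to
the vocabulary with a warning. Documents contribute relative-frequency
counts (term count / document length — the "smoothed relative frequency"
normalization), and class-conditional likelihoods are add-one-smoothed
multinomial estimates over the selected features; priors are class
proportions. Prediction is the standard log-space posterior; inputs with no
selected features return the prior. Note that add-one smoothing makes the
estimates *approximately*, not exactly, invariant to duplicating the
training corpus: the drift is O(1/N) and the test suite checks it is small
at moderate N rather than zero.

**Hybrid arbitration** is rule-first: a nonzero rule score decides; a zero
score falls back to the NB posterior with the 0.5 tie going negative (a
conservative default for a pain corpus, where the base rate is negative).
The combination rule and both confidence formulas are this package's
constructions — published hybrid classifiers of this kind do not specify
them — so the alternative confidence-weighted vote is available behind
`arbitration="vote"` and the choice surfaces in the pipeline's logged
parameters.

**Agreement.** Cohen's κ = (p_o − p_e)/(1 − p_e) from the two-rater
contingency table. For ≥3 raters no single generalization is canonical, so
`multi_rater_kappa` returns both the mean pairwise Cohen's κ and Fleiss' κ,
labeled. Degenerate cases: a constant rater gives κ = 0; perfect agreement
with zero label variance gives κ = 1.

The packaged lexicon is an AFINN-style sample (~150 terms, 25 emoticons)
sufficient for tests and examples; any full AFINN-111 TSV loads through
`Lexicon.from_tsv` (negators, if present in the file, are dropped to keep
the negator set disjoint from weighted terms).

## Geo-temporal statistics

Proportions of positive tweets are tabulated per city or per local hour,
with the cross-group median reported. The omnibus comparison is the Pearson
chi-square test of homogeneity on the k×2 table (df = k−1, no continuity
correction); a warning attaches when an expected cell falls below 1.
Hour-of-day comparisons pool all cities by local hour. City-level
correlations use Spearman's ρ with average ranks and the t-approximation
p-value (n−2 df); constant vectors are rejected rather than returning NaN.
These are ecological analyses of city aggregates: they support no inference
about individual tweeters and no causal claims.

## Mention networks

Edges run from the tweet's author to each distinct mentioned handle;
retweets (`RT @x`) and bare mentions are one edge type by default
(`retweets_only=True` restricts), self-mentions are dropped, and parallel
mentions accumulate as weights. Conventions for fragmented graphs: diameter
and average path length are computed on the **largest weakly connected
component, undirected** (the only way a single finite value exists for a
fragmented digraph); density uses the simple directed graph
`m / n(n−1)`; strong components come from a linear-time algorithm; the
modularity community count runs this package's Louvain on the undirected
weighted projection. The per-node ratios (WCCs/node, communities/node)
quantify fragmentation: emotion-style corpora (many small planted blocks)
score high, broadcast-style corpora (one star cascade) score near 1/n.

Network comparisons use the two-sided Mann-Whitney U test (exact for small
tie-free samples, tie-corrected normal approximation otherwise) with effect
size |Z|/√N — chosen because degree distributions are heavily skewed, where
a rank test with a small standardized effect size is the natural reading of
large mean differences coexisting with tiny effects; a Welch t-test is
available via `test="welch_t"`. Fully tied inputs return p = 1, effect 0.

Timeline sampling draws users uniformly without replacement among those who
authored an edge-bearing tweet containing the query term, then keeps each
user's most recent tweets (ties broken by id, descending). Term-frequency
reports count whole-token matches only (no substrings) and report rates
relative to a reference term, rounded to 2 decimals.

## Pipeline

`run_pipeline` wires the stages behind one YAML-configurable `RunConfig`;
every open design parameter (negation window, arbitration, k, resolution,
test choice) is an explicit logged config value so ablations are one-line
changes, and every summary value is recomputable by calling the module
functions directly. Reports: top-term/edge CSVs, GraphML exports
(Gephi-compatible), per-city/hour sentiment CSVs, NB model JSON, and a
deterministic `summary.json`.

## Problem sizes and numerical conventions

The test suite and acceptance script run on deliberately moderate sizes —
10,000 tweets for mixture recovery (3-binomial-SD band), 200-node 4-block
partitions over 10 seeds for Louvain recovery (mean ARI ≥ 0.9), 100
simulated null tables for the chi-square type-I check ([0.02, 0.09] band at
α = 0.05), 50 random digraphs (n ≤ 40) against Floyd-Warshall/reachability
oracles, 1,000 random streams against a brute-force negation-window scan,
and exact Mann-Whitney enumeration at n = 5+5 — sizes chosen to make the
statistical bands tight enough to be meaningful while keeping a full run in
seconds. NB posterior equality to the brute-force Bayes oracle is asserted
at 1e−12; modularity against the direct formula likewise.

## Known limitations

- The generator's vocabulary is tiny and disjoint by construction; lexical
  ambiguity, sarcasm, misspellings, code-switching and hashtag semantics are
  out of scope, so sentiment accuracies reported on synthetic data are upper
  bounds.
- No stemming, n-grams or synonym handling in the term graph.
- Fixed UTC offsets ignore daylight-saving time.
- The hybrid arbitration and confidence definitions are package conventions,
  not community standards; both are configurable.
- Louvain is greedy and seed-dependent; only Q monotonicity and recovery on
  well-separated planted partitions are guaranteed, not global optimality.
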