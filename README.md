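# painstream

Content, sentiment, and retweet-network analysis of microblog ("tweet")
corpora about pain — an infodemiology toolkit for studying how a health
concept is discussed in everyday social-media discourse.

Public pain-tweet studies typically collect ~1,500 recent tweets per city or
search term, reduce them to non-duplicate texts, and then ask three
questions: *what* is said together with "pain" (term co-occurrence and
community structure), *how* it is said (positive vs negative sentiment, by
city and hour of day), and *who passes it on* (directed retweet/mention
network topology). The original corpora behind such studies are almost never
deposited, so `painstream` pairs every analysis with a synthetic tweet
generator that plants known sentiment mixtures, topic communities, city/hour
strata and mention topologies, making each stage testable against ground
truth.

## What it computes

- **Corpus handling** — JSON-lines/CSV tweet I/O, exact-duplicate removal
  (case-folded, whitespace-collapsed), microblog tokenization (URLs,
  @-mentions, `#` prefixes stripped; contractions and emoticons preserved;
  negators never stopworded), and localization of UTC timestamps to per-city
  hour bins 1..24 (midnight = bin 24).
- **Term graph** — terms sharing a tweet share an undirected edge (once per
  tweet); degree centrality = distinct-neighbour count. Communities via a
  from-scratch **Louvain** method maximizing weighted modularity
  `Q = Σ_c [ w_in(c)/W − (s(c)/2W)² ]`.
- **Hybrid sentiment** — an AFINN-style weighted lexicon (integer weights in
  −5..+5, plus emoticons) sums keyword contributions; a negator within the 5
  preceding tokens reverses a keyword to ±1. Zero rule scores fall back to a
  multinomial **Naive Bayes** over the top-k terms ranked by the smoothed
  document-frequency **risk ratio**
  `RR(t) = [(d⁺+s)/(N⁺+2s)] / [(d⁻+s)/(N⁻+2s)]`,
  with relative-frequency counts and add-one smoothing. Validation helpers:
  Cohen's κ, mean pairwise κ, Fleiss' κ.
- **Geo-temporal** — positive-sentiment proportions per city/hour, Pearson
  chi-square homogeneity tests, and Spearman rank correlations against a
  documented city covariate CSV (population, % uninsured, September
  temperature, ...).
- **Retweet networks** — directed author→mentioned-user edges extracted from
  tweet text; diameter, average path length, density, weak/strong component
  counts, giant-component fraction, Louvain community count, per-node
  in/out/total degrees, Mann-Whitney U network comparisons with effect size
  |Z|/√N, sampled-user timeline pools and relative term-frequency reports.

## Worked example

```python
from painstream import (GeneratorConfig, classify_corpus, generate_corpus,
                        load_default_lexicon, percent_positive,
                        rule_score, tokenize, tokenize_corpus)

lex = load_default_lexicon()
toks = tokenize("Exercise was great! No pain, no gain!", "pain", keep_query=True)
print(rule_score(toks, lex))
# RuleResult(score=4, polarity='positive', confidence=0.8,
#            matches=(('great', 3, False), ('pain', 1, True)))
# "great" contributes +3; "pain" (weight -2) is preceded by the negator "no"
# and reverses to +1, so the tweet scores +4: positive.

corpus, truth = generate_corpus(GeneratorConfig(n_tweets=5000, p_positive=0.3, seed=2))
results = classify_corpus(tokenize_corpus(corpus, keep_query=True), lex)
print(round(percent_positive(results), 2))   # 30.32
# The planted 30% positive mixture is recovered within binomial error.
```

The `examples/` directory holds one short narrative script per capability
(term graph, sentiment, geo-temporal, networks, full pipeline); each prints
what it computes and what the numbers mean. The same pipeline is scriptable
from the shell:

```bash
painstream run-all --seed 11 --out out/        # full report bundle
painstream sentiment --seed 2                  # single stage
```

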