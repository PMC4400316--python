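"""Aggregate positive sentiment by city and local hour and test homogeneity.

Plants different positive-sentiment rates in two cities, localizes UTC
timestamps to each city's clock, and shows that the chi-square homogeneity
test flags the city difference while the (uniform) hour-of-day profile is
not flagged.
"""

from painstream import (
    CityConfig,
    GeneratorConfig,
    classify_corpus,
    generate_corpus,
    homogeneity_test,
    load_default_lexicon,
    localize_timestamps,
    proportion_by_group,
    tokenize_corpus,
)
from painstream.synth import city_offsets

cfg = GeneratorConfig(
    n_tweets=6000, p_positive=0.30, seed=3,
    cities=(CityConfig("gloomtown", -5, p_positive_offset=-0.12),
            CityConfig("sunnyville", +10, p_positive_offset=+0.20)),
)
corpus, _ = generate_corpus(cfg)
corpus = localize_timestamps(corpus, city_offsets(cfg))
results = classify_corpus(tokenize_corpus(corpus, keep_query=True),
                          load_default_lexicon())
positives = [r.hybrid_polarity == "positive" for r in results]

by_city = proportion_by_group([tw.city for tw in corpus], positives, "city")
print(by_city.table.to_string(index=False))
stat, df, p = homogeneity_test(by_city)
print(f"city homogeneity: chi2={stat:.1f}, df={df}, p={p:.2e} (planted difference)")

by_hour = proportion_by_group([tw.local_hour for tw in corpus], positives, "hour")
stat, df, p = homogeneity_test(by_hour)
print(f"hour homogeneity: chi2={stat:.1f}, df={df}, p={p:.3f} (uniform profile)")
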