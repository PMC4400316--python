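"""Hybrid rule-based / Naive Bayes sentiment classification with agreement stats.

The rule component sums signed AFINN-style keyword weights (integers in
-5..+5) over a token stream, supplemented with emoticon weights.  A negator
(``no``, ``not``, ``don't`` ...) occurring within the 5 tokens *preceding* a
weighted keyword reverses that keyword's contribution to a unit score of the
opposite sign (+/-1) rather than negating the full weight.  Emoticons are
never negated.  Polarity is the sign of the total; confidence is
``min(1, |score|/5)``.

The statistical component is a multinomial Naive Bayes over the top-k most
class-discriminative terms, ranked by the (smoothed) document-frequency risk
ratio between the positive and negative classes.  Per-document features are
smoothed relative frequencies: raw token counts are divided by document
length, then class-conditional likelihoods use add-one (Laplace) smoothing
over the selected feature set.

The hybrid arbitration is rule-first: a nonzero rule score decides polarity;
a zero rule score falls back to the NB posterior (tie at exactly 0.5 goes
negative).  An alternative confidence-weighted vote is available via
``hybrid_classify(..., arbitration="vote")``.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Lexicon",
    "RuleResult",
    "NBModel",
    "SentimentResult",
    "AgreementResult",
    "DEFAULT_NEGATORS",
    "load_default_lexicon",
    "rule_score",
    "risk_ratio_rank",
    "train_nb",
    "nb_predict",
    "hybrid_classify",
    "classify_corpus",
    "cohens_kappa",
    "fleiss_kappa",
    "multi_rater_kappa",
    "percent_positive",
]

NEGATION_WINDOW = 5

DEFAULT_NEGATORS = frozenset({
    "no", "not", "never", "none", "neither", "nor", "nothing", "cannot",
    "don't", "dont", "can't", "cant", "won't", "wont", "isn't", "isnt",
    "wasn't", "wasnt", "aren't", "arent", "weren't", "werent", "doesn't",
    "doesnt", "didn't", "didnt", "couldn't", "couldnt", "wouldn't", "wouldnt",
    "shouldn't", "shouldnt", "ain't", "aint", "haven't", "havent", "hasn't",
    "hasnt", "hardly", "barely",
})


@dataclass(frozen=True)
class Lexicon:
    """Signed integer term weights plus emoticon weights and negators."""

    weights: Mapping[str, int]
    emoticon_weights: Mapping[str, int] = field(default_factory=dict)
    negators: frozenset[str] = DEFAULT_NEGATORS

    def __post_init__(self) -> None:
        bad = [t for t, w in self.weights.items() if w == 0 or not -5 <= w <= 5]
        if bad:
            raise ValueError(f"weights must be nonzero integers in [-5, 5]: {bad[:5]}")
        if any(w == 0 for w in self.emoticon_weights.values()):
            raise ValueError("emoticon weights must be nonzero")
        clash = self.negators.intersection(self.weights)
        if clash:
            raise ValueError(f"negators must be disjoint from weighted terms: {sorted(clash)}")

    @staticmethod
    def read_tsv(path: str | Path) -> dict[str, int]:
        """Read a ``term<TAB>weight`` TSV (AFINN-111 dialect)."""
        out: dict[str, int] = {}
        for line in Path(path).read_text("utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            term, weight = line.rsplit("\t", 1)
            out[term] = int(weight)
        return out

    @classmethod
    def from_tsv(cls, term_path: str | Path,
                 emoticon_path: str | Path | None = None,
                 negators: frozenset[str] = DEFAULT_NEGATORS) -> "Lexicon":
        weights = cls.read_tsv(term_path)
        for neg in negators:
            weights.pop(neg, None)
        emo = cls.read_tsv(emoticon_path) if emoticon_path else {}
        return cls(weights=weights, emoticon_weights=emo, negators=negators)


def load_default_lexicon() -> Lexicon:
    """Packaged AFINN-style sample (~150 terms) plus emoticon supplement."""
    data = resources.files("painstream.data")
    with resources.as_file(data.joinpath("afinn_sample.tsv")) as tp, \
            resources.as_file(data.joinpath("emoticons.tsv")) as ep:
        return Lexicon.from_tsv(tp, ep)


@dataclass(frozen=True)
class RuleResult:
    score: int
    polarity: str  # positive | negative | neutral
    confidence: float
    matches: tuple = ()  # (term, contribution, negated?)


def rule_score(tokens: Sequence[str], lexicon: Lexicon) -> RuleResult:
    """Weighted-lexicon score with preceding-window negation reversal."""
    score = 0
    matches: list[tuple[str, int, bool]] = []
    for i, tok in enumerate(tokens):
        if tok in lexicon.emoticon_weights:
            w = lexicon.emoticon_weights[tok]
            score += w
            matches.append((tok, w, False))
            continue
        w = lexicon.weights.get(tok)
        if w is None:
            continue
        window = tokens[max(0, i - NEGATION_WINDOW):i]
        negated = any(t in lexicon.negators for t in window)
        contrib = -(1 if w > 0 else -1) if negated else w
        score += contrib
        matches.append((tok, contrib, negated))
    polarity = "positive" if score > 0 else "negative" if score < 0 else "neutral"
    confidence = 0.0 if not matches else min(1.0, abs(score) / 5.0)
    return RuleResult(score=score, polarity=polarity, confidence=confidence,
                      matches=tuple(matches))


def _doc_frequencies(docs: Sequence[Sequence[str]]) -> Counter:
    df: Counter = Counter()
    for doc in docs:
        df.update(set(doc))
    return df


def risk_ratio_rank(
    docs: Sequence[Sequence[str]],
    labels: Sequence[str],
    smoothing: float = 0.5,
) -> list[tuple[str, float]]:
    """Rank vocabulary terms by class discrimination via document-frequency risk ratio.

    For term t with positive/negative document frequencies d_pos, d_neg and
    class sizes N_pos, N_neg:

        RR(t) = [(d_pos + s) / (N_pos + 2s)] / [(d_neg + s) / (N_neg + 2s)]

    Terms are ranked by max(RR, 1/RR) descending (most discriminative first),
    ties broken lexicographically. Returns (term, max(RR, 1/RR)) pairs.
    """
    if len(docs) != len(labels):
        raise ValueError("docs and labels must align")
    pos_docs = [d for d, y in zip(docs, labels) if y == "positive"]
    neg_docs = [d for d, y in zip(docs, labels) if y == "negative"]
    if not pos_docs or not neg_docs:
        raise ValueError("both classes must be present to rank features")
    df_pos, df_neg = _doc_frequencies(pos_docs), _doc_frequencies(neg_docs)
    n_pos, n_neg, s = len(pos_docs), len(neg_docs), smoothing
    vocab = sorted(set(df_pos) | set(df_neg))
    ranked = []
    for t in vocab:
        rr = ((df_pos[t] + s) / (n_pos + 2 * s)) / ((df_neg[t] + s) / (n_neg + 2 * s))
        ranked.append((t, max(rr, 1.0 / rr)))
    ranked.sort(key=lambda p: (-p[1], p[0]))
    return ranked


@dataclass
class NBModel:
    prior_positive: float
    features: tuple[str, ...]
    # log P(t | class), add-one smoothed over the selected feature set
    log_lik_pos: dict[str, float]
    log_lik_neg: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "prior_positive": self.prior_positive,
            "features": list(self.features),
            "log_lik_pos": self.log_lik_pos,
            "log_lik_neg": self.log_lik_neg,
        }, indent=1), "utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        d = json.loads(Path(path).read_text("utf-8"))
        return cls(prior_positive=d["prior_positive"], features=tuple(d["features"]),
                   log_lik_pos=d["log_lik_pos"], log_lik_neg=d["log_lik_neg"])


def train_nb(
    docs: Sequence[Sequence[str]],
    labels: Sequence[str],
    k_features: int = 2000,
    rr_smoothing: float = 0.5,
) -> NBModel:
    """Train multinomial NB on smoothed relative-frequency features.

    Features are the ``k_features`` top terms by :func:`risk_ratio_rank`.
    Each document contributes fractional counts (term count / document
    length); class-conditional likelihoods are add-one-smoothed multinomial
    estimates over the selected features; priors are class proportions.
    """
    if k_features < 1:
        raise ValueError("k_features must be >= 1")
    ranked = risk_ratio_rank(docs, labels, smoothing=rr_smoothing)
    if k_features > len(ranked):
        warnings.warn(
            f"k_features={k_features} exceeds vocabulary size {len(ranked)}; clamping")
        k_features = len(ranked)
    features = tuple(t for t, _ in ranked[:k_features])
    fset = set(features)
    sums = {"positive": Counter(), "negative": Counter()}
    n_docs = Counter(labels)
    for doc, y in zip(docs, labels):
        if not doc:
            continue
        length = len(doc)
        counts = Counter(t for t in doc if t in fset)
        for t, c in counts.items():
            sums[y][t] += c / length
    nf = len(features)
    log_lik = {}
    for y in ("positive", "negative"):
        total = sum(sums[y].values())
        log_lik[y] = {t: math.log((sums[y][t] + 1.0) / (total + nf)) for t in features}
    return NBModel(
        prior_positive=n_docs["positive"] / (n_docs["positive"] + n_docs["negative"]),
        features=features,
        log_lik_pos=log_lik["positive"],
        log_lik_neg=log_lik["negative"],
    )


def nb_predict(model: NBModel, tokens: Sequence[str]) -> float:
    """P(positive | tokens) under the trained model; unmatched input -> prior."""
    counts = Counter(t for t in tokens if t in model.log_lik_pos)
    if not counts:
        return model.prior_positive
    lp = math.log(model.prior_positive) if model.prior_positive > 0 else -math.inf
    ln = math.log(1 - model.prior_positive) if model.prior_positive < 1 else -math.inf
    for t, c in counts.items():
        lp += c * model.log_lik_pos[t]
        ln += c * model.log_lik_neg[t]
    m = max(lp, ln)
    ep, en = math.exp(lp - m), math.exp(ln - m)
    return ep / (ep + en)


@dataclass(frozen=True)
class SentimentResult:
    rule: RuleResult
    nb_posterior_positive: Optional[float]
    hybrid_polarity: str  # positive | negative
    source: str  # rule | nb
    confidence: float


def hybrid_classify(
    rule: RuleResult,
    nb_posterior: Optional[float],
    arbitration: str = "rule_first",
) -> SentimentResult:
    """Arbitrate rule score and NB posterior into a binary polarity.

    ``rule_first`` (default): a nonzero rule score wins; otherwise the NB
    posterior decides (exactly 0.5 -> negative).  ``vote``: confidence-
    weighted average of the two components' signed confidences.
    """
    if arbitration == "rule_first":
        if rule.score != 0:
            return SentimentResult(rule=rule, nb_posterior_positive=nb_posterior,
                                   hybrid_polarity=rule.polarity, source="rule",
                                   confidence=rule.confidence)
        post = 0.5 if nb_posterior is None else nb_posterior
        polarity = "positive" if post > 0.5 else "negative"
        return SentimentResult(rule=rule, nb_posterior_positive=nb_posterior,
                               hybrid_polarity=polarity, source="nb",
                               confidence=abs(2 * post - 1))
    if arbitration == "vote":
        rule_signed = (1 if rule.score > 0 else -1 if rule.score < 0 else 0) * rule.confidence
        post = 0.5 if nb_posterior is None else nb_posterior
        nb_signed = 2 * post - 1
        combined = (rule_signed + nb_signed) / 2
        polarity = "positive" if combined > 0 else "negative"
        source = "rule" if abs(rule_signed) >= abs(nb_signed) else "nb"
        return SentimentResult(rule=rule, nb_posterior_positive=nb_posterior,
                               hybrid_polarity=polarity, source=source,
                               confidence=min(1.0, abs(combined)))
    raise ValueError(f"unknown arbitration {arbitration!r}")


def classify_corpus(
    token_streams: Sequence[Sequence[str]],
    lexicon: Lexicon,
    model: Optional[NBModel] = None,
    arbitration: str = "rule_first",
) -> list[SentimentResult]:
    """Score every token stream with the hybrid classifier."""
    out = []
    for tokens in token_streams:
        rr = rule_score(tokens, lexicon)
        post = nb_predict(model, tokens) if model is not None else None
        out.append(hybrid_classify(rr, post, arbitration=arbitration))
    return out


def percent_positive(results: Sequence[SentimentResult]) -> float:
    """Percentage of results classified positive (0-100 scale)."""
    if not results:
        raise ValueError("cannot compute a proportion of zero results")
    n_pos = sum(1 for r in results if r.hybrid_polarity == "positive")
    return 100.0 * n_pos / len(results)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    p_o: float
    p_e: float
    n_raters: int
    method: str


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> AgreementResult:
    """Two-rater Cohen's kappa from the contingency table of paired labels."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    n = len(ratings_a)
    if n == 0:
        raise ValueError("need at least one rated item")
    labels = sorted(set(ratings_a) | set(ratings_b), key=str)
    p_o = sum(1 for a, b in zip(ratings_a, ratings_b) if a == b) / n
    ca, cb = Counter(ratings_a), Counter(ratings_b)
    p_e = sum((ca[l] / n) * (cb[l] / n) for l in labels)
    kappa = 0.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(kappa=kappa, p_o=p_o, p_e=p_e, n_raters=2, method="cohen")


def fleiss_kappa(ratings: Sequence[Sequence]) -> AgreementResult:
    """Fleiss' kappa for ``ratings[rater][item]`` with a fixed rater count."""
    n_raters = len(ratings)
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    n_items = len(ratings[0])
    if any(len(r) != n_items for r in ratings):
        raise ValueError("all raters must rate every item")
    labels = sorted({x for r in ratings for x in r}, key=str)
    # counts[item][label]
    counts = [Counter(r[i] for r in ratings) for i in range(n_items)]
    p_o = sum(
        sum(c[l] * (c[l] - 1) for l in labels) / (n_raters * (n_raters - 1))
        for c in counts
    ) / n_items
    pj = {l: sum(c[l] for c in counts) / (n_items * n_raters) for l in labels}
    p_e = sum(p * p for p in pj.values())
    if p_e >= 1.0:
        kappa = 1.0 if p_o >= 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(kappa=kappa, p_o=p_o, p_e=p_e, n_raters=n_raters, method="fleiss")


def multi_rater_kappa(ratings: Sequence[Sequence]) -> dict[str, AgreementResult]:
    """Both generalizations of kappa to >2 raters, labeled.

    Returns ``{"cohen_pairwise_mean": ..., "fleiss": ...}`` — the mean of all
    pairwise Cohen's kappas, and Fleiss' kappa.
    """
    if len(ratings) < 2:
        raise ValueError("need at least 2 raters")
    pairs = [cohens_kappa(a, b) for a, b in combinations(ratings, 2)]
    mean_k = sum(p.kappa for p in pairs) / len(pairs)
    mean_po = sum(p.p_o for p in pairs) / len(pairs)
    mean_pe = sum(p.p_e for p in pairs) / len(pairs)
    return {
        "cohen_pairwise_mean": AgreementResult(
            kappa=mean_k, p_o=mean_po, p_e=mean_pe,
            n_raters=len(ratings), method="cohen_pairwise_mean"),
        "fleiss": fleiss_kappa(ratings),
    }
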