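"""Rule scorer, risk-ratio NB, hybrid arbitration, and agreement statistics."""

import math
import random

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from painstream import (
    Lexicon,
    cohens_kappa,
    fleiss_kappa,
    hybrid_classify,
    multi_rater_kappa,
    nb_predict,
    percent_positive,
    risk_ratio_rank,
    rule_score,
    tokenize,
    train_nb,
)
from painstream.sentiment import DEFAULT_NEGATORS


# ---------------------------------------------------------------- rule scorer

class TestRuleScore:
    def test_paper_style_positive_exemplar(self, lexicon):
        toks = tokenize("Exercise was great! No pain, no gain!", "pain", keep_query=True)
        res = rule_score(toks, lexicon)
        # great contributes +3; negated "pain" is reversed to +1
        assert ("pain", 1, True) in res.matches
        assert res.score == 4 and res.polarity == "positive"

    def test_no_matches_neutral_zero_confidence(self, lexicon):
        res = rule_score(["kitchen", "window"], lexicon)
        assert res.score == 0 and res.polarity == "neutral" and res.confidence == 0.0

    def test_reversal_to_unit(self, lexicon):
        res = rule_score(["not", "good"], lexicon)
        assert res.score == -1 and res.polarity == "negative"

    def test_negation_window_is_five_preceding(self, lexicon):
        inside = ["not", "x1", "x2", "x3", "x4", "good"]
        outside = ["not", "x1", "x2", "x3", "x4", "x5", "good"]
        assert rule_score(inside, lexicon).score == -1
        assert rule_score(outside, lexicon).score == 3

    def test_following_negator_does_not_reverse(self, lexicon):
        assert rule_score(["good", "not"], lexicon).score == 3

    def test_emoticons_weighted_and_never_negated(self, lexicon):
        assert rule_score([":)"], lexicon).score == 2
        assert rule_score(["not", ":)"], lexicon).score == 2

    def test_confidence_formula(self, lexicon):
        assert rule_score(["good"], lexicon).confidence == pytest.approx(3 / 5)
        assert rule_score(["awesome", "love"], lexicon).confidence == 1.0

    def test_bruteforce_window_scan_agreement(self, lexicon):
        rng = random.Random(0)
        vocab = (list(lexicon.weights)[:40] + list(lexicon.emoticon_weights)
                 + list(DEFAULT_NEGATORS)[:10] + ["filler", "word", "thing"])

        def oracle(tokens):
            score = 0
            for i, t in enumerate(tokens):
                if t in lexicon.emoticon_weights:
                    score += lexicon.emoticon_weights[t]
                elif t in lexicon.weights:
                    negated = any(tokens[j] in lexicon.negators
                                  for j in range(max(0, i - 5), i))
                    w = lexicon.weights[t]
                    score += (-1 if w > 0 else 1) if negated else w
            return score

        for _ in range(1000):
            tokens = [rng.choice(vocab) for _ in range(rng.randint(0, 15))]
            assert rule_score(tokens, lexicon).score == oracle(tokens)

    def test_sign_antisymmetry_without_negators(self, lexicon):
        flipped = Lexicon(
            weights={t: -w for t, w in lexicon.weights.items()},
            emoticon_weights={t: -w for t, w in lexicon.emoticon_weights.items()},
            negators=frozenset(),
        )
        plain = Lexicon(weights=dict(lexicon.weights),
                        emoticon_weights=dict(lexicon.emoticon_weights),
                        negators=frozenset())
        rng = random.Random(1)
        vocab = list(lexicon.weights)[:30] + [":)", ":(", "blah"]
        for _ in range(200):
            tokens = [rng.choice(vocab) for _ in range(rng.randint(0, 10))]
            assert rule_score(tokens, flipped).score == -rule_score(tokens, plain).score


class TestLexicon:
    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            Lexicon(weights={"meh": 0})

    def test_negator_clash_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            Lexicon(weights={"not": 2})

    def test_tsv_roundtrip(self, tmp_path, lexicon):
        p = tmp_path / "lex.tsv"
        p.write_text("good\t3\nbad\t-3\n")
        assert Lexicon.read_tsv(p) == {"good": 3, "bad": -3}


# ------------------------------------------------------------------ NB model

_POS_DOCS = [["good", "fun"], ["good", "day"], ["fun", "day"]]
_NEG_DOCS = [["bad", "day"], ["bad", "gloom"], ["gloom", "fun"]]
_DOCS = _POS_DOCS + _NEG_DOCS
_LABELS = ["positive"] * 3 + ["negative"] * 3


class TestRiskRatio:
    def test_hand_computed_toy_corpus(self):
        # s=0.5, N_pos=N_neg=3: RR(good)=(2.5/4)/(0.5/4)=5, RR(fun)=(2.5/4)/(1.5/4)=5/3
        ranked = risk_ratio_rank(_DOCS, _LABELS)
        assert ranked == [
            ("bad", pytest.approx(5.0)),
            ("gloom", pytest.approx(5.0)),
            ("good", pytest.approx(5.0)),
            ("day", pytest.approx(5 / 3)),
            ("fun", pytest.approx(5 / 3)),
        ]

    def test_class_exclusive_term_dominates(self):
        docs = [["only", "both"], ["both"]]
        ranked = dict(risk_ratio_rank(docs, ["positive", "negative"]))
        assert ranked["only"] > ranked["both"]

    def test_mirror_symmetry(self):
        docs = [["p1"], ["p1", "p2"], ["n1"], ["n1", "n2"]]
        labels = ["positive", "positive", "negative", "negative"]
        scores = dict(risk_ratio_rank(docs, labels))
        assert scores["p1"] == pytest.approx(scores["n1"])
        assert scores["p2"] == pytest.approx(scores["n2"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            risk_ratio_rank([["a"]], ["positive"])


def _oracle_posterior(docs, labels, test_doc, features):
    """Direct Bayes enumeration (no logs) over the selected feature set."""
    fs = list(features)
    sums = {"positive": {t: 0.0 for t in fs}, "negative": {t: 0.0 for t in fs}}
    for d, y in zip(docs, labels):
        if not d:
            continue
        for t in d:
            if t in sums[y]:
                sums[y][t] += 1.0 / len(d)
    probs = {}
    for y, s in sums.items():
        tot = sum(s.values())
        probs[y] = {t: (s[t] + 1.0) / (tot + len(fs)) for t in fs}
    prior_pos = labels.count("positive") / len(labels)
    lik = {"positive": prior_pos, "negative": 1 - prior_pos}
    for y in lik:
        for t in test_doc:
            if t in probs[y]:
                lik[y] *= probs[y][t]
    return lik["positive"] / (lik["positive"] + lik["negative"])


class TestNaiveBayes:
    def test_separable_vocabulary_perfect_training_accuracy(self):
        docs = [["yes"]] * 3 + [["ugh"]] * 3
        labels = ["positive"] * 3 + ["negative"] * 3
        model = train_nb(docs, labels, k_features=2)
        preds = ["positive" if nb_predict(model, d) > 0.5 else "negative" for d in docs]
        assert preds == labels

    def test_uninformative_corpus_returns_prior(self):
        docs = [["w"], ["w"], ["w"]]
        labels = ["positive", "positive", "negative"]
        model = train_nb(docs, labels, k_features=1)
        assert nb_predict(model, ["w", "w"]) == pytest.approx(2 / 3)

    def test_empty_input_returns_prior(self):
        model = train_nb(_DOCS, _LABELS, k_features=5)
        assert nb_predict(model, []) == pytest.approx(0.5)
        assert nb_predict(model, ["unseen"]) == pytest.approx(0.5)

    def test_symmetric_model_gives_half(self):
        docs = [["p"], ["n"]]
        model = train_nb(docs, ["positive", "negative"], k_features=2)
        assert nb_predict(model, ["p", "n"]) == pytest.approx(0.5)

    def test_bruteforce_bayes_enumeration(self):
        rng = random.Random(4)
        vocab = ["a", "b", "c", "d", "e"]
        for _ in range(50):
            docs = [[rng.choice(vocab) for _ in range(rng.randint(1, 6))]
                    for _ in range(6)]
            labels = ["positive"] * 3 + ["negative"] * 3
            model = train_nb(docs, labels, k_features=5)
            test_doc = [rng.choice(vocab) for _ in range(rng.randint(0, 5))]
            expected = _oracle_posterior(docs, labels, test_doc, model.features)
            assert nb_predict(model, test_doc) == pytest.approx(expected, abs=1e-12)

    def test_k_exceeding_vocabulary_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            model = train_nb(_DOCS, _LABELS, k_features=999)
        assert len(model.features) == 5

    def test_duplicating_corpus_barely_moves_posterior(self):
        # Exact invariance holds only without smoothing; with add-one
        # smoothing the drift is O(1/N), so check at a moderate corpus size.
        docs, labels = _DOCS * 10, _LABELS * 10
        model1 = train_nb(docs, labels, k_features=5)
        model2 = train_nb(docs * 2, labels * 2, k_features=5)
        for doc in (["good"], ["bad", "gloom"], ["fun", "day"]):
            p1, p2 = nb_predict(model1, doc), nb_predict(model2, doc)
            assert (p1 > 0.5) == (p2 > 0.5)
            assert abs(p1 - p2) < 0.05

    def test_json_roundtrip(self, tmp_path):
        model = train_nb(_DOCS, _LABELS, k_features=5)
        path = tmp_path / "m.json"
        model.to_json(path)
        from painstream import NBModel
        back = NBModel.from_json(path)
        assert nb_predict(back, ["good", "fun"]) == pytest.approx(
            nb_predict(model, ["good", "fun"]))


# -------------------------------------------------------------------- hybrid

class TestHybrid:
    def test_rule_precedence(self, lexicon):
        rr = rule_score(["awesome"], lexicon)
        res = hybrid_classify(rr, nb_posterior=0.1)
        assert res.hybrid_polarity == "positive" and res.source == "rule"

    def test_nb_fallback_on_zero_rule(self, lexicon):
        rr = rule_score(["kitchen"], lexicon)
        res = hybrid_classify(rr, nb_posterior=0.9)
        assert res.hybrid_polarity == "positive" and res.source == "nb"
        assert res.confidence == pytest.approx(0.8)

    def test_tie_at_half_goes_negative(self, lexicon):
        rr = rule_score(["kitchen"], lexicon)
        assert hybrid_classify(rr, nb_posterior=0.5).hybrid_polarity == "negative"

    def test_source_invariant(self, lexicon):
        for toks, post in ((["good"], 0.1), (["window"], 0.9), (["bad"], None)):
            res = hybrid_classify(rule_score(toks, lexicon), post)
            assert (res.source == "rule") == (res.rule.score != 0)

    def test_percent_positive(self, lexicon):
        rules = [rule_score(["good"], lexicon)] * 42 + [rule_score(["bad"], lexicon)] * 58
        results = [hybrid_classify(r, None) for r in rules]
        assert percent_positive(results) == pytest.approx(42.0)

    def test_percent_positive_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_positive([])


class TestEndToEnd:
    def test_negation_rule_beats_ablation(self, lexicon):
        """With planted negations, the negation-aware rule scorer is strictly
        more accurate against generator truth than a no-negation ablation."""
        from painstream import GeneratorConfig, generate_corpus, tokenize_corpus

        corpus, truth = generate_corpus(
            GeneratorConfig(n_tweets=1500, p_positive=0.5, negation_rate=0.4, seed=21))
        streams = tokenize_corpus(corpus, keep_query=True)
        ablated = Lexicon(weights=dict(lexicon.weights),
                          emoticon_weights=dict(lexicon.emoticon_weights),
                          negators=frozenset())

        def accuracy(lex):
            ok = 0
            for tw, toks in zip(corpus, streams):
                res = hybrid_classify(rule_score(toks, lex), None)
                ok += res.hybrid_polarity == truth.tweet_polarity[tw.id]
            return ok / len(corpus)

        assert accuracy(lexicon) > accuracy(ablated)
        assert accuracy(lexicon) > 0.95


# ------------------------------------------------------------------- kappas

class TestKappa:
    def test_identical_ratings(self):
        res = cohens_kappa(["p", "n", "p", "n"], ["p", "n", "p", "n"])
        assert res.kappa == pytest.approx(1.0)

    def test_contingency_closed_form(self):
        # table [[45,15],[25,15]]: p_o=0.60, p_e=0.6*0.7+0.4*0.3=0.54 -> k=6/46
        a = ["p"] * 60 + ["n"] * 40
        b = ["p"] * 45 + ["n"] * 15 + ["p"] * 25 + ["n"] * 15
        res = cohens_kappa(a, b)
        assert res.p_o == pytest.approx(0.60)
        assert res.p_e == pytest.approx(0.54)
        assert res.kappa == pytest.approx(6 / 46)

    def test_constant_rater_zero(self):
        res = cohens_kappa(["p"] * 6, ["p", "n", "p", "n", "p", "n"])
        assert res.kappa == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohens_kappa(["p"], ["p", "n"])

    def test_matches_sklearn_on_random_ratings(self):
        rng = random.Random(5)
        for _ in range(20):
            n = rng.randint(10, 60)
            a = [rng.choice("pn") for _ in range(n)]
            b = [rng.choice("pn") for _ in range(n)]
            if len(set(a)) + len(set(b)) < 4 and a == b:
                continue
            expected = cohen_kappa_score(a, b)
            if math.isnan(expected):
                continue
            assert cohens_kappa(a, b).kappa == pytest.approx(expected, abs=1e-12)

    def test_fleiss_hand_worked(self):
        # 3 raters x 6 items; p_o=7/9, p_e=1/2 -> kappa=5/9
        r1 = ["p", "p", "n", "p", "n", "p"]
        r2 = ["p", "p", "n", "n", "n", "p"]
        r3 = ["p", "n", "n", "n", "n", "p"]
        res = fleiss_kappa([r1, r2, r3])
        assert res.p_o == pytest.approx(7 / 9)
        assert res.p_e == pytest.approx(0.5)
        assert res.kappa == pytest.approx(5 / 9)

    def test_multi_rater_identical(self):
        r = ["p", "n", "p", "n", "n"]
        out = multi_rater_kappa([r, r, r])
        assert out["cohen_pairwise_mean"].kappa == pytest.approx(1.0)
        assert out["fleiss"].kappa == pytest.approx(1.0)

    def test_multi_rater_requires_two(self):
        with pytest.raises(ValueError):
            multi_rater_kappa([["p", "n"]])

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(6)
        ratings = [list(rng.choice(["p", "n"], size=10_000)) for _ in range(3)]
        out = multi_rater_kappa(ratings)
        assert abs(out["cohen_pairwise_mean"].kappa) < 0.05
        assert abs(out["fleiss"].kappa) < 0.05
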