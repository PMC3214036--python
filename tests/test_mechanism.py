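"""Mechanism text classification: lexicon scoring, naive Bayes, corpus tabulation."""

import math

import pytest

import essgenes as eg
from essgenes.io import DiseaseAssociation, TextRecord
from essgenes.mechanism import Lexicon, UNCLASSIFIED
from tests.conftest import make_gene_table


@pytest.fixture
def toy_lexicon():
    return Lexicon({"loss": {"deficien"}, "gain": {"activat"}, "neutral": {"translocat"}})


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Loss-of-function; deficiency.", ["loss", "of", "function", "deficiency"]),
            ("", []),
            ("A1B2  c-d_E", ["a1b2", "c", "d", "e"]),
        ],
    )
    def test_examples(self, text, expected):
        assert eg.tokenize(text) == expected


class TestWordScore:
    def test_majority_category_wins(self, toy_lexicon):
        text = "enzyme deficiency with deficiency despite activation"
        assert eg.word_score_classify(text, toy_lexicon) == "loss"

    def test_empty_text_unclassified(self, toy_lexicon):
        assert eg.word_score_classify("", toy_lexicon) == UNCLASSIFIED

    def test_tie_unclassified(self, toy_lexicon):
        text = "activation activation deficiency deficient"
        assert eg.word_score_classify(text, toy_lexicon) == UNCLASSIFIED

    def test_neutral_maps_to_other(self, toy_lexicon):
        assert eg.word_score_classify("a translocation event", toy_lexicon) == "other"

    def test_stem_prefix_matching(self, toy_lexicon):
        assert eg.word_score_classify("constitutively activating allele", toy_lexicon) == "gain"

    def test_token_order_invariance(self, toy_lexicon):
        a = "activation of gene then deficiency then deficiency"
        b = "deficiency deficiency activation of gene then then"
        assert eg.word_score_classify(a, toy_lexicon) == eg.word_score_classify(b, toy_lexicon)

    def test_shared_stems_removed_on_construction(self):
        lex = Lexicon({"loss": {"mut", "deficien"}, "gain": {"mut", "activat"}, "neutral": {"mut", "fusion"}})
        assert "mut" not in lex.stems["loss"] and "mut" not in lex.stems["gain"]


def records(*specs):
    return [TextRecord(f"r{i}", f"g{i}", text, label) for i, (text, label) in enumerate(specs)]


class TestTrainNB:
    def test_separable_corpus_recovers_classes(self):
        corpus = records(
            ("alpha alpha alpha beta beta alpha", "loss"),
            ("alpha beta beta alpha alpha beta", "loss"),
            ("gamma gamma delta gamma delta gamma", "gain"),
            ("gamma delta delta gamma gamma delta", "gain"),
            ("epsilon zeta epsilon zeta epsilon zeta", "neutral"),
            ("zeta epsilon zeta epsilon zeta epsilon", "neutral"),
        )
        model = eg.train_nb(corpus, frequent_df_cutoff=1.1, exclude_shared=False)
        call, post = eg.nb_classify(model, "alpha beta alpha")
        assert call == "loss" and post["loss"] > 0.9

    def test_shared_word_excluded(self):
        corpus = records(
            ("mutation alpha", "loss"), ("mutation alpha2", "loss"),
            ("mutation gamma", "gain"), ("mutation gamma2", "gain"),
            ("mutation zeta", "neutral"), ("mutation zeta2", "neutral"),
        )
        model = eg.train_nb(corpus, frequent_df_cutoff=1.1, exclude_shared=True)
        assert "mutation" not in model.vocabulary
        assert "mutation" in model.excluded_words

    def test_frequent_word_cutoff(self):
        corpus = records(
            ("common alpha", "loss"), ("common beta", "loss"),
            ("common gamma", "gain"), ("rare gamma", "gain"),
            ("common zeta", "neutral"), ("common eta", "neutral"),
        )
        model = eg.train_nb(corpus, frequent_df_cutoff=0.5, exclude_shared=False)
        assert "common" not in model.vocabulary  # df 5/6
        assert "rare" in model.vocabulary

    def test_posterior_matches_hand_bayes_rule(self):
        # 4 training docs, alpha=1; hand-applied Bayes on "a b" with the
        # frequency-interpolated likelihood p(w|c) = (f + 1/V) / 2, V = 3
        corpus = records(
            ("a a", "loss"), ("a b", "loss"), ("b b", "gain"), ("c", "neutral")
        )
        model = eg.train_nb(corpus, alpha=1.0, frequent_df_cutoff=1.1, exclude_shared=False)
        # frequencies: loss a=3/4, b=1/4; gain b=1; neutral c=1
        like = {
            "loss": ((3 / 4 + 1 / 3) / 2) * ((1 / 4 + 1 / 3) / 2),
            "gain": ((0 + 1 / 3) / 2) * ((1 + 1 / 3) / 2),
            "neutral": ((0 + 1 / 3) / 2) * ((0 + 1 / 3) / 2),
        }
        prior = {"loss": 0.5, "gain": 0.25, "neutral": 0.25}
        z = sum(prior[c] * like[c] for c in like)
        call, post = eg.nb_classify(model, "a b")
        assert call == "loss"
        for cat in like:
            assert post[cat] == pytest.approx(prior[cat] * like[cat] / z)

    def test_training_duplication_invariance(self):
        corpus = records(
            ("alpha beta", "loss"), ("gamma delta", "gain"), ("epsilon", "neutral")
        )
        m1 = eg.train_nb(corpus, frequent_df_cutoff=1.1, exclude_shared=False)
        doubled = corpus + [
            TextRecord(f"dup{i}", r.gene_id, r.text, r.known_label) for i, r in enumerate(corpus)
        ]
        m2 = eg.train_nb(doubled, frequent_df_cutoff=1.1, exclude_shared=False)
        assert m1.priors == pytest.approx(m2.priors)
        for cat in m1.log_likelihoods:
            for w in m1.vocabulary:
                assert m1.log_likelihoods[cat][w] == pytest.approx(m2.log_likelihoods[cat][w])

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            eg.train_nb(records(("a", "loss"), ("b", "neutral")))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            eg.train_nb(records(("a", "loss"), ("b", "gain"), ("c", "neutral")), alpha=0)


class TestNBClassify:
    @pytest.fixture
    def model(self):
        return eg.train_nb(
            records(
                ("alpha alpha", "loss"), ("alpha beta", "loss"),
                ("gamma gamma", "gain"), ("gamma delta", "gain"),
                ("zeta", "neutral"), ("zeta eta", "neutral"),
            ),
            frequent_df_cutoff=1.1,
            exclude_shared=False,
        )

    def test_oov_document_returns_priors(self, model):
        _, post = eg.nb_classify(model, "unseen words only")
        assert post == pytest.approx(model.priors)

    def test_posterior_sums_to_one(self, model):
        for text in ("alpha", "gamma zeta", "alpha gamma zeta delta"):
            _, post = eg.nb_classify(model, text)
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)


class TestClassifyCorpus:
    @pytest.fixture
    def setting(self, toy_lexicon):
        spec = [("g0", {"embryonic lethality"}, True, False), ("g1", set(), True, False)]
        classified = eg.classify(make_gene_table(spec))
        train = records(
            ("deficiency deficient", "loss"), ("activation activating", "gain"),
            ("translocation fusion", "neutral"),
        )
        model = eg.train_nb(train, frequent_df_cutoff=1.1, exclude_shared=False)
        return classified, toy_lexicon, model

    def test_all_loss_corpus_gives_loss_fraction_one(self, setting):
        classified, lexicon, model = setting
        corpus = [TextRecord(f"r{i}", f"g{i % 2}", "a deficiency of enzyme") for i in range(6)]
        result = eg.classify_corpus(corpus, lexicon, model, classified)
        for _, row in result.proportions.iterrows():
            if row["n_records"]:
                assert row["wordscore_loss"] == 1.0 and row["final_loss"] == 1.0

    def test_polygenic_records_dropped(self, setting):
        classified, lexicon, model = setting
        assocs = [DiseaseAssociation("g1", "d1", genicity="polygenic")]
        corpus = [
            TextRecord(f"r{i}", "g1" if i < 3 else "g0", "deficiency") for i in range(10)
        ]
        kept = eg.classify_corpus(corpus, lexicon, model, classified, assocs, "monogenic_only")
        assert len(kept.calls) == 7
        all_kept = eg.classify_corpus(corpus, lexicon, model, classified, assocs, "all")
        assert len(all_kept.calls) == 10

    def test_agreement_rate_over_mutually_classified(self, setting):
        classified, lexicon, model = setting
        corpus = [
            TextRecord("r1", "g0", "deficiency deficiency"),
            TextRecord("r2", "g1", "activation activating"),
        ]
        result = eg.classify_corpus(corpus, lexicon, model, classified)
        assert result.agreement_rate == 1.0
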