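import numpy as np
import pytest

from playseq.io_model import PipelineConfig
from playseq.prediction import (
    fit_ngram_model,
    interpolated_score,
    kfold_accuracy,
    naive_bayes_accuracy,
    predict_distribution,
)
from playseq.preprocess import ElementSequence

from conftest import make_bout


def seq(*tokens):
    return ElementSequence("b", "p", tuple(tokens))


class TestSmoothing:
    def test_add_one_arithmetic(self):
        # counts row A: {B: 4} over vocabulary {A, B, C} -> {1/7, 5/7, 1/7}
        train = [seq(*(["A", "B"] * 4)), seq("C")]
        model = fit_ngram_model(train, max_order=1)
        row = model.smoothed_tables[1][("A",)]
        expected = {"A": 1 / 7, "B": 5 / 7, "C": 1 / 7}
        for el, p in expected.items():
            assert row[model.vocabulary.index(el)] == pytest.approx(p)

    def test_smoothed_rows_sum_to_one(self):
        train = [seq("A", "B", "C", "A", "C", "B", "A")]
        model = fit_ngram_model(train, max_order=3)
        for order_table in model.smoothed_tables.values():
            for row in order_table.values():
                assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_base_probs_positive_and_normalized(self):
        model = fit_ngram_model([seq("A", "A", "B")], max_order=1)
        assert np.all(model.base_probs > 0)
        assert model.base_probs.sum() == pytest.approx(1.0)


class TestInterpolation:
    def test_product_of_suffix_conditionals(self):
        # P(C|B) = 0.5 and P(C|A,B) = 0.8 -> score(C | A,B) = 0.4
        model = fit_ngram_model([seq("A", "B", "C")], max_order=2)
        model.smoothed_tables[1][("B",)] = np.array([0.25, 0.25, 0.5])
        model.smoothed_tables[2][("A", "B")] = np.array([0.1, 0.1, 0.8])
        assert interpolated_score(model, ("A", "B"), "C") == pytest.approx(0.4)

    def test_single_antecedent_is_plain_first_order(self):
        model = fit_ngram_model([seq("A", "B", "A", "B")], max_order=2)
        row = model.smoothed_tables[1][("A",)]
        score = interpolated_score(model, ("A",), "B")
        assert score == pytest.approx(row[model.vocabulary.index("B")])

    def test_uniform_rows_give_power_of_uniform(self):
        # all rows uniform over |V| = 4 -> score(. | a,b,c) = (1/4)^3
        train = [seq("A", "B", "C", "D")]
        model = fit_ngram_model(train, max_order=3)
        for k in model.smoothed_tables:
            for ant in model.smoothed_tables[k]:
                model.smoothed_tables[k][ant] = np.full(4, 0.25)
        assert interpolated_score(model, ("A", "B", "C"), "D") == pytest.approx(0.25**3)

    def test_unseen_tuple_contributes_laplace_floor(self):
        model = fit_ngram_model([seq("A", "B", "A", "B")], max_order=2)
        # ("B","B") never observed: second-order factor is 1/|V|
        s = interpolated_score(model, ("B", "B"), "A")
        first = model.smoothed_tables[1][("B",)][model.vocabulary.index("A")]
        assert s == pytest.approx(first * (1 / 2))

    def test_too_long_antecedents_rejected(self):
        model = fit_ngram_model([seq("A", "B")], max_order=1)
        with pytest.raises(ValueError):
            interpolated_score(model, ("A", "B"), "A")


class TestPredictDistribution:
    def test_normalizes_scores(self):
        model = fit_ngram_model([seq("A", "B", "A", "C")], max_order=1)
        dist = predict_distribution(model, ("A",))
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_single_element_vocabulary(self):
        model = fit_ngram_model([seq("X", "X", "X")], max_order=1)
        dist = predict_distribution(model, ("X",))
        assert dist == {"X": pytest.approx(1.0)}


class TestKFold:
    @pytest.fixture
    def alternating_bouts(self):
        return [make_bout([{"A"}, {"B"}] * 6, f"b{i}") for i in range(25)]

    def test_deterministic_alternation_order1_argmax_perfect(self, alternating_bouts, rng):
        cfg = PipelineConfig(kfold_reps=5, lump_min_count=1)
        rep = kfold_accuracy(alternating_bouts, 1, "argmax", cfg, rng)
        assert rep.mean_accuracy == pytest.approx(1.0)

    def test_order0_expected_match_is_sum_of_squares(self, alternating_bouts, rng):
        # alternating A,B: base probs 0.5/0.5 -> expected match = sum p^2 = 0.5
        cfg = PipelineConfig(kfold_reps=5, lump_min_count=1)
        rep = kfold_accuracy(alternating_bouts, 0, "expected_match", cfg, rng)
        assert rep.mean_accuracy == pytest.approx(0.5, abs=0.02)

    def test_order0_oracle_on_frozen_fold(self, rng):
        """expected_match at order 0 equals sum_i p_i * p-hat_i analytically."""
        from playseq.prediction import _score_vector, fit_ngram_model

        train = [seq(*(["A"] * 6 + ["B"] * 3 + ["C"]))]
        test_tokens = ["A"] * 4 + ["B"] * 2
        model = fit_ngram_model(train, max_order=1)
        vec = model.base_probs / model.base_probs.sum()
        # oracle: mean over test tokens of predicted probability of truth
        idx = {el: i for i, el in enumerate(model.vocabulary)}
        oracle = np.mean([vec[idx[t]] for t in test_tokens])
        scored = np.mean(
            [
                _score_vector(model, ())[idx[t]] / _score_vector(model, ()).sum()
                for t in test_tokens
            ]
        )
        assert scored == pytest.approx(oracle, abs=1e-12)

    def test_windows_never_cross_breaks(self, rng):
        # every adjacent pair straddles a BREAK: nothing is scoreable at order 1
        bouts = [make_bout([{"A"}, "BREAK", {"B"}], f"b{i}") for i in range(20)]
        cfg = PipelineConfig(kfold_reps=3, lump_min_count=1)
        with pytest.raises(ValueError, match="scoreable"):
            kfold_accuracy(bouts, 1, "argmax", cfg, rng)


class TestNaiveBayes:
    def test_constant_consequent_perfect_accuracy(self, rng):
        bouts = [make_bout([{"A"}, {"B"}, {"A"}, {"B"}], f"b{i}") for i in range(25)]
        cfg = PipelineConfig(kfold_reps=5, lump_min_count=1)
        rep = naive_bayes_accuracy(bouts, 1, cfg, rng)
        assert rep.mean_accuracy == pytest.approx(1.0)

    def test_order1_matches_first_order_argmax(self, rng):
        # one feature: NB argmax and smoothed first-order argmax agree
        rng_data = np.random.default_rng(9)
        bouts = []
        for i in range(30):
            toks = rng_data.choice(["A", "B", "C"], size=12, p=[0.5, 0.3, 0.2])
            bouts.append(make_bout([{t} for t in toks], f"b{i}"))
        cfg = PipelineConfig(kfold_reps=30, lump_min_count=1)
        nb = naive_bayes_accuracy(bouts, 1, cfg, np.random.default_rng(1))
        am = kfold_accuracy(bouts, 1, "argmax", cfg, np.random.default_rng(1))
        assert nb.mean_accuracy == pytest.approx(am.mean_accuracy, abs=0.05)

    def test_order2_beats_order1_on_second_order_rule(self, rng):
        # consequent determined jointly by the two previous elements
        from playseq.synthetic_data import GeneratorParams, make_order2_structure, simulate_order2_bouts

        truth = make_order2_structure(6, concentration=0.9, rng=np.random.default_rng(2))
        params = GeneratorParams(n_bouts=15, mean_bout_length=25)
        bouts = simulate_order2_bouts(truth, params, np.random.default_rng(3))
        cfg = PipelineConfig(kfold_reps=20, lump_min_count=1)
        nb1 = naive_bayes_accuracy(bouts, 1, cfg, np.random.default_rng(4))
        nb2 = naive_bayes_accuracy(bouts, 2, cfg, np.random.default_rng(4))
        assert nb2.mean_accuracy > nb1.mean_accuracy
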