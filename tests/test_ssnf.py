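import json

import numpy as np
import pytest

from hossnf import ssnf, synth, texture
from hossnf.exceptions import SchemaError, ValidationError
from hossnf.imgio import CLASS_NAMES
from hossnf.ssnf import (FuzzyRule, SsNFModel, TrainConfig, classify,
                         classify_batch, consequent_output, forward,
                         forward_batch, init_structure, load_model, loss,
                         mf_eval, normalize_firings, rule_firing, save_model,
                         self_systematize, train)


def one_rule_model(biases, n_inputs=2):
    rule = FuzzyRule(
        centers=np.zeros(n_inputs), widths=np.ones(n_inputs),
        weights=np.zeros((7, n_inputs)), biases=np.asarray(biases, dtype=float),
    )
    return SsNFModel(n_inputs=n_inputs, class_names=CLASS_NAMES, rules=[rule])


def random_model(rng, n_rules, n_inputs):
    rules = [
        FuzzyRule(
            centers=rng.normal(0, 1, n_inputs),
            widths=rng.uniform(0.2, 2.0, n_inputs),
            weights=rng.normal(0, 1, (7, n_inputs)),
            biases=rng.normal(0, 1, 7),
        )
        for _ in range(n_rules)
    ]
    return SsNFModel(n_inputs=n_inputs, class_names=CLASS_NAMES, rules=rules)


class TestMembershipAndFiring:
    def test_membership_at_center_is_one(self):
        assert mf_eval(2.0, 0.5, 2.0) == 1.0

    def test_membership_one_sigma(self):
        assert mf_eval(0.0, 1.5, 1.5) == pytest.approx(np.exp(-1.0))

    def test_membership_symmetry(self):
        for d in (0.1, 1.0, 3.7):
            assert mf_eval(1.0, 0.8, 1.0 + d) == pytest.approx(
                mf_eval(1.0, 0.8, 1.0 - d)
            )

    def test_firing_at_center(self):
        rule = FuzzyRule(np.array([1.0, 2.0]), np.array([0.5, 0.5]),
                         np.zeros((7, 2)), np.zeros(7))
        assert rule_firing(rule, np.array([1.0, 2.0])) == 1.0

    def test_firing_two_unit_deviations(self):
        rule = FuzzyRule(np.zeros(2), np.ones(2), np.zeros((7, 2)), np.zeros(7))
        assert rule_firing(rule, np.ones(2)) == pytest.approx(np.exp(-2.0))

    def test_product_form_equals_quadratic_form(self, rng):
        for _ in range(20):
            n = 4
            rule = FuzzyRule(rng.normal(0, 1, n), rng.uniform(0.3, 2, n),
                             np.zeros((7, n)), np.zeros(7))
            x = rng.normal(0, 1, n)
            prod = np.prod([mf_eval(rule.centers[m], rule.widths[m], x[m])
                            for m in range(n)])
            assert rule_firing(rule, x) == pytest.approx(prod, abs=1e-12)

    def test_dim_mismatch(self):
        rule = FuzzyRule(np.zeros(2), np.ones(2), np.zeros((7, 2)), np.zeros(7))
        with pytest.raises(ValidationError):
            rule_firing(rule, np.zeros(3))


class TestNormalizeFirings:
    def test_single_rule(self):
        np.testing.assert_allclose(normalize_firings(np.array([0.3])), [1.0])

    def test_equal_pair(self):
        np.testing.assert_allclose(normalize_firings(np.array([0.2, 0.2])),
                                   [0.5, 0.5])

    def test_simplex_property(self, rng):
        for _ in range(50):
            f = rng.uniform(0, 1, rng.integers(1, 10))
            assert normalize_firings(f).sum() == pytest.approx(1.0)

    def test_underflow_falls_back_to_uniform(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_firings(np.zeros(4))
        np.testing.assert_allclose(out, 0.25)
        assert "underflow" in caplog.text


class TestForward:
    def test_consequent_hand_value(self):
        rule = FuzzyRule(np.zeros(2), np.ones(2),
                         weights=np.vstack([[1.0, 2.0]] + [[0, 0]] * 6),
                         biases=np.array([0.5, 0, 0, 0, 0, 0, 0.0]))
        out = consequent_output(rule, np.array([1.0, 1.0]), 1.0)
        assert out[0] == pytest.approx(3.5)

    def test_zero_firing_zero_contribution(self):
        rule = FuzzyRule(np.zeros(2), np.ones(2), np.ones((7, 2)), np.ones(7))
        np.testing.assert_allclose(
            consequent_output(rule, np.array([3.0, -1.0]), 0.0), 0.0
        )

    def test_single_rule_biases_pass_through(self):
        biases = np.arange(1.0, 8.0)
        model = one_rule_model(biases)
        np.testing.assert_allclose(forward(model, np.array([5.0, -3.0])), biases)

    def test_scores_convex_combination_of_consequents(self, rng):
        model = random_model(rng, n_rules=5, n_inputs=3)
        for _ in range(20):
            x = rng.normal(0, 1, 3)
            cons = np.stack([r.weights @ x + r.biases for r in model.rules])
            scores = forward(model, x)
            assert np.all(scores >= cons.min(axis=0) - 1e-9)
            assert np.all(scores <= cons.max(axis=0) + 1e-9)

    def test_rule_permutation_invariance(self, rng):
        model = random_model(rng, n_rules=4, n_inputs=3)
        x = rng.normal(0, 1, 3)
        base = forward(model, x)
        shuffled = SsNFModel(model.n_inputs, model.class_names,
                             rules=model.rules[::-1])
        np.testing.assert_allclose(forward(shuffled, x), base, atol=1e-12)


class TestClassify:
    def test_argmax_label(self):
        model = one_rule_model([0.1, 0.9, 0, 0, 0, 0, 0])
        assert classify(model, np.zeros(2)) == CLASS_NAMES[1]

    def test_tie_goes_to_lowest_index(self):
        model = one_rule_model([0.5, 0.2, 0.5, 0, 0, 0, 0])
        assert classify(model, np.zeros(2)) == CLASS_NAMES[0]

    def test_sensitive_to_score_order(self):
        a = one_rule_model([1, 2, 0, 0, 0, 0, 0])
        b = one_rule_model([2, 1, 0, 0, 0, 0, 0])
        assert classify(a, np.zeros(2)) != classify(b, np.zeros(2))


class TestStructureLearning:
    def _data(self, rng, n=70):
        X, y = [], []
        for i in range(n):
            c = i % 7
            X.append(rng.normal(0, 0.3, 4) + 3.0 * np.eye(7)[c, :4])
            y.append(CLASS_NAMES[c])
        return np.array(X), y

    def test_one_rule_per_class_at_class_means(self, rng):
        X, y = self._data(rng)
        model = init_structure(X, y, TrainConfig())
        assert len(model.rules) == 7
        y_arr = np.asarray(y)
        for rule, c in zip(model.rules, CLASS_NAMES):
            np.testing.assert_allclose(rule.centers, X[y_arr == c].mean(axis=0))
        assert all(np.all(r.widths >= 0.1) for r in model.rules)

    def test_growth_on_novel_sample(self, rng):
        X, y = self._data(rng)
        model = init_structure(X, y, TrainConfig())
        n0 = len(model.rules)
        far = np.full(4, 50.0)
        self_systematize(model, far, CLASS_NAMES[0], f_min=0.1)
        assert len(model.rules) == n0 + 1
        # a second pass on the same point fires the new rule at 1.0
        self_systematize(model, far, CLASS_NAMES[0], f_min=0.1)
        assert len(model.rules) == n0 + 1

    def test_no_growth_at_existing_center(self, rng):
        X, y = self._data(rng)
        model = init_structure(X, y, TrainConfig())
        n0 = len(model.rules)
        self_systematize(model, model.rules[0].centers.copy(), CLASS_NAMES[0], 0.1)
        assert len(model.rules) == n0

    def test_degenerate_data_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValidationError):
            init_structure(X, [CLASS_NAMES[0]] * 10, TrainConfig())


class TestLoss:
    def test_perfect_scores_zero_loss(self):
        model = one_rule_model([1, 0, 0, 0, 0, 0, 0])
        assert loss(model, np.zeros((1, 2)), [CLASS_NAMES[0]]) == 0.0

    def test_all_zero_scores(self):
        model = one_rule_model([0] * 7)
        assert loss(model, np.zeros((3, 2)), [CLASS_NAMES[0]] * 3) == pytest.approx(1 / 7)

    def test_nonnegative(self, rng):
        model = random_model(rng, 3, 2)
        X = rng.normal(0, 1, (10, 2))
        y = [CLASS_NAMES[i % 7] for i in range(10)]
        assert loss(model, X, y) >= 0.0


class TestTraining:
    def test_two_separated_clusters(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(6, 1, (30, 2))])
        y = [CLASS_NAMES[0]] * 30 + [CLASS_NAMES[3]] * 30
        tf, Xs = texture.standardize_features(X)
        model = train(Xs, y, TrainConfig(budget=1000, seed=1))
        acc = np.mean([p == t for p, t in zip(classify_batch(model, Xs), y)])
        assert acc >= 0.95

    def test_deterministic(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(5, 1, (15, 2))])
        y = [CLASS_NAMES[0]] * 15 + [CLASS_NAMES[4]] * 15
        tf, Xs = texture.standardize_features(X)
        a = train(Xs, y, TrainConfig(budget=300, seed=9))
        b = train(Xs, y, TrainConfig(budget=300, seed=9))
        for ra, rb in zip(a.rules, b.rules):
            np.testing.assert_array_equal(ra.centers, rb.centers)
            np.testing.assert_array_equal(ra.weights, rb.weights)

    def test_rule_growth_bounded(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = [CLASS_NAMES[i % 7] for i in range(40)]
        tf, Xs = texture.standardize_features(X)
        model = train(Xs, y, TrainConfig(budget=200, seed=0))
        assert len(model.rules) <= 7 + 40

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train(np.zeros((5, 2)), [CLASS_NAMES[0]] * 5, TrainConfig())


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        model = random_model(rng, 3, 4)
        p = tmp_path / "model.json"
        save_model(model, p)
        loaded = load_model(p)
        x = rng.normal(0, 1, (5, 4))
        np.testing.assert_allclose(forward_batch(loaded, x),
                                   forward_batch(model, x), atol=1e-12)

    def test_wrong_schema_version(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(SchemaError):
            load_model(p)

    def test_transform_preserved(self, rng, tmp_path):
        X = rng.normal(0, 1, (20, 4))
        tf, Xs = texture.standardize_features(X)
        model = random_model(rng, 2, 4)
        model.transform = tf
        p = tmp_path / "m.json"
        save_model(model, p)
        loaded = load_model(p)
        np.testing.assert_allclose(loaded.transform.apply(X), tf.apply(X))
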