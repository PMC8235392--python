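"""LSTM classifier: gradients, forward contracts, splitting, training."""

import numpy as np
import pytest

import thawspec as ts
from thawspec.lstm import _loss_from_probs, init_parameters, lstm_forward


def tiny_model(hidden=4, T=6, seed=3, dropout=0.0, l2=1e-3):
    cfg = ts.LSTMConfig(hidden_units=hidden, dropout_rate=dropout, l2_penalty=l2, seed=seed)
    rng = np.random.default_rng(seed)
    params = init_parameters(cfg, T, rng)
    for k in params:  # perturb biases/BN so no gradient is trivially zero
        params[k] = params[k] + rng.normal(0, 0.1, params[k].shape)
    return ts.ClassifierModel(
        cfg, params,
        running_mean=np.zeros((T, hidden)), running_var=np.ones((T, hidden)),
        x_mean=np.zeros(T), x_std=np.ones(T),
    )


def training_loss(model, X, y):
    """Forward in training mode without mutating the running statistics."""
    rm, rv = model.running_mean.copy(), model.running_var.copy()
    probs, cache = lstm_forward(model, X, training_mode=True)
    model.running_mean, model.running_var = rm, rv
    return _loss_from_probs(probs, y, model.params, model.config.l2_penalty), cache


class TestGradients:
    def test_analytic_matches_central_differences(self):
        """Every parameter tensor, full BPTT + batch-norm, within 1e-5."""
        model = tiny_model()
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 6, 1))
        y = np.array([0, 1, 0])
        _, cache = training_loss(model, X, y)
        grads = ts.lstm_gradients(model, cache, y)
        for key, g in grads.items():
            num = np.zeros_like(g)
            it = np.nditer(model.params[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = model.params[key][idx]
                h = 1e-5 * max(1.0, abs(orig))
                model.params[key][idx] = orig + h
                lp, _ = training_loss(model, X, y)
                model.params[key][idx] = orig - h
                lm, _ = training_loss(model, X, y)
                model.params[key][idx] = orig
                num[idx] = (lp - lm) / (2 * h)
            rel = np.abs(num - g) / np.maximum(1e-8, np.maximum(np.abs(num), np.abs(g)))
            assert rel.max() < 1e-5, f"{key}: max rel err {rel.max():.2e}"

    def test_l2_contribution_is_exactly_2_lambda_w(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3, 6, 1))
        y = np.array([1, 0, 1])
        m_reg = tiny_model(l2=1e-2)
        m_none = tiny_model(l2=0.0)
        m_none.params = {k: v.copy() for k, v in m_reg.params.items()}
        m_none.config = ts.LSTMConfig(hidden_units=4, dropout_rate=0.0, l2_penalty=0.0)
        _, cache_r = training_loss(m_reg, X, y)
        _, cache_n = training_loss(m_none, X, y)
        g_r = ts.lstm_gradients(m_reg, cache_r, y)
        g_n = ts.lstm_gradients(m_none, cache_n, y)
        for k in ("lstm1.Wx", "lstm2.Wh", "dense.W"):
            np.testing.assert_allclose(
                g_r[k] - g_n[k], 2 * 1e-2 * m_reg.params[k], rtol=1e-10, atol=1e-12
            )

    def test_dead_path_has_zero_gradient(self):
        """A dense weight feeding the non-target logit of an untouched class
        pair still gets gradient; but an input weight column whose unit is
        severed from the head (zero dense row) receives none."""
        model = tiny_model()
        model.params["dense.W"][2, :] = 0.0  # sever hidden unit 2 of layer 2
        rng = np.random.default_rng(6)
        X = rng.normal(size=(2, 6, 1))
        y = np.array([0, 1])
        # freeze recurrence into unit 2 as well so nothing routes around
        model.params["lstm2.Wh"][:, [2, 6, 10, 14]] = 0.0
        model.params["lstm2.Wh"][2, :] = 0.0
        _, cache = training_loss(model, X, y)
        grads = ts.lstm_gradients(model, cache, y)
        # gate columns writing only into unit 2 of layer 2: gradient is pure L2
        col = grads["lstm2.Wx"][:, 2] - 2 * model.config.l2_penalty * model.params["lstm2.Wx"][:, 2]
        np.testing.assert_allclose(col, 0.0, atol=1e-12)


class TestForward:
    def test_zero_weights_give_uniform_probabilities(self):
        model = tiny_model()
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        probs, _ = lstm_forward(model, np.random.default_rng(0).normal(size=(4, 6, 1)))
        np.testing.assert_allclose(probs, 0.5)

    def test_probabilities_sum_to_one(self):
        model = tiny_model()
        rng = np.random.default_rng(1)
        probs, _ = lstm_forward(model, rng.normal(size=(5, 6, 1)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_eval_mode_is_deterministic(self):
        model = tiny_model(dropout=0.5)
        X = np.random.default_rng(2).normal(size=(4, 6, 1))
        p1, _ = lstm_forward(model, X, training_mode=False)
        p2, _ = lstm_forward(model, X, training_mode=False)
        np.testing.assert_array_equal(p1, p2)

    def test_non_finite_input_rejected(self):
        model = tiny_model()
        X = np.zeros((1, 6, 1))
        X[0, 0, 0] = np.nan
        with pytest.raises(ts.ValidationError):
            lstm_forward(model, X)


class TestSplit:
    def test_proportions_90_90(self):
        labels = np.array(["fast"] * 90 + ["slow"] * 90)
        tr, te = ts.stratified_split(labels, 0.8, seed=0)
        assert len(tr) == 144 and len(te) == 36
        assert np.sum(labels[tr] == "fast") == 72
        assert np.sum(labels[te] == "fast") == 18
        assert len(np.intersect1d(tr, te)) == 0

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            ts.stratified_split(np.array(["a", "a", "b", "b"]), 1.0, seed=0)

    def test_same_seed_same_split(self):
        labels = np.array(["a"] * 20 + ["b"] * 20)
        s1 = ts.stratified_split(labels, 0.8, seed=7)
        s2 = ts.stratified_split(labels, 0.8, seed=7)
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])

    def test_group_aware_mode_keeps_groups_together(self):
        labels = np.repeat(["a", "b"], 45)
        groups = np.repeat(np.arange(10), 9)
        tr, te = ts.stratified_split(labels, 0.8, seed=1, groups=groups)
        assert set(groups[tr]).isdisjoint(set(groups[te]))


class TestTraining:
    def _toy_data(self, n=60, T=12, gap=2.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate(
            [rng.normal(0.0, 0.3, (n // 2, T)), rng.normal(gap, 0.3, (n // 2, T))]
        )
        y = np.array(["lo"] * (n // 2) + ["hi"] * (n // 2))
        return X, y

    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = self._toy_data()
        cfg = ts.LSTMConfig(hidden_units=8, seed=0, max_epochs=50, patience=50,
                            dropout_rate=0.1)
        model, rep = ts.train_classifier(X, y, cfg)
        assert rep.test_accuracy == 1.0

    def test_training_loss_decreases(self):
        X, y = self._toy_data(gap=1.0, seed=1)
        cfg = ts.LSTMConfig(hidden_units=8, seed=1, max_epochs=12, patience=12)
        _, rep = ts.train_classifier(X, y, cfg)
        assert rep.history[9]["train_loss"] < rep.history[0]["train_loss"]

    def test_permuted_labels_give_chance_accuracy(self):
        X, y = self._toy_data(n=90, gap=2.0, seed=2)
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        cfg = ts.LSTMConfig(hidden_units=8, seed=2, max_epochs=40, patience=40)
        _, rep = ts.train_classifier(X, y_perm, cfg)
        # 18 test samples: binomial 3 sigma around 0.5 is ~ +-0.35
        assert 0.15 <= rep.test_accuracy <= 0.85

    def test_uniform_model_loss_is_ln2(self):
        model = tiny_model()
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        model.classes = ("a", "b")
        X = np.random.default_rng(0).normal(size=(10, 6))
        acc, loss = ts.evaluate_classifier(model, X, np.array(["a"] * 5 + ["b"] * 5))
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_serialization_roundtrip_is_bitwise(self):
        X, y = self._toy_data(seed=4)
        cfg = ts.LSTMConfig(hidden_units=6, seed=4, max_epochs=8, patience=8)
        model, _ = ts.train_classifier(X, y, cfg)
        clone = ts.ClassifierModel.from_json(model.to_json())
        p1 = model.predict_proba(X)
        p2 = clone.predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_training_is_seed_deterministic(self):
        X, y = self._toy_data(seed=5)
        cfg = ts.LSTMConfig(hidden_units=6, seed=9, max_epochs=6, patience=6)
        _, r1 = ts.train_classifier(X, y, cfg)
        _, r2 = ts.train_classifier(X, y, cfg)
        assert r1.history == r2.history
        assert r1.test_accuracy == r2.test_accuracy
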