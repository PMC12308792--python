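"""Training loop, early stopping, prediction, gradient correctness."""

import numpy as np
import pytest

import molorb as mo
from molorb.fingerprint import pack_graphs
from molorb.regressor import (
    Hyperparameters,
    NeuralFingerprintRegression,
    TrainingHistory,
    early_stop_check,
    gradient_check,
    init_model,
    loss_and_grads,
    model_forward,
    predict_energy,
)


class TestEarlyStop:
    def test_flat_tail_stops(self):
        assert early_stop_check([0.5] * 20)

    def test_decreasing_does_not_stop(self):
        losses = [1.0 - 0.1 * i for i in range(30)]
        assert not early_stop_check(losses)

    def test_band_boundary_inclusive(self):
        # spread of the last 20 exactly equals the band
        losses = [0.51] + [0.50] * 18 + [0.51]
        assert max(losses) - min(losses) == pytest.approx(0.01)
        assert early_stop_check(losses, window=20, band=0.01)

    def test_short_history_cannot_stop(self):
        assert not early_stop_check([0.5] * 19)

    def test_accepts_history_object(self):
        h = TrainingHistory(val_loss=[0.3] * 25)
        assert early_stop_check(h)


class TestHyperparameters:
    def test_grid_validation(self):
        Hyperparameters().validate(strict_grid=True)
        with pytest.raises(ValueError):
            Hyperparameters(fp_length=48).validate(strict_grid=True)
        with pytest.raises(ValueError):
            Hyperparameters(learning_rate=0.5).validate(strict_grid=True)


class TestPrediction:
    def test_deterministic(self, tiny_hyper):
        model = init_model(tiny_hyper, "homo", seed=1)
        a = predict_energy("CCO", model)
        b = predict_energy("CCO", model)
        assert a == b

    def test_zero_ann_weights_predict_standardization_mean(self, tiny_hyper):
        model = init_model(tiny_hyper, "homo", seed=1)
        model.y_mean, model.y_std = -6.5, 1.3
        for k in model.weights:
            if k.startswith(("ann:", "annout:")):
                model.weights[k][:] = 0.0
        assert predict_energy("CC(=O)O", model) == pytest.approx(-6.5)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            init_model(Hyperparameters(), "bandgap", seed=0)


class TestGradients:
    def test_end_to_end_finite_difference(self, tiny_hyper):
        """Analytic backprop through GCN+ANN matches central differences."""
        model = init_model(tiny_hyper, "homo", seed=3)
        graphs = [mo.parse_smiles(s) for s in ["CCOCC", "CC(=O)O", "c1ccccc1"]]
        pack = pack_graphs(graphs)
        y = np.array([-6.0, -5.5, -7.2])
        worst = gradient_check(pack, model, y, eps=1e-4, n_per_array=4)
        assert worst < 1e-4

    def test_directional_derivative(self, tiny_hyper):
        """Full-gradient directional check, independent of the sampled one."""
        model = init_model(tiny_hyper, "homo", seed=4)
        pack = pack_graphs([mo.parse_smiles("CCOCC")])
        y = np.array([-6.0])
        _, grads = loss_and_grads(pack, model, y)
        rng = np.random.default_rng(0)
        v = {k: rng.normal(size=w.shape) for k, w in model.weights.items()}
        eps = 1e-6
        for k in model.weights:
            model.weights[k] += eps * v[k]
        lp, _ = loss_and_grads(pack, model, y)
        for k in model.weights:
            model.weights[k] -= 2 * eps * v[k]
        lm, _ = loss_and_grads(pack, model, y)
        fd = (lp - lm) / (2 * eps)
        an = sum((grads[k] * v[k]).sum() for k in grads)
        assert abs(fd - an) / max(abs(fd), abs(an)) < 1e-6


class TestTraining:
    def test_seed_determinism(self, tiny_surrogate_split):
        train, _, val = tiny_surrogate_split
        hyper = Hyperparameters(max_epochs=3, hidden_width=8, ann_width=8,
                                batch_size=64)
        m1 = NeuralFingerprintRegression(train, val, "surrogate", hyper).fit(5)
        m2 = NeuralFingerprintRegression(train, val, "surrogate", hyper).fit(5)
        for k in m1.model.weights:
            np.testing.assert_array_equal(
                m1.model.weights[k], m2.model.weights[k]
            )
        assert m1.history.val_loss == m2.history.val_loss

    def test_training_reduces_loss(self, tiny_surrogate_split, tiny_hyper):
        """Trained model beats its own random initialization on held-out MSE."""
        train, test, val = tiny_surrogate_split
        spec = NeuralFingerprintRegression(train, val, "surrogate", tiny_hyper)
        untrained = init_model(tiny_hyper, "surrogate", seed=0)
        untrained.y_mean = float(np.mean(spec.train_y))
        untrained.y_std = float(np.std(spec.train_y))
        res = spec.fit(seed=0)
        graphs = [mo.parse_smiles(s) for s in test.df["smiles"]]
        pack = pack_graphs(graphs)
        y = test.df["surrogate_target"].to_numpy(float)
        mse_before = np.mean((model_forward(pack, untrained) - y) ** 2)
        mse_after = np.mean((model_forward(pack, res.model) - y) ** 2)
        assert mse_after < mse_before

    def test_l2_shrinks_weight_norm(self, tiny_surrogate_split):
        train, _, val = tiny_surrogate_split
        base = dict(max_epochs=10, hidden_width=8, ann_width=8, batch_size=64)
        free = NeuralFingerprintRegression(
            train, val, "surrogate", Hyperparameters(l2=0.0, **base)
        ).fit(seed=2)
        pen = NeuralFingerprintRegression(
            train, val, "surrogate", Hyperparameters(l2=0.01, **base)
        ).fit(seed=2)

        def wnorm(m):
            return sum(
                float((v**2).sum()) for k, v in m.model.weights.items()
                if ":W" in k or k.startswith(("conv:", "out:"))
            )

        assert wnorm(pen) < wnorm(free)

    def test_constant_target_converges_to_constant(self):
        ds = mo.generate_synthetic_dataset(60, seed=9)
        ds.df["surrogate_target"] = -4.0
        hyper = Hyperparameters(max_epochs=10, hidden_width=8, ann_width=8,
                                batch_size=32)
        res = NeuralFingerprintRegression(ds, None, "surrogate", hyper).fit(0)
        preds = res.predict(ds)
        np.testing.assert_allclose(preds, -4.0, atol=0.2)

    def test_missing_target_column_errors(self):
        ds = mo.generate_synthetic_dataset(10, seed=1)
        with pytest.raises(ValueError):
            NeuralFingerprintRegression(ds, None, "homo", Hyperparameters())

    def test_summary_mentions_key_facts(self, tiny_members):
        res = mo.regressor.NeuralFingerprintResults(None, tiny_members[0])
        text = res.summary()
        assert "SURROGATE" in text
        assert "GCN layers" in text and "epochs run" in text
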