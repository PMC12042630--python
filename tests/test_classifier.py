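"""Network architectures, training contracts, and the ablation harness."""

import numpy as np
import pytest

from toothseq import nn
from toothseq.classifier import (
    ModelConfig,
    TrainingConfig,
    build_model,
    evaluate,
    parameter_count,
    predict,
    run_ablation,
    train,
)
from toothseq.encoding import extract_features, to_feature_image


def _tiny_cfg(variant="GRU", units=6, T=5, D=4, K=4):
    return ModelConfig(
        variant=variant,
        recurrent_units=units,
        fc_units=5,
        num_classes=K,
        input_shape=(T, D),
    )


def _images(rng, n, T, D):
    return [rng.standard_normal((T, D)) for _ in range(n)]


class TestBuildModel:
    @pytest.mark.parametrize("variant", ["GRU", "LSTM", "RNN", "CNN"])
    def test_softmax_output_is_probability_vector(self, variant, rng):
        model = build_model(_tiny_cfg(variant))
        X = rng.standard_normal((3, 5, 4))
        logits, _ = model.forward(X)
        probs = nn.softmax(logits)
        assert probs.shape == (3, 4)
        assert np.all(probs >= 0)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_output_dimension_matches_classes(self):
        for k in (4, 8, 16):
            model = build_model(_tiny_cfg(K=k))
            logits, _ = model.forward(np.zeros((1, 5, 4)))
            assert logits.shape == (1, k)

    def test_invalid_num_classes(self):
        with pytest.raises(ValueError, match="num_classes"):
            ModelConfig(num_classes=5)

    def test_gru_parameter_count_closed_form(self):
        """2 GRU layers + FC(64) + head, counted by hand:
        each GRU layer has 3·(d_in·U + U² + U) parameters."""
        U, D, K, F = 128, 12, 16, 64
        cfg = ModelConfig(
            variant="GRU", recurrent_units=U, fc_units=F, num_classes=K,
            input_shape=(900, D),
        )
        expected = (
            3 * (D * U + U * U + U)
            + 3 * (U * U + U * U + U)
            + (U * F + F)
            + (F * K + K)
        )
        assert parameter_count(build_model(cfg)) == expected


class TestGradients:
    @pytest.mark.parametrize("variant", ["GRU", "LSTM", "RNN", "CNN"])
    def test_analytic_gradients_match_finite_differences(self, variant):
        cfg = _tiny_cfg(variant, T=6, D=4)
        model = build_model(cfg)
        rng = np.random.default_rng(1)
        model.init_params(rng)
        X = rng.standard_normal((3, 6, 4))
        y = np.array([0, 2, 3])
        logits, cache = model.forward(X)
        _, dlogits, _ = nn.softmax_xent(logits, y)
        grads = model.backward(dlogits, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for name, g in grads.items():
            p = model.params[name]
            flat = p.reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                l1, _, _ = nn.softmax_xent(model.forward(X)[0], y)
                flat[idx] = orig - eps
                l2, _, _ = nn.softmax_xent(model.forward(X)[0], y)
                flat[idx] = orig
                num = (l1 - l2) / (2 * eps)
                ana = g.reshape(-1)[idx]
                assert abs(num - ana) < 1e-4 * max(1.0, abs(num)), (
                    f"{variant} {name}[{idx}]: numeric {num} vs analytic {ana}"
                )


class TestTraining:
    def test_same_seed_identical_loss(self, rng):
        cfg = _tiny_cfg()
        data = list(zip(_images(rng, 12, 5, 4), [i % 4 for i in range(12)]))
        tcfg = TrainingConfig(epochs=5, batch_size=4, val_fraction=0.0,
                              early_stopping_patience=0, seed=3)
        _, h1 = train(build_model(cfg), data, tcfg)
        _, h2 = train(build_model(cfg), data, tcfg)
        assert abs(h1["train_loss"][-1] - h2["train_loss"][-1]) < 1e-6

    def test_zero_learning_rate_freezes_loss(self, rng):
        cfg = _tiny_cfg()
        cfg.learning_rate = 0.0
        data = list(zip(_images(rng, 10, 5, 4), [i % 4 for i in range(10)]))
        _, h = train(
            build_model(cfg),
            data,
            TrainingConfig(epochs=4, batch_size=3, val_fraction=0.0,
                           early_stopping_patience=0, seed=0),
        )
        assert max(h["train_loss"]) - min(h["train_loss"]) < 1e-9

    def test_label_out_of_range_rejected_before_training(self, rng):
        data = [(rng.standard_normal((5, 4)), 7)]
        with pytest.raises(ValueError, match="label 7"):
            train(build_model(_tiny_cfg()), data, TrainingConfig())

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(_tiny_cfg()), [], TrainingConfig())

    def test_loss_history_is_finite(self, rng):
        data = list(zip(_images(rng, 8, 5, 4), [i % 2 for i in range(8)]))
        _, h = train(
            build_model(_tiny_cfg()),
            data,
            TrainingConfig(epochs=3, batch_size=4, val_fraction=0.0,
                           early_stopping_patience=0, seed=0),
        )
        assert np.isfinite(h["train_loss"]).all()


class TestPredictEvaluate:
    def test_argmax_and_tie_break(self):
        model = build_model(_tiny_cfg())
        # zero head weights force equal logits -> uniform probabilities -> tie
        model.params["head.W"][:] = 0.0
        model.params["head.b"][:] = 0.0
        label, probs = predict(model, np.zeros((5, 4)))
        assert label == 0
        assert np.abs(probs - 0.25).max() < 1e-12

    def test_shape_mismatch(self):
        model = build_model(_tiny_cfg())
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((9, 4)))

    def test_predict_consistent_with_evaluate(self, rng):
        cfg = _tiny_cfg()
        model = build_model(cfg)
        data = list(zip(_images(rng, 10, 5, 4), [i % 4 for i in range(10)]))
        report = evaluate(model, data)
        preds = [predict(model, x)[0] for x, _ in data]
        from toothseq import compute_metrics

        again = compute_metrics([y for _, y in data], preds, labels=[0, 1, 2, 3])
        assert np.array_equal(report.confusion, again.confusion)

    def test_evaluate_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(build_model(_tiny_cfg()), [])


class TestAblationHarness:
    def test_single_cell_and_determinism(self, small_bank):
        meshes, _ = small_bank
        dataset = [(m, i % 4) for i, m in enumerate(meshes)]
        kwargs = dict(
            variants=("GRU",),
            subsets=("both",),
            seeds=(0,),
            num_classes=4,
            model_overrides={"recurrent_units": 8},
            training=TrainingConfig(epochs=2, val_fraction=0.0,
                                    early_stopping_patience=0),
        )
        t1 = run_ablation(dataset, **kwargs)
        t2 = run_ablation(dataset, **kwargs)
        assert len(t1) == 1
        assert np.isfinite(t1.loc[0, "mean_accuracy"])
        assert t1.equals(t2)

    def test_needs_a_seed(self, small_bank):
        meshes, _ = small_bank
        with pytest.raises(ValueError, match="seed"):
            run_ablation([(m, 0) for m in meshes], seeds=())
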