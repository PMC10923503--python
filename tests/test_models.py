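import numpy as np
import pytest

from idnet.errors import ConfigurationError, DataError, LabelError
from idnet.models import (
    DEFAULT_EPOCHS,
    DEFAULT_MODELS,
    ModelSpec,
    TrainedModel,
    build_model,
    default_specs,
    evaluate,
    fit_and_score,
    train,
)
from idnet.models._engine import (
    BatchNorm,
    Conv1D,
    Dense,
    GlobalAvgPool,
    Network,
    ReLU,
)


def _sine_problem(rng, length=128, n=30, f_a=6.0, f_b=25.0, noise=0.3, rate=250.0):
    t = np.arange(length) / rate

    def cls(f, n):
        return np.array(
            [
                np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                + noise * rng.standard_normal(length)
                for _ in range(n)
            ]
        )

    x = np.vstack([cls(f_a, n), cls(f_b, n)])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    return x, y


class TestSpecs:
    def test_unknown_architecture_rejected(self):
        with pytest.raises(ConfigurationError, match="architecture"):
            ModelSpec("transformer", 100)

    def test_epoch_defaults_per_architecture(self):
        assert DEFAULT_EPOCHS["cnn"] == 200
        assert all(DEFAULT_EPOCHS[m] == 20 for m in ("resnet", "fcn", "mcdcnn", "mlp"))
        assert ModelSpec("cnn", 100).effective_epochs == 200
        assert ModelSpec("fcn", 100).effective_epochs == 20

    def test_default_zoo_excludes_mlp_and_keeps_registry_order(self):
        specs = default_specs(100)
        assert [s.architecture for s in specs] == list(DEFAULT_MODELS)
        assert "mlp" not in DEFAULT_MODELS

    def test_knn_fallback_needs_no_epochs(self):
        spec = ModelSpec("knn_fallback", 100)
        assert not spec.trainable
        build_model(spec)  # must not require epochs


class TestEngineGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of a conv + BN + dense net agree with numeric ones."""
        rng = np.random.default_rng(7)
        net = Network(
            [Conv1D(1, 3, 5), BatchNorm(3), ReLU(), GlobalAvgPool(), Dense(3, 2)],
            head="softmax",
        )
        net.init(0)
        x = rng.standard_normal((4, 12))
        y = np.array([0, 1, 0, 1])

        def loss() -> float:
            logits = net._forward(x, train=True)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return float(-np.log(p[np.arange(4), y]).mean())

        # analytic pass
        logits = net._forward(x, train=True)
        grad = net._loss_grad(logits, y)
        for layer in reversed(net.layers):
            grad = layer.backward(grad)

        eps = 1e-6
        for p, g in net.params:
            flat = p.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-6)


class TestTrainEvaluate:
    def test_fallback_training_is_deterministic(self):
        rng = np.random.default_rng(0)
        x, y = _sine_problem(rng)
        spec = ModelSpec("knn_fallback", x.shape[1])
        preds = []
        for _ in range(2):
            m = train(build_model(spec), x, y, spec, ("a", "b"))
            preds.append(m.predict(x))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_constant_classes_are_perfectly_separable(self):
        x = np.vstack([np.zeros((8, 64)), np.ones((8, 64))])
        y = np.r_[np.zeros(8, dtype=int), np.ones(8, dtype=int)]
        spec = ModelSpec(
            "fcn",
            64,
            epochs=50,
            seed=0,
            hyperparams={"filters": (4, 8, 4), "batch_size": 4},
        )
        m = train(build_model(spec), x, y, spec, ("lo", "hi"))
        assert evaluate(m, x, y) == 1.0

    def test_segment_length_mismatch_is_a_shape_error(self):
        spec = ModelSpec("knn_fallback", 100)
        with pytest.raises(DataError, match="input_length"):
            train(build_model(spec), np.zeros((4, 64)), np.array([0, 0, 1, 1]), spec, ("a", "b"))

    def test_evaluate_is_the_fraction_correct(self):
        class Fixed:
            def predict(self, x):
                return np.array([0, 1, 0, 0])

        m = TrainedModel(ModelSpec("knn_fallback", 4), ("a", "b"), Fixed())
        assert evaluate(m, np.zeros((4, 4)), np.array([0, 1, 0, 1])) == 0.75

    def test_evaluate_rejects_unseen_labels(self):
        spec = ModelSpec("knn_fallback", 8)
        x = np.vstack([np.zeros((4, 8)), np.ones((4, 8))])
        y = np.r_[np.zeros(4, dtype=int), np.ones(4, dtype=int)]
        m = train(build_model(spec), x, y, spec, ("a", "b"))
        with pytest.raises(LabelError):
            evaluate(m, x, np.array([0, 1, 2, 0, 1, 0, 1, 0]))

    def test_score_invariant_to_test_set_order(self):
        rng = np.random.default_rng(1)
        x, y = _sine_problem(rng)
        spec = ModelSpec("knn_fallback", x.shape[1])
        m = train(build_model(spec), x[::2], y[::2], spec, ("a", "b"))
        s1 = evaluate(m, x[1::2], y[1::2])
        perm = rng.permutation(len(y[1::2]))
        s2 = evaluate(m, x[1::2][perm], y[1::2][perm])
        assert s1 == s2


class TestModelAgreementOnExtremes:
    """Fallback and a net agree: both near 1 on separated data, both near
    chance on exchangeable data."""

    @pytest.mark.parametrize(
        "arch,hp",
        [
            ("knn_fallback", {}),
            ("fcn", {"filters": (8, 16, 8)}),
        ],
    )
    def test_separated_pair_scores_high(self, arch, hp):
        rng = np.random.default_rng(2)
        x, y = _sine_problem(rng, n=40)
        xt, yt = _sine_problem(rng, n=20)
        spec = ModelSpec(arch, x.shape[1], epochs=20, seed=1, hyperparams=hp)
        assert fit_and_score(spec, x, y, xt, yt) >= 0.9

    @pytest.mark.parametrize(
        "arch,hp",
        [
            ("knn_fallback", {}),
            ("fcn", {"filters": (8, 16, 8)}),
        ],
    )
    def test_exchangeable_pair_scores_at_chance(self, arch, hp):
        rng = np.random.default_rng(3)
        shared = rng.standard_normal((60, 128))
        x = np.vstack([shared[:30], shared[:30]]) + 0.05 * rng.standard_normal((60, 128))
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        xt = np.vstack([shared[30:], shared[30:]]) + 0.05 * rng.standard_normal((60, 128))
        spec = ModelSpec(arch, 128, epochs=20, seed=1, hyperparams=hp)
        score = fit_and_score(spec, x, y, xt, y)
        assert abs(score - 0.5) <= 1.96 * np.sqrt(0.25 / 60) + 0.05
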