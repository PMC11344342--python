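"""3D CNN: layer correctness vs oracles, config rules, training mechanics."""

import numpy as np
import pytest

from helpers import direct_conv3d
from spherotype.dataset import STANDARD_SHAPE, CellSample
from spherotype.nn.layers import (
    BatchNorm3D,
    Conv3D,
    MaxPool3D,
    softmax_cross_entropy,
)
from spherotype.nn.model import CNN3D, ModelConfig, build_model
from spherotype.nn.train import (
    categorical_cross_entropy,
    predict,
    run_seeds,
    train_bootstrap,
    train_run,
)
from spherotype.synthetic import FIBROBLAST, TUMOR


class TestConv:
    def test_forward_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        conv = Conv3D(2, 4, 5, rng)
        x = rng.standard_normal((2, 2, 6, 7, 9)).astype(np.float32)
        y = conv.forward(x)
        ref = direct_conv3d(
            x.astype(float), conv.w.astype(float), conv.b.astype(float)
        )
        np.testing.assert_allclose(y, ref, atol=1e-4)

    def test_forward_matches_direct_convolution_chunked(self):
        rng = np.random.default_rng(1)
        conv = Conv3D(3, 2, 3, rng)
        conv._CHUNK_LIMIT = 1  # force the per-sample spectral path
        x = rng.standard_normal((3, 3, 5, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(
            conv.forward(x),
            direct_conv3d(x.astype(float), conv.w.astype(float), conv.b.astype(float)),
            atol=1e-4,
        )

    @pytest.mark.parametrize("param", ["x", "w", "b"])
    def test_gradients_match_finite_differences(self, param):
        rng = np.random.default_rng(2)
        conv = Conv3D(2, 3, 5, rng)
        x = rng.standard_normal((2, 2, 6, 6, 6)).astype(np.float32)
        dy = rng.standard_normal((2, 3, 6, 6, 6)).astype(np.float32)
        conv.forward(x)
        dx = conv.backward(dy)
        eps = 1e-2
        if param == "x":
            i = (1, 0, 3, 2, 4)
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num = ((conv.forward(xp) * dy).sum() - (conv.forward(xm) * dy).sum()) / (2 * eps)
            got = dx[i]
        elif param == "w":
            i = (2, 1, 0, 3, 4)
            w0 = conv.w.copy()
            conv.w = w0.copy(); conv.w[i] += eps
            up = (conv.forward(x) * dy).sum()
            conv.w = w0.copy(); conv.w[i] -= eps
            dn = (conv.forward(x) * dy).sum()
            conv.w = w0
            conv.forward(x); conv.backward(dy)
            num, got = (up - dn) / (2 * eps), conv.dw[i]
        else:
            b0 = conv.b.copy()
            conv.b = b0.copy(); conv.b[1] += eps
            up = (conv.forward(x) * dy).sum()
            conv.b = b0.copy(); conv.b[1] -= eps
            dn = (conv.forward(x) * dy).sum()
            conv.b = b0
            conv.forward(x); conv.backward(dy)
            num, got = (up - dn) / (2 * eps), conv.db[1]
        assert got == pytest.approx(num, rel=2e-2, abs=2e-2)

    def test_first_layer_skips_input_gradient(self):
        rng = np.random.default_rng(3)
        conv = Conv3D(2, 2, 3, rng, first_layer=True)
        x = rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
        conv.forward(x)
        assert conv.backward(np.ones((1, 2, 4, 4, 4), np.float32)) is None
        assert np.abs(conv.dw).sum() > 0


class TestLayers:
    def test_batchnorm_normalizes_and_tracks_running_stats(self):
        rng = np.random.default_rng(4)
        bn = BatchNorm3D(3)
        x = (rng.standard_normal((8, 3, 4, 5, 5)) * 5 + 2).astype(np.float32)
        y = bn.forward(x, train=True)
        assert np.allclose(y.mean(axis=(0, 2, 3, 4)), 0, atol=1e-4)
        assert np.allclose(y.std(axis=(0, 2, 3, 4)), 1, atol=1e-3)
        for _ in range(60):
            bn.forward(x, train=True)
            bn.backward(np.zeros_like(x))
        y_eval = bn.forward(x, train=False)
        assert np.allclose(y_eval.mean(axis=(0, 2, 3, 4)), 0, atol=0.05)

    def test_maxpool_drops_odd_trailing_planes(self):
        x = np.arange(2 * 1 * 5 * 4 * 3, dtype=np.float32).reshape(2, 1, 5, 4, 3)
        mp = MaxPool3D()
        y = mp.forward(x)
        assert y.shape == (2, 1, 2, 2, 1)
        assert y[0, 0, 0, 0, 0] == x[0, 0, 1, 1, 1]

    def test_softmax_cross_entropy_closed_forms(self):
        logits = np.array([[0.0, 0.0]])
        loss, grad, probs = softmax_cross_entropy(logits, np.array([0]))
        assert loss == pytest.approx(np.log(2))
        assert probs[0].tolist() == pytest.approx([0.5, 0.5])
        big = np.array([[30.0, -30.0]])
        loss2, _, _ = softmax_cross_entropy(big, np.array([0]))
        assert loss2 == pytest.approx(0.0, abs=1e-6)


class TestCategoricalCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert categorical_cross_entropy([1, 0], [1 - 1e-9, 1e-9]) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_uniform_prediction_ln2(self):
        assert categorical_cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_zero_probability_clipped_finite(self):
        loss = categorical_cross_entropy([1, 0], [0.0, 1.0])
        assert np.isfinite(loss) and loss > 10

    def test_nonnegative_on_batches(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet([1, 1], size=50)
        y = np.eye(2)[rng.integers(0, 2, 50)]
        assert categorical_cross_entropy(y, p) >= 0


class TestModelConfig:
    def test_feature_dims_after_three_pools(self):
        assert ModelConfig().feature_dims() == (2, 6, 6)

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError, match="collapse"):
            ModelConfig(n_conv_blocks=5)

    def test_lr_schedule_exponential(self):
        cfg = ModelConfig(learning_rate=1e-4, lr_decay=0.9)
        assert cfg.lr_at(0) == pytest.approx(1e-4)
        assert cfg.lr_at(3) == pytest.approx(1e-4 * 0.9**3)


class TestModel:
    def test_forward_probabilities_sum_to_one(self):
        model = build_model(ModelConfig(seed=0))
        x = np.zeros((2, 3) + STANDARD_SHAPE, np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)

    def test_duplicate_inputs_identical_outputs(self):
        rng = np.random.default_rng(6)
        model = build_model(ModelConfig(seed=1))
        x = rng.standard_normal((1, 3) + STANDARD_SHAPE).astype(np.float32)
        batch = np.concatenate([x, x])
        probs = model.predict_proba(batch)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_wrong_shape_rejected(self):
        model = build_model(ModelConfig(seed=0))
        with pytest.raises(ValueError, match="shape"):
            model.predict_proba(np.zeros((1, 3, 10, 50, 50), np.float32))

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        model = build_model(ModelConfig(seed=2))
        model.norm_mean = rng.random(3).astype(np.float32)
        model.norm_std = (rng.random(3) + 0.5).astype(np.float32)
        x = rng.standard_normal((2, 3) + STANDARD_SHAPE).astype(np.float32)
        before = model.predict_proba(x)
        model.save(tmp_path / "m.npz")
        back = CNN3D.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.predict_proba(x), before)


def _tiny_samples(n_per_class, rng, n_images=4, separation=3.0):
    """Metadata + tensor samples with a crude channel-mean class signal."""
    out = []
    for i in range(2 * n_per_class):
        label = FIBROBLAST if i % 2 == 0 else TUMOR
        t = rng.standard_normal((3,) + STANDARD_SHAPE).astype(np.float32)
        if label == TUMOR:
            t[1] *= separation
        out.append(
            CellSample(
                sample_id=f"c{i}", label=label, source_image=f"img{i % n_images}",
                roi_label_id=i, f_index=1.0 if label == FIBROBLAST else 0.0,
                tensor=t,
            )
        )
    return out


class TestTraining:
    def test_run_seeds_distinct_and_bounded(self):
        seeds = run_seeds(123, 25)
        assert len(set(seeds)) == 25
        assert all(0 <= s < 2**31 for s in seeds)

    def test_best_run_selection_invariant(self):
        rng = np.random.default_rng(8)
        samples = _tiny_samples(16, rng)
        cfg = ModelConfig(seed=3)
        model, results = train_bootstrap(samples, cfg, n_runs=2, epochs=2)
        best = min(r.best_val_loss for r in results)
        assert all(best <= r.best_val_loss for r in results)
        assert all(r.best_val_loss == min(r.val_loss) for r in results)
        assert all(r.best_epoch == int(np.argmin(r.val_loss)) for r in results)

    def test_empty_split_rejected(self):
        cfg = ModelConfig(seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_run({"train": (np.zeros((0, 3) + STANDARD_SHAPE, np.float32),
                                 np.zeros(0, int)),
                       "val": (np.zeros((0, 3) + STANDARD_SHAPE, np.float32),
                               np.zeros(0, int))}, cfg, seed=0)

    def test_predict_returns_labels_and_probabilities(self):
        rng = np.random.default_rng(9)
        samples = _tiny_samples(4, rng)
        model = build_model(ModelConfig(seed=4))
        rows = predict(model, samples)
        assert len(rows) == 8
        assert all(r["label"] in (FIBROBLAST, TUMOR) for r in rows)
        assert all(0.5 <= r["probability"] <= 1.0 for r in rows)
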