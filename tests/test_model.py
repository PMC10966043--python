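"""Architecture construction: exact parameter counts, shape recurrence,
branch ablations, softmax behavior."""

import numpy as np
import pytest

from ginspect import nn
from ginspect.errors import ModelSpecError
from ginspect.model import (
    FccnnSpec,
    build_fccnn,
    build_image_branch,
    build_spectral_branch,
    count_parameters,
)

DEFAULT = FccnnSpec()  # 396 spectra + 256x1024x6 images, 7 classes


@pytest.fixture(scope="module")
def default_network():
    return build_fccnn(DEFAULT, np.random.default_rng(0))


class TestParameterCounts:
    """Layer-by-layer weight counts of the reference architecture."""

    def test_spectral_branch_counts(self):
        _, summary = build_spectral_branch(DEFAULT)
        assert summary.params_for("Dense") == [203264, 525312, 524800, 65664]
        assert summary.params_for("Dropout") == [0, 0, 0]

    def test_image_branch_counts(self):
        _, summary = build_image_branch(DEFAULT)
        assert summary.params_for("Conv") == [3520, 73856, 147584, 73792, 18464]
        assert summary.params_for("BatchNorm") == [256, 512, 512, 256, 128]
        assert summary.params_for("Dense") == [4194816]
        # flatten length after five pools of a 256x1024 input
        flat_row = [r for r in summary.rows if r[0] == "Flatten"][0]
        assert flat_row[1] == "(None, 8192)"

    def test_head_counts_and_concat_width(self, default_network):
        _, summary = default_network
        concat = [r for r in summary.rows if r[0] == "Concatenate"][0]
        assert concat[1] == "(None, 640)"
        assert summary.params_for("Dense")[-1] == 4487

    def test_total_matches_recount_from_arrays(self, default_network):
        net, summary = default_network
        assert count_parameters(net).total == summary.total == net.param_count

    def test_binary_head(self):
        spec = FccnnSpec(n_classes=2)
        _, summary = build_fccnn(spec)
        assert summary.params_for("Dense")[-1] == 640 * 2 + 2

    def test_tiny_input_formula(self):
        spec = FccnnSpec(spectral_input_len=1)
        _, summary = build_spectral_branch(spec)
        assert summary.params_for("Dense")[0] == 1 * 512 + 512

    def test_small_image_shape_recurrence(self):
        # 32x32x1: five pools -> 1x1x32 -> flatten 32 -> dense 32*512+512
        spec = FccnnSpec(image_shape=(32, 32), image_channels=1)
        _, summary = build_image_branch(spec)
        flat = [r for r in summary.rows if r[0] == "Flatten"][0]
        assert flat[1] == "(None, 32)"
        assert summary.params_for("Dense") == [32 * 512 + 512]


class TestSpecErrors:
    def test_indivisible_spatial_dims(self):
        with pytest.raises(ModelSpecError):
            build_image_branch(FccnnSpec(image_shape=(100, 1024)))

    def test_zero_channels(self):
        with pytest.raises(ModelSpecError):
            build_image_branch(FccnnSpec(image_channels=0))

    def test_non_positive_spectral_input(self):
        with pytest.raises(ModelSpecError):
            FccnnSpec(spectral_input_len=0)

    def test_both_branches_absent(self):
        with pytest.raises(ModelSpecError):
            FccnnSpec(spectral_input_len=None, image_channels=0)

    def test_zero_dim_dense_forbidden(self):
        with pytest.raises(ModelSpecError):
            nn.Dense(0, 4, np.random.default_rng(0))


class TestForward:
    def test_softmax_rows_sum_to_one(self):
        spec = FccnnSpec(
            spectral_input_len=12, image_shape=(32, 64), image_channels=2,
            n_classes=7, spectral_units=(8, 8, 8, 4), conv_filters=(4, 4, 4, 4, 4),
        )
        net, _ = build_fccnn(spec, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        p = net.predict_proba(rng.normal(size=(5, 12)), rng.normal(size=(5, 32, 64, 2)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-5)
        assert (p >= 0).all() and (p <= 1).all()

    def test_pure_spectral_ablation(self):
        """image_channels=0 degenerates to the spectra-only model: a
        128-wide embedding feeding the head directly."""
        spec = FccnnSpec(image_channels=0, n_classes=2)
        net, summary = build_fccnn(spec, np.random.default_rng(0))
        assert net.image is None
        assert summary.params_for("Dense")[-1] == 128 * 2 + 2
        p = net.predict_proba(np.random.default_rng(1).normal(size=(3, 396)), None)
        assert p.shape == (3, 2)

    def test_pure_image_ablation(self):
        spec = FccnnSpec(
            spectral_input_len=None, image_shape=(32, 64), image_channels=3,
            n_classes=2, conv_filters=(4, 4, 4, 4, 4),
        )
        net, summary = build_fccnn(spec, np.random.default_rng(0))
        assert net.spectral is None
        assert summary.params_for("Dense")[-1] == 512 * 2 + 2

    def test_pool_shape_recurrence_at_runtime(self):
        spec = FccnnSpec(
            spectral_input_len=None, image_shape=(64, 128), image_channels=2,
            n_classes=2, conv_filters=(4, 4, 4, 4, 4),
        )
        net, _ = build_fccnn(spec, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 64, 128, 2)).astype(np.float32)
        cur = x
        for layer in net.image.layers:
            cur = layer.forward(cur, training=False)
        assert cur.shape == (2, 512)


class TestTrainingMechanics:
    def test_numeric_gradient_check(self):
        """Backprop agrees with central finite differences through both
        branches (dropout off; batch statistics)."""
        spec = FccnnSpec(
            spectral_input_len=10, image_shape=(32, 32), image_channels=2,
            n_classes=3, dropout_spectral=0.0, dropout_image=0.0, dropout_head=0.0,
            spectral_units=(8, 6, 5, 4), conv_filters=(4, 4, 4, 4, 4),
        )
        rng = np.random.default_rng(0)
        net, _ = build_fccnn(spec, rng)
        for p, _ in net.params_grads():  # move off zero-init so grads flow
            if p.size and not p.any():
                p += rng.normal(0, 0.05, p.shape).astype(p.dtype)
        xs = rng.normal(size=(4, 10))
        xi = rng.normal(size=(4, 32, 32, 2))
        y = np.eye(3)[rng.integers(0, 3, 4)] * 0.9 + 0.1 / 3

        logits = net.forward(xs, xi, training=True)
        _, gz = nn.mae_softmax_grad(y, logits)
        net.backward(gz)

        def loss():
            return nn.mae(y, nn.softmax(net.forward(xs, xi, training=True)))

        bad = 0
        for p, g in net.params_grads():
            fp, fg = p.ravel(), g.ravel()
            for k in rng.choice(fp.size, min(3, fp.size), replace=False):
                old, eps = fp[k], 1e-3
                fp[k] = old + eps
                lp = loss()
                fp[k] = old - eps
                lm = loss()
                fp[k] = old
                num = (lp - lm) / (2 * eps)
                if abs(num - fg[k]) > 2e-3 * max(1.0, abs(num), abs(fg[k])):
                    bad += 1
        assert bad == 0

    def test_batchnorm_moving_stats_used_at_inference(self):
        bn = nn.BatchNorm(3)
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 3.0, size=(50, 3)).astype(np.float32)
        out_train = bn.forward(x, training=True)
        np.testing.assert_allclose(out_train.mean(axis=0), 0.0, atol=1e-5)
        out_eval = bn.forward(x, training=False)
        np.testing.assert_allclose(out_eval.mean(axis=0), 0.0, atol=1e-4)

    def test_dropout_inverted_scaling(self):
        rng = np.random.default_rng(0)
        d = nn.Dropout(0.5, rng)
        x = np.ones((200, 50), dtype=np.float32)
        out = d.forward(x, training=True)
        assert out.mean() == pytest.approx(1.0, abs=0.05)
        np.testing.assert_array_equal(d.forward(x, training=False), x)
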