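"""Residual artifact network: architecture contract, loss closed forms, gradients."""

import numpy as np
import pytest

from destreak.artifact_net import (
    NetworkConfig,
    TrainedModel,
    build_network,
    correct_image,
    predict_artifact,
    residual_loss,
)
from destreak.phantoms import Image2D

TINY = NetworkConfig(trunk_channels=4, n_inception_blocks=1,
                     inception_branch_kernels=(1, 3))


class TestConfig:
    def test_defaults_follow_trunk_contract(self):
        cfg = NetworkConfig()
        assert cfg.trunk_channels == 64
        assert cfg.n_inception_blocks == 8
        assert cfg.inception_branch_kernels == (1, 3, 5, 7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_inception_blocks=0),
            dict(inception_branch_kernels=(1, 4)),
            dict(trunk_channels=30),  # not divisible by 4 branches
            dict(entry_kernel=2),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)

    def test_json_round_trip(self):
        cfg = NetworkConfig.small()
        assert NetworkConfig.from_json(cfg.to_json()) == cfg


class TestBuildNetwork:
    @pytest.mark.parametrize("size", [32, 48, 64])
    def test_output_shape_matches_input(self, size):
        model = build_network(TINY, seed=0)
        x = np.random.default_rng(1).normal(size=(1, size, size, 1)).astype(np.float32)
        assert model.net.forward(x, training=False).shape == x.shape

    def test_seeded_init_is_bit_identical(self):
        a = build_network(NetworkConfig.small(), seed=5)
        b = build_network(NetworkConfig.small(), seed=5)
        c = build_network(NetworkConfig.small(), seed=6)
        pairs = list(zip(a.net.iter_layers(), b.net.iter_layers()))
        assert all(
            np.array_equal(la.params[k], lb.params[k])
            for la, lb in pairs for k in la.params
        )
        differs = any(
            not np.array_equal(la.params[k], lc.params[k])
            for la, lc in zip(a.net.iter_layers(), c.net.iter_layers())
            for k in la.params
        )
        assert differs

    def test_parameter_counts_pinned(self):
        """Regression values computed once from the layer shapes."""
        assert build_network(NetworkConfig(), seed=0).n_parameters() == 727_937
        assert build_network(NetworkConfig.small(), seed=0).n_parameters() == 53_121

    def test_one_scale_variant_structure(self):
        """multiscale=False gives plain 3x3 blocks of identical depth/width."""
        multi = build_network(NetworkConfig.small(), seed=0)
        plain = build_network(
            NetworkConfig(trunk_channels=32, n_inception_blocks=2, multiscale=False),
            seed=0,
        )
        plain_convs = [l for l in plain.net.iter_layers() if hasattr(l, "k")]
        multi_convs = [l for l in multi.net.iter_layers() if hasattr(l, "k")]
        # same depth in blocks: 2 entry convs + 2 block convs + head
        assert len(plain_convs) == 5
        assert len(multi_convs) == 2 + 2 * 4 + 1
        assert all(c.k == 3 for c in plain_convs)
        # block convs preserve the 32-channel trunk
        assert all(c.c_in == 32 and c.c_out == 32 for c in plain_convs[1:-1])

    def test_uneven_branch_split_rejected(self):
        with pytest.raises(ValueError):
            build_network(
                NetworkConfig(trunk_channels=32, inception_branch_kernels=(1, 3, 5)),
                seed=0,
            )


class TestPredict:
    def test_untrained_network_predicts_zero_artifact(self):
        """Zero-initialized head: mu(f) = 0 before training, for any input."""
        model = build_network(TINY, seed=0)
        f = Image2D(np.random.default_rng(0).uniform(0, 4095, (40, 40)))
        n_hat = predict_artifact(model, f)
        assert np.all(n_hat.pixels == 0.0)

    def test_inference_is_deterministic(self):
        model = build_network(TINY, seed=1)
        f = Image2D(np.random.default_rng(2).uniform(0, 4095, (40, 40)))
        a = predict_artifact(model, f)
        b = predict_artifact(model, f)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_small_input_rejected(self):
        model = build_network(TINY, seed=0)
        with pytest.raises(ValueError):
            predict_artifact(model, Image2D(np.zeros((16, 16))))

    def test_save_load_round_trip_is_bit_identical(self, tmp_path):
        model = build_network(NetworkConfig.small(), seed=3)
        model.training_meta["note"] = "round-trip"
        f = Image2D(np.random.default_rng(4).uniform(0, 4095, (48, 48)))
        before = predict_artifact(model, f)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.config == model.config
        assert loaded.training_meta["note"] == "round-trip"
        after = predict_artifact(loaded, f)
        np.testing.assert_array_equal(before.pixels, after.pixels)

    def test_tiled_prediction_matches_whole_image_interior(self):
        """Fully-convolutional consistency: tiles agree away from their edges."""
        model = build_network(TINY, seed=9)
        # give the head a nonzero value so predictions are non-trivial
        head = [l for l in model.net.iter_layers() if hasattr(l, "k")][-1]
        head.params["W"] = np.random.default_rng(0).normal(
            0, 0.05, head.params["W"].shape
        ).astype(np.float32)
        f = Image2D(np.random.default_rng(5).uniform(0, 4095, (96, 96)))
        whole = predict_artifact(model, f).pixels
        margin = 16
        for r0, c0 in [(0, 0), (0, 48), (48, 0), (48, 48)]:
            tile = Image2D(f.pixels[r0:r0 + 48, c0:c0 + 48])
            pred = predict_artifact(model, tile).pixels
            inner = slice(margin, 48 - margin)
            np.testing.assert_allclose(
                pred[inner, inner],
                whole[r0 + margin:r0 + 48 - margin, c0 + margin:c0 + 48 - margin],
                atol=1e-3,
            )


class TestCorrectImage:
    def test_zero_artifact_is_identity(self):
        f = Image2D(np.random.default_rng(0).uniform(0, 10, (32, 32)))
        out = correct_image(f, Image2D(np.zeros((32, 32))))
        np.testing.assert_array_equal(out.pixels, f.pixels)

    def test_oracle_residual_recovers_reference(self):
        rng = np.random.default_rng(1)
        # stored 12-bit counts: integer-valued, so subtraction is exact
        f = Image2D(np.rint(rng.uniform(0, 4095, (32, 32))))
        x = Image2D(np.rint(rng.uniform(0, 4095, (32, 32))))
        n = Image2D(f.pixels - x.pixels)
        np.testing.assert_array_equal(correct_image(f, n).pixels, x.pixels)

    def test_self_correction_is_zero(self):
        f = Image2D(np.random.default_rng(2).uniform(0, 10, (32, 32)))
        assert np.all(correct_image(f, f).pixels == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correct_image(Image2D(np.zeros((32, 32))), Image2D(np.zeros((40, 40))))


class TestResidualLoss:
    def test_perfect_prediction_gives_zero(self, rng):
        f = rng.uniform(0, 1, (3, 8, 8))
        x = rng.uniform(0, 1, (3, 8, 8))
        assert residual_loss(f - x, f, x) == 0.0

    def test_zero_prediction_closed_form(self, rng):
        f = rng.uniform(0, 1, (4, 8, 8))
        x = rng.uniform(0, 1, (4, 8, 8))
        expected = np.sum((f - x) ** 2) / (2 * 4)
        assert residual_loss(np.zeros_like(f), f, x) == pytest.approx(expected, rel=1e-14)

    def test_hand_computed_single_pixel_case(self):
        """f = 3, x = 1, prediction 0: loss = (1/2)(3-1)^2 = 2."""
        f = np.array([[[3.0]]])
        x = np.array([[[1.0]]])
        assert residual_loss(np.zeros((1, 1, 1)), f, x) == 2.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            residual_loss(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)), np.zeros((0, 4, 4)))

    def test_accepts_image2d_batches(self):
        f = [Image2D(np.full((16, 16), 3.0))]
        x = [Image2D(np.full((16, 16), 1.0))]
        n = [Image2D(np.zeros((16, 16)))]
        assert residual_loss(n, f, x) == pytest.approx(0.5 * 4.0 * 256)


def test_gradients_match_finite_differences():
    """Backprop vs central differences across all layer types (float64)."""
    rng = np.random.default_rng(0)
    cfg = NetworkConfig(trunk_channels=4, n_inception_blocks=1,
                        inception_branch_kernels=(1, 5))
    model = build_network(cfg, seed=3, dtype=np.float64)
    x = rng.normal(size=(2, 36, 36, 1))
    t = rng.normal(size=(2, 36, 36, 1))

    def loss():
        p = model.net.forward(x, True)
        return float(np.sum((p - t) ** 2) / (2 * x.shape[0]))

    pred = model.net.forward(x, True)
    model.net.backward((pred - t) / x.shape[0])
    checked = 0
    for layer in model.net.iter_layers():
        for name, grad in layer.grads.items():
            arr = layer.params[name]
            flat_idx = [0, arr.size // 2, arr.size - 1]
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                eps = 1e-6
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss()
                arr[idx] = orig - eps
                lm = loss()
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) <= 1e-5 + 1e-4 * max(abs(fd), abs(grad[idx]))
                checked += 1
    assert checked >= 30
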