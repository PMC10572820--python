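"""Network construction: layer inventory, filter schedule, shapes, inference."""

import numpy as np
import pytest

from glomseg.model import (
    ModifiedUNet,
    NetworkSpec,
    SpecError,
    build_modified_unet,
    feature_trace,
    layer_inventory,
    predict_mask,
    predict_proba,
)


class TestSpec:
    def test_canonical_defaults(self):
        spec = NetworkSpec.canonical()
        assert (spec.depth, spec.base_filters, spec.tile_size) == (5, 72, 512)

    def test_indivisible_tile_size_rejected(self):
        with pytest.raises(SpecError, match="divisible"):
            NetworkSpec(tile_size=500)

    def test_collapsed_width_rejected(self):
        with pytest.raises(SpecError, match="width_scale"):
            NetworkSpec(width_scale=0.0)

    def test_filter_schedule_closed_form(self):
        """Per-block widths follow F1(k) = 72*2^(k-1), F2(k) = 144*2^(k-1)."""
        spec = NetworkSpec.canonical()
        assert [spec.conv1_filters(k) for k in range(1, 6)] == [72, 144, 288, 576, 1152]
        assert [spec.conv2_filters(k) for k in range(1, 6)] == [144, 288, 576, 1152, 2304]
        assert spec.bottleneck_channels == 2304
        assert spec.bottleneck_size == 16

    def test_width_scale_applies_to_every_filter_count(self):
        spec = NetworkSpec(width_scale=0.125, tile_size=64)
        assert [spec.conv1_filters(k) for k in range(1, 6)] == [9, 18, 36, 72, 144]
        assert spec.bottleneck_channels == 288
        assert spec.bottleneck_size == 2


class TestInventory:
    def test_modified_unet_inventory(self):
        net = build_modified_unet(NetworkSpec(width_scale=0.01, tile_size=32))
        inv = layer_inventory(net)
        assert inv.as_dict() == {
            "convolutional": 15, "max_pooling": 5, "upsampling": 5,
            "normalization": 5, "concatenate": 5,
        }

    def test_baseline_unet_inventory(self):
        net = build_modified_unet(
            NetworkSpec.baseline_unet(width_scale=0.05, tile_size=32)
        )
        inv = layer_inventory(net)
        assert inv.as_dict() == {
            "convolutional": 12, "max_pooling": 4, "upsampling": 4,
            "normalization": 4, "concatenate": 4,
        }

    @pytest.mark.parametrize("scale,tile", [(0.01, 32), (0.125, 64), (0.05, 128)])
    def test_inventory_invariant_under_scale_and_size(self, scale, tile):
        net = build_modified_unet(NetworkSpec(width_scale=scale, tile_size=tile))
        assert layer_inventory(net)["convolutional"] == 15


class TestTrace:
    def test_encoder_spatial_progression(self):
        trace = feature_trace(NetworkSpec.canonical())
        assert trace.encoder_spatial_sizes == (512, 256, 128, 64, 32, 16)

    def test_bottleneck_and_output(self):
        trace = feature_trace(NetworkSpec.canonical())
        assert (trace.bottleneck.spatial, trace.bottleneck.channels) == (16, 2304)
        assert (trace.output.spatial, trace.output.channels) == (512, 1)

    def test_post_first_pool_width(self):
        trace = feature_trace(NetworkSpec.canonical())
        rec = trace.stage("enc1_pool")
        assert (rec.spatial, rec.channels) == (256, 144)

    def test_scaled_down_bottleneck(self):
        trace = feature_trace(NetworkSpec(width_scale=0.125, tile_size=64))
        assert (trace.bottleneck.spatial, trace.bottleneck.channels) == (2, 288)

    def test_tiny_tile_progression(self):
        trace = feature_trace(NetworkSpec(tile_size=32, width_scale=0.01))
        assert trace.encoder_spatial_sizes == (32, 16, 8, 4, 2, 1)

    def test_indivisible_size_rejected(self):
        with pytest.raises(SpecError, match="divisible"):
            feature_trace(NetworkSpec.canonical(), tile_size=100)

    def test_upsampling_doubles_and_pooling_halves(self):
        trace = feature_trace(NetworkSpec(width_scale=0.125, tile_size=64))
        records = list(trace)
        for prev, cur in zip(records, records[1:]):
            if cur.stage.endswith("_pool"):
                assert cur.spatial == prev.spatial // 2
            elif cur.stage.endswith("_up"):
                assert cur.spatial == prev.spatial * 2
            else:
                assert cur.spatial == prev.spatial
        assert records[0].spatial == records[-1].spatial == 64

    def test_trace_matches_constructed_graph_channels(self):
        """The symbolic trace agrees with the actual convolution layers."""
        spec = NetworkSpec(width_scale=0.125, tile_size=64)
        net = build_modified_unet(spec)
        trace = feature_trace(net)
        for k in range(1, 6):
            assert net.enc_conv1[k - 1].out_channels == trace.stage(f"enc{k}_conv1").channels
            assert net.enc_conv2[k - 1].out_channels == trace.stage(f"enc{k}_conv2").channels
        for j in range(1, 6):
            assert net.dec_conv[j - 1].out_channels == trace.stage(f"dec{j}_conv").channels


class TestForward:
    @pytest.mark.parametrize("tile_size", [32, 64])
    def test_shape_contract(self, tile_size):
        """Forward output is T x T x 1 with probabilities in [0, 1]."""
        spec = NetworkSpec(width_scale=0.02, tile_size=tile_size)
        net = build_modified_unet(spec, seed=0)
        x = np.random.default_rng(0).random((2, tile_size, tile_size, 3), np.float32)
        y = net.forward(x)
        assert y.shape == (2, tile_size, tile_size, 1)
        assert (y >= 0).all() and (y <= 1).all()

    def test_skip_connections_join_equal_spatial_sizes(self):
        """Every concatenate fuses the upsampled map with a same-resolution
        encoder activation (verified on a real forward pass by instrumenting
        the concatenate layers)."""
        spec = NetworkSpec(width_scale=0.02, tile_size=32)
        net = build_modified_unet(spec, seed=0)
        joined = []
        for cat in net.dec_cat:
            orig = cat.forward

            def spy(a, b, training, _orig=orig):
                joined.append((a.shape[1:3], b.shape[1:3]))
                return _orig(a, b, training)

            cat.forward = spy
        net.forward(np.zeros((1, 32, 32, 3), np.float32))
        assert len(joined) == 5
        assert all(a == b for a, b in joined)

    def test_predict_mask_thresholding(self):
        spec = NetworkSpec(width_scale=0.02, tile_size=32)
        net = build_modified_unet(spec, seed=1)
        img = np.random.default_rng(1).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        probs = predict_proba(net, img)
        mask = predict_mask(net, img, threshold=0.5)
        np.testing.assert_array_equal(mask, (probs >= 0.5).astype(np.uint8))
        assert mask.shape == img.shape[:2]
        assert set(np.unique(mask)) <= {0, 1}

    def test_predict_shape_mismatch_rejected(self):
        net = build_modified_unet(NetworkSpec(width_scale=0.02, tile_size=32))
        with pytest.raises(ValueError, match="does not match"):
            predict_mask(net, np.zeros((64, 64, 3), np.uint8))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Analytic gradients agree with float64 central differences through
        conv, batch norm, pooling, upsampling and concatenation."""
        spec = NetworkSpec(depth=2, base_filters=2, tile_size=8)
        net = build_modified_unet(spec, seed=3)
        for par in net.parameters():
            par.value = par.value.astype(np.float64)
            par.grad = np.zeros_like(par.value)
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 3))
        y = (rng.random((2, 8, 8, 1)) > 0.5).astype(np.float64)

        def loss_of(p):
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            return float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())

        p = net.forward(x, training=True)
        net.backward((p - y) / p.size)
        for par in net.parameters():
            flat, gflat = par.value.ravel(), par.grad.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                lp = loss_of(net.forward(x, training=True))
                flat[i] = orig - eps
                lm = loss_of(net.forward(x, training=True))
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_checkpoint_round_trip(tmp_path):
    spec = NetworkSpec(width_scale=0.02, tile_size=32)
    net = build_modified_unet(spec, seed=5)
    x = np.random.default_rng(2).random((1, 32, 32, 3), np.float32)
    before = net.forward(x)
    net.save(tmp_path / "ckpt.pkl")
    loaded = ModifiedUNet.load(tmp_path / "ckpt.pkl")
    np.testing.assert_allclose(loaded.forward(x), before, atol=1e-6)
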