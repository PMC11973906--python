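"""Architecture contracts: shapes, ablation toggles, parameter oracles."""

import numpy as np
import pytest

from lite_thyseg import nn
from lite_thyseg.conv_math import conv_param_count
from lite_thyseg.losses import tversky_loss
from lite_thyseg.network import (
    ChannelAttention,
    ModelConfig,
    SpatialAttention,
    build_aspp,
    build_encoder,
    build_model,
    build_ppm,
    expected_param_count,
    model_conv_specs,
    param_report,
)

# small widths keep forward passes cheap; architecture topology is identical
TINY = dict(input_size=96, width_multiplier=0.35, aspp_branch_channels=24,
            aspp_out_channels=32, ppm_branch_channels=16,
            ppm_pool_sizes=(1, 2, 3),
            decoder_channels={"fuse_s8": 24, "fuse_s4": 24, "shallow": 16,
                              "horizontal": 32, "simple": 32})


def tiny_config(**overrides):
    return ModelConfig(**{**TINY, **overrides})


class TestConfigValidation:
    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)
        with pytest.raises(ValueError):
            ModelConfig(output_stride=8)

    def test_rejects_duplicate_dilations(self):
        with pytest.raises(ValueError):
            ModelConfig(aspp_dilations=(6, 6, 18))

    def test_round_trips_through_dict(self):
        cfg = tiny_config(use_ppm=False)
        again = ModelConfig.from_dict(cfg.to_dict())
        assert again == cfg


class TestEncoder:
    @pytest.mark.parametrize("size,taps", [(512, (128, 64, 32)), (160, (40, 20, 10))])
    def test_tap_resolutions(self, size, taps):
        enc = build_encoder(tiny_config(input_size=size))
        x = nn.Tensor(np.zeros((1, 1, size, size), dtype=np.float32))
        s4, s8, s16 = enc(x)
        assert (s4.shape[2], s8.shape[2], s16.shape[2]) == taps
        assert s4.shape[3] == taps[0] and s16.shape[3] == taps[2]

    def test_rejects_indivisible_input(self):
        enc = build_encoder(tiny_config())
        with pytest.raises(ValueError):
            enc(nn.Tensor(np.zeros((1, 1, 50, 50), dtype=np.float32)))

    def test_param_count_matches_closed_form(self):
        enc = build_encoder(ModelConfig())
        assert enc.num_parameters() == expected_param_count(enc)


class TestASPP:
    def test_branch_effective_kernel(self):
        cfg = tiny_config()
        aspp = build_aspp(cfg, cin=16)
        spec = aspp.dilated[1].spec  # second branch, dilation 12
        assert spec.dilation == 12
        assert spec.kernel + (spec.kernel - 1) * (spec.dilation - 1) == 25

    def test_ds_toggle_changes_only_dilated_branches(self):
        on = build_aspp(tiny_config(use_ds_aspp=True), cin=16)
        off = build_aspp(tiny_config(use_ds_aspp=False), cin=16)
        diff = off.num_parameters() - on.num_parameters()
        per_branch_on = [b.num_parameters() for b in on.dilated]
        per_branch_off = [b.num_parameters() for b in off.dilated]
        assert diff == sum(per_branch_off) - sum(per_branch_on) > 0
        # non-dilated branches identical in size
        assert on.branch1x1.num_parameters() == off.branch1x1.num_parameters()
        assert on.project.num_parameters() == off.project.num_parameters()

    def test_preserves_spatial_size(self):
        aspp = build_aspp(tiny_config(), cin=16)
        y = aspp(nn.Tensor(np.random.default_rng(0)
                           .random((1, 16, 10, 10)).astype(np.float32)))
        assert y.shape == (1, 32, 10, 10)


class TestPPM:
    def test_branches_upsampled_and_stacked(self):
        cfg = tiny_config(ppm_pool_sizes=(1, 2, 3, 6))
        ppm = build_ppm(cfg, cin=32)
        x = nn.Tensor(np.random.default_rng(0).random((1, 32, 32, 32))
                      .astype(np.float32))
        y = ppm(x)
        assert y.shape == (1, 32 + 4 * cfg.ppm_branch_channels, 32, 32)

    def test_pool_size_one_is_broadcast_global_context(self):
        cfg = tiny_config(ppm_pool_sizes=(1,))
        ppm = build_ppm(cfg, cin=8)
        x = nn.Tensor(np.random.default_rng(1).random((1, 8, 6, 6))
                      .astype(np.float32))
        branch = ppm(x).data[:, 8:]
        assert np.allclose(branch, branch[:, :, :1, :1], atol=1e-6)

    def test_pool_exceeding_feature_size_rejected(self):
        ppm = build_ppm(tiny_config(ppm_pool_sizes=(1, 2, 3, 6)), cin=8)
        with pytest.raises(ValueError):
            ppm(nn.Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))

    def test_removing_ppm_shrinks_context_by_its_width(self):
        with_ppm = build_model(tiny_config(use_ppm=True))
        without = build_model(tiny_config(use_ppm=False))
        width = len(TINY["ppm_pool_sizes"]) * TINY["ppm_branch_channels"]
        assert (with_ppm.ppm.out_channels
                == without.aspp.out_channels + width)


class TestAttention:
    def test_zero_input_zero_output_and_weight_range(self):
        cam = ChannelAttention(8, reduction=4, rng=np.random.default_rng(0))
        sam = SpatialAttention(rng=np.random.default_rng(1))
        zeros = nn.Tensor(np.zeros((1, 8, 5, 5), dtype=np.float32))
        assert np.all(cam(zeros).data == 0)
        assert np.all(sam(zeros).data == 0)
        x = nn.Tensor(np.random.default_rng(2).random((2, 8, 5, 5))
                      .astype(np.float32))
        for module in (cam, sam):
            w = module.weights(x).data
            assert np.all((w > 0) & (w < 1))
            assert module(x).shape == x.shape

    def test_max_and_avg_paths_share_one_mlp(self):
        """On spatially constant input both pooled descriptors coincide, so
        the gate must equal sigmoid(2 * MLP(descriptor)) — true only if the
        two pooling paths really share the same bottleneck weights."""
        cam = ChannelAttention(6, reduction=2, rng=np.random.default_rng(3))
        desc = np.random.default_rng(4).random((1, 6, 1, 1)).astype(np.float32)
        x = nn.Tensor(np.broadcast_to(desc, (1, 6, 4, 4)).copy())
        w = cam.weights(x).data[0, :, 0, 0]
        mlp = cam.fc2(nn.relu(cam.fc1(nn.Tensor(desc)))).data
        expected = 1.0 / (1.0 + np.exp(-2.0 * mlp[0, :, 0, 0]))
        assert np.allclose(w, expected, atol=1e-6)

    def test_uniform_input_gives_uniform_spatial_weights(self):
        sam = SpatialAttention(rng=np.random.default_rng(5))
        x = nn.Tensor(np.full((1, 3, 9, 9), 0.7, dtype=np.float32))
        w = sam.weights(x).data[0, 0]
        interior = w[3:-3, 3:-3]  # away from zero-padding border effects
        assert interior.std() < 1e-6

    def test_reduction_larger_than_channels(self):
        cam = ChannelAttention(4, reduction=16)
        assert cam.fc1.out_channels == 1


class TestFullModel:
    def test_forward_is_sigmoid_probability_map(self):
        model = build_model(tiny_config(), seed=0)
        x = np.random.default_rng(0).random((2, 1, 96, 96)).astype(np.float32)
        y = model.predict_probs(x)
        assert y.shape == (2, 1, 96, 96)
        assert np.all((y >= 0) & (y <= 1))

    def test_forward_deterministic_given_weights(self):
        model = build_model(tiny_config(), seed=1)
        x = np.random.default_rng(1).random((1, 1, 96, 96)).astype(np.float32)
        model.eval()
        assert np.array_equal(model.predict_probs(x), model.predict_probs(x))

    @pytest.mark.parametrize("toggle", ["use_ds_aspp", "use_ppm",
                                        "use_attention", "use_multi_skip"])
    def test_ablation_toggles_change_params_not_shape(self, toggle):
        on = build_model(tiny_config(**{toggle: True}), seed=0)
        off = build_model(tiny_config(**{toggle: False}), seed=0)
        assert on.num_parameters() != off.num_parameters()
        x = np.random.default_rng(2).random((1, 1, 96, 96)).astype(np.float32)
        assert on.predict_probs(x).shape == off.predict_probs(x).shape

    def test_attention_toggle_drops_exactly_attention_params(self):
        on = build_model(tiny_config(use_attention=True), seed=0)
        off = build_model(tiny_config(use_attention=False), seed=0)
        att = param_report(model=on).per_component["attention"]
        assert on.num_parameters() - off.num_parameters() == att

    def test_gradient_step_reduces_tversky_loss(self):
        model = build_model(tiny_config(), seed=3)
        rng = np.random.default_rng(3)
        x = rng.random((1, 1, 96, 96)).astype(np.float32)
        g = np.zeros((1, 1, 96, 96), dtype=np.float32)
        g[:, :, 30:60, 25:55] = 1.0
        opt = nn.Adam(model.parameters(), lr=1e-3)
        before = None
        for step in range(3):
            loss = tversky_loss(model(nn.Tensor(x)), g)
            if step == 0:
                before = loss.item()
            opt.zero_grad()
            loss.backward()
            opt.step()
        after = tversky_loss(model(nn.Tensor(x)), g).item()
        assert after < before


class TestParameterOracle:
    def test_random_conv_layers_match_closed_form(self):
        """Constructed array sizes equal the conv_math formulas, 50 specs."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.choice([1, 3, 5, 7]))
            cin = int(rng.integers(1, 64))
            cout = int(rng.integers(1, 64))
            bias = bool(rng.integers(0, 2))
            layer = nn.Conv2d(cin, cout, k, bias=bias, rng=rng)
            actual = sum(p.size for p in layer.parameters())
            assert actual == conv_param_count(model_conv_specs(layer)[0])

    @pytest.mark.parametrize("overrides", [
        {},
        {"use_ds_aspp": False},
        {"use_ppm": False, "use_attention": False, "use_multi_skip": False},
        {"use_attention": False, "width_multiplier": 0.5},
    ])
    def test_model_counts_match_conv_math_sums(self, overrides):
        model = build_model(tiny_config(**overrides), seed=0)
        assert model.num_parameters() == expected_param_count(model)

    def test_component_report_sums_to_total(self):
        model = build_model(tiny_config(), seed=0)
        report = param_report(model=model)
        assert report.total_count == model.num_parameters()
        assert set(report.per_component) == {
            "encoder", "aspp", "ppm", "attention", "decoder", "head"}
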