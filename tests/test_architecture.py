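"""Layer plans, closed-form parameter counting and model construction."""

import numpy as np
import pytest

from resmini.architecture import (LayerKind, LayerSpec, ResMiniConfig,
                                  ShortcutPolicy, build_model,
                                  build_resnet18_baseline, count_parameters,
                                  layer_parameter_count, layer_specs,
                                  resnet18_layer_specs, summarize,
                                  weighted_layer_count)


def closed_form_total(f: int, c0: int, k: int) -> int:
    """Independent polynomial oracle for the projection-all, 4-module plan.

    Derived layer by layer: module convs contribute (19+56+224+896) f^2,
    module batch norms (12+24+48+96) f, the stem 9*c0*f + 4f, the dense
    head 8*f*k + k (batch-norm statistics included).
    """
    return 1195 * f ** 2 + f * (9 * c0 + 184) + 8 * f * k + k


class TestLayerPlan:
    def test_reference_plan_has_ten_weighted_layers(self):
        specs = layer_specs(ResMiniConfig())
        assert weighted_layer_count(specs) == 10

    def test_dense_head_matches_num_classes(self):
        for k in (3, 4):
            specs = layer_specs(ResMiniConfig(num_classes=k))
            dense = [s for s in specs if s.kind is LayerKind.DENSE]
            assert len(dense) == 1 and dense[0].out_channels == k

    def test_width_doubling_rule(self):
        cfg = ResMiniConfig(base_width=1)
        assert cfg.module_widths() == [1, 2, 4, 8]

    def test_stem_conv_printed_geometry(self):
        stem = layer_specs(ResMiniConfig())[0]
        assert (stem.kernel_h, stem.kernel_w, stem.stride, stem.padding) == (3, 3, 1, 3)
        assert not stem.has_bias

    def test_stem_plus_dense_only_plan_has_depth_two(self):
        cfg = ResMiniConfig(num_modules=0, module_strides=())
        assert weighted_layer_count(layer_specs(cfg)) == 2

    def test_projection_on_downsample_drops_module1_shortcut(self):
        cfg = ResMiniConfig(shortcut_policy=ShortcutPolicy.PROJECTION_ON_DOWNSAMPLE)
        shortcuts = [s for s in layer_specs(cfg)
                     if s.on_shortcut and s.kind is LayerKind.CONV2D]
        assert len(shortcuts) == 3  # modules 2-4 only

    @pytest.mark.parametrize("kwargs", [
        {"base_width": 0}, {"num_classes": 1}, {"input_channels": 0},
        {"module_strides": (1, 2, 2, 3)}, {"module_strides": (1, 2)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ResMiniConfig(**kwargs)


class TestParameterCounting:
    def test_plain_conv_count(self):
        spec = LayerSpec(LayerKind.CONV2D, "c", 1, 8, 3, 3)
        assert layer_parameter_count(spec) == 72

    def test_conv_plus_batchnorm_with_statistics(self):
        conv = LayerSpec(LayerKind.CONV2D, "c", 1, 8, 3, 3)
        bn = LayerSpec(LayerKind.BATCHNORM, "b", 8, 8)
        assert (layer_parameter_count(conv) + layer_parameter_count(bn)) == 104
        assert layer_parameter_count(bn, include_bn_statistics=False) == 16

    def test_reference_total_is_98751(self):
        assert summarize(ResMiniConfig()).total_parameters == 98_751

    def test_unknown_layer_kind_rejected(self):
        with pytest.raises(ValueError):
            layer_parameter_count(LayerSpec("wavelet", "w", 1, 1))

    @pytest.mark.parametrize("f", [1, 2, 4, 8, 9, 16])
    @pytest.mark.parametrize("c0", [1, 3])
    @pytest.mark.parametrize("k", [3, 4])
    def test_closed_form_matches_per_layer_sum(self, f, c0, k):
        cfg = ResMiniConfig(base_width=f, input_channels=c0, num_classes=k)
        assert summarize(cfg).total_parameters == closed_form_total(f, c0, k)

    def test_total_strictly_increases_in_width_and_classes(self):
        totals_f = [summarize(ResMiniConfig(base_width=f)).total_parameters
                    for f in (1, 2, 4, 9, 16)]
        assert all(a < b for a, b in zip(totals_f, totals_f[1:]))
        totals_k = [summarize(ResMiniConfig(num_classes=k)).total_parameters
                    for k in (2, 3, 4, 10)]
        assert all(a < b for a, b in zip(totals_k, totals_k[1:]))

    def test_summary_total_is_sum_of_per_layer(self):
        s = summarize(ResMiniConfig())
        assert s.total_parameters == sum(c for _, c in s.per_layer)
        assert all(c >= 0 for _, c in s.per_layer)


class TestResNet18Baseline:
    def test_depth_is_eighteen(self):
        assert weighted_layer_count(resnet18_layer_specs(3)) == 18

    def test_total_in_printed_order_of_magnitude(self):
        total = build_resnet18_baseline(3).total_parameters
        assert 1e7 <= total < 1e8
        assert abs(total - 11_181_379) / 11_181_379 < 0.01

    def test_resmini_is_smaller_than_baseline(self):
        assert (summarize(ResMiniConfig()).total_parameters
                <= build_resnet18_baseline(3).total_parameters)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            resnet18_layer_specs(1)


class TestBuildModel:
    def test_forward_shape_and_simplex(self, small_config, rng):
        model = build_model(small_config, seed=0)
        x = rng.normal(size=(2, 1, 95, 79))
        probs = model.forward(x)
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_four_class_head(self, rng):
        model = build_model(ResMiniConfig(base_width=2, num_classes=4), seed=0)
        assert model.forward(rng.normal(size=(3, 1, 95, 79))).shape == (3, 4)

    @pytest.mark.parametrize("cfg", [
        ResMiniConfig(),
        ResMiniConfig(base_width=2, num_classes=4),
        ResMiniConfig(base_width=4, input_channels=3),
        ResMiniConfig(base_width=2,
                      shortcut_policy=ShortcutPolicy.PROJECTION_ON_DOWNSAMPLE),
    ])
    def test_realized_count_equals_closed_form(self, cfg):
        model = build_model(cfg, seed=1)
        summary = count_parameters(layer_specs(cfg), cfg.count_bn_statistics)
        assert model.parameter_total(True) == summary.total_parameters
        trainable_only = count_parameters(layer_specs(cfg), False)
        assert model.parameter_total(False) == trainable_only.total_parameters

    @pytest.mark.parametrize("hw", [(32, 32), (95, 79), (64, 100)])
    def test_output_shape_independent_of_image_size(self, small_config, rng, hw):
        model = build_model(small_config, seed=0)
        assert model.forward(rng.normal(size=(1, 1, *hw))).shape == (1, 3)

    def test_too_small_input_raises_clear_error(self, small_config, rng):
        model = build_model(small_config, seed=0)
        with pytest.raises(ValueError, match="too small"):
            model.forward(rng.normal(size=(1, 1, 16, 16)))
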