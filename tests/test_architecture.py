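"""Shape inference and parameter counting for the screening network."""

import numpy as np
import pytest

from spheroscreen.architecture import (
    LayerSpec,
    ModelSpec,
    build_model,
    count_parameters,
    default_model_spec,
    infer_shapes,
)

# printed layer table of the screening network at 400x320x1
EXPECTED_ROWS = [
    ("conv2d_1", (398, 318, 32), 320),
    ("activation_1", (398, 318, 32), 0),
    ("max_pooling2d_1", (199, 159, 32), 0),
    ("conv2d_2", (197, 157, 64), 18_496),
    ("activation_2", (197, 157, 64), 0),
    ("max_pooling2d_2", (98, 78, 64), 0),
    ("conv2d_3", (96, 76, 64), 36_928),
    ("activation_3", (96, 76, 64), 0),
    ("max_pooling2d_3", (48, 38, 64), 0),
    ("conv2d_4", (46, 36, 128), 73_856),
    ("activation_4", (46, 36, 128), 0),
    ("max_pooling2d_4", (23, 18, 128), 0),
    ("flatten_1", (52_992,), 0),
    ("dense_1", (128,), 6_783_104),
    ("activation_5", (128,), 0),
    ("dropout_1", (128,), 0),
    ("dense_2", (3,), 387),
    ("activation_6", (3,), 0),
]
EXPECTED_TOTAL = 6_913_091


class TestDefaultArchitecture:
    def test_every_layer_shape_matches_the_printed_table(self):
        shapes = infer_shapes(default_model_spec())
        assert [(n, s) for n, s in shapes] == [(n, s) for n, s, _ in EXPECTED_ROWS]

    def test_every_layer_parameter_count_matches_the_printed_table(self):
        counts, total = count_parameters(default_model_spec())
        assert counts == [(n, p) for n, _, p in EXPECTED_ROWS]
        assert total == EXPECTED_TOTAL

    def test_flatten_width_is_product_of_final_pooled_map(self):
        shapes = dict(infer_shapes(default_model_spec()))
        assert shapes["max_pooling2d_4"] == (23, 18, 128)
        assert shapes["flatten_1"] == (23 * 18 * 128,) == (52_992,)


class TestShapeArithmetic:
    def test_single_valid_conv_on_minimal_input(self):
        spec = ModelSpec(
            layers=(LayerSpec("conv2d", filters=4),), input_shape=(3, 3, 1)
        )
        assert infer_shapes(spec)[-1][1] == (1, 1, 4)

    def test_conv_deeper_than_input_is_rejected(self):
        spec = ModelSpec(
            layers=(LayerSpec("conv2d", filters=4), LayerSpec("conv2d", filters=4)),
            input_shape=(3, 3, 1),
        )
        with pytest.raises(ValueError, match="kernel"):
            infer_shapes(spec)

    def test_dense_parameter_formula(self):
        # 10 inputs x 4 outputs + 4 biases = 44
        spec = ModelSpec(
            layers=(LayerSpec("flatten"), LayerSpec("dense", filters=4)),
            input_shape=(10, 1, 1),
        )
        counts, total = count_parameters(spec)
        assert total == 10 * 4 + 4 == 44

    def test_empty_spec_has_zero_parameters(self):
        assert count_parameters(ModelSpec(layers=(), input_shape=(5, 5, 1)))[1] == 0

    def test_invalid_layer_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown layer kind"):
            LayerSpec("deconv")


def _random_small_spec(rng):
    h = int(rng.integers(12, 30))
    w = int(rng.integers(12, 30))
    layers = []
    c = 1
    for _ in range(int(rng.integers(1, 3))):
        f = int(rng.integers(2, 9))
        layers += [
            LayerSpec("conv2d", filters=f),
            LayerSpec("activation_relu"),
            LayerSpec("maxpool2d"),
        ]
        c = f
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", filters=int(rng.integers(2, 17))))
    layers.append(LayerSpec("dense", filters=3))
    layers.append(LayerSpec("activation_softmax"))
    return ModelSpec(layers=tuple(layers), input_shape=(h, w, 1))


class TestBuildModel:
    def test_framework_parameter_total_equals_declared_count(self):
        spec = default_model_spec()
        counts, total = count_parameters(spec)
        net = build_model(spec, seed=0)
        assert net.n_parameters == total == EXPECTED_TOTAL

    @pytest.mark.parametrize("seed", range(8))
    def test_instantiated_count_matches_oracle_on_random_specs(self, seed):
        """Hand-rolled counting oracle vs the framework-reported total."""
        rng = np.random.default_rng(seed)
        spec = _random_small_spec(rng)

        # independent oracle: walk shapes by the conv/pool arithmetic
        def oracle(spec):
            h, w, c = spec.input_shape
            total = 0
            flat = None
            for lay in spec.layers:
                if lay.kind == "conv2d":
                    total += 3 * 3 * c * lay.filters + lay.filters
                    h, w, c = h - 2, w - 2, lay.filters
                elif lay.kind == "maxpool2d":
                    h, w = h // 2, w // 2
                elif lay.kind == "flatten":
                    flat = h * w * c
                elif lay.kind == "dense":
                    total += flat * lay.filters + lay.filters
                    flat = lay.filters
            return total

        net = build_model(spec, seed=seed)
        assert net.n_parameters == oracle(spec) == count_parameters(spec)[1]

    def test_forward_pass_returns_probability_rows(self):
        spec = default_model_spec(input_shape=(48, 48, 1))
        net = build_model(spec, seed=0)
        x = np.random.default_rng(0).random((4, 48, 48), dtype=np.float32)
        p = net.forward(x)
        assert p.shape == (4, 3)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_all_zero_input_yields_finite_probabilities(self):
        spec = default_model_spec(input_shape=(48, 48, 1))
        net = build_model(spec, seed=1)
        p = net.forward(np.zeros((1, 48, 48), dtype=np.float32))
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(), 1.0, atol=1e-5)
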