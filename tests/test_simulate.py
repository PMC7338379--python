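"""Synthetic spheroid micrograph generator: contracts and phenotype axis."""

import numpy as np
import pytest
from skimage import measure

from spheroscreen.morphometry import compute_features, segment_spheroid
from spheroscreen.simulate import (
    CLASS_NAMES,
    ClassMorphParams,
    SimulationConfig,
    default_class_params,
    render_class,
    render_spheroid,
    validate_class_params,
)


class TestRenderSpheroid:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"fragmentation": 1.0, "debris_density": 0.4, "edge_softness": 5.0},
            {"image_height": 64, "image_width": 64, "texture_noise_sd": 0.1},
            {"vignette_strength": 0.0, "background_level": 0.3},
        ],
    )
    def test_output_contract_shape_and_intensity_range(self, kwargs):
        cfg = SimulationConfig(rng_seed=5, **kwargs)
        img = render_spheroid(cfg)
        assert img.pixels.shape == (cfg.image_height, cfg.image_width)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_noise_free_unfragmented_mass_is_one_component(self):
        cfg = SimulationConfig(
            fragmentation=0.0, texture_noise_sd=0.0, edge_softness=0.0, rng_seed=11
        )
        img = render_spheroid(cfg).pixels
        midpoint = (img.min() + img.max()) / 2
        assert measure.label(img > midpoint, connectivity=2).max() == 1

    def test_identical_config_and_seed_is_bit_identical(self):
        cfg = SimulationConfig(fragmentation=0.6, debris_density=0.2, rng_seed=42)
        a = render_spheroid(cfg).pixels
        b = render_spheroid(cfg).pixels
        np.testing.assert_array_equal(a, b)

    def test_oversized_radius_is_rejected(self):
        with pytest.raises(ValueError, match="base_radius"):
            SimulationConfig(image_height=64, image_width=64, base_radius=40)

    def test_nonpositive_radius_is_rejected(self):
        with pytest.raises(ValueError, match="base_radius"):
            SimulationConfig(base_radius=0)

    def test_fragmentation_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="fragmentation"):
            SimulationConfig(fragmentation=1.2)


class TestRenderClass:
    def test_three_classes_of_400_yield_1200_labelled_images(self):
        # counted at reduced raster size; the count logic is size-independent
        cfg = SimulationConfig(image_height=32, image_width=32)
        total = 0
        for cls in CLASS_NAMES:
            imgs = render_class(cls, n=400, seed=0, base_config=cfg)
            assert all(i.true_class == cls for i in imgs)
            total += len(imgs)
        assert total == 1200

    def test_empty_request_is_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            render_class("unaffected", n=0)

    def test_unknown_class_is_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            render_class("necrotic", n=1)

    def test_same_seed_renders_identical_image_sets(self):
        cfg = SimulationConfig(image_height=64, image_width=64)
        a = render_class("mildly_affected", n=3, seed=9, base_config=cfg)
        b = render_class("mildly_affected", n=3, seed=9, base_config=cfg)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)


class TestClassMorphParams:
    def test_default_ranges_are_ordered_and_disjoint(self):
        params = default_class_params()
        highs = [params[c].fragmentation_range for c in CLASS_NAMES]
        for (lo1, hi1), (lo2, hi2) in zip(highs, highs[1:]):
            assert hi1 < lo2

    def test_overlapping_fragmentation_ranges_rejected(self):
        params = default_class_params().copy()
        params["mildly_affected"] = ClassMorphParams(
            "mildly_affected", (0.05, 0.5), (1.5, 3.0), (0.05, 0.15)
        )
        with pytest.raises(ValueError, match="non-overlapping"):
            validate_class_params(params)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            ClassMorphParams("affected", (0.8, 0.7), (3.0, 5.0), (0.2, 0.4))


def _mean_edge_contrast(fragmentation, n_seeds=20):
    vals = []
    for seed in range(n_seeds):
        cfg = SimulationConfig(fragmentation=fragmentation, rng_seed=seed)
        img = render_spheroid(cfg).pixels
        feats = compute_features(img, segment_spheroid(img))
        vals.append(feats.edge_contrast)
    return float(np.mean(vals))


def test_edge_contrast_decreases_monotonically_with_fragmentation():
    """The phenotype axis: cohesion loss must lower boundary edge contrast."""
    sweep = [_mean_edge_contrast(f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert all(a > b for a, b in zip(sweep, sweep[1:])), sweep


def test_edge_contrast_decreases_with_edge_softness():
    means = []
    for soft in (0.0, 2.0, 4.0):
        vals = []
        for seed in range(20):
            cfg = SimulationConfig(edge_softness=soft, rng_seed=seed)
            img = render_spheroid(cfg).pixels
            vals.append(compute_features(img, segment_spheroid(img)).edge_contrast)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
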