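"""Label-preserving real-time data augmentation for training batches.

The transform set is the classic image-generator family: multiplicative
intensity rescale, random rotation, random shear, random zoom and a random
horizontal flip. Out-of-frame pixels after a geometric transform are filled
with the nearest edge value — constant-fill dark corners would themselves
look like the "affected" phenotype and leak label information.

Geometric transforms are applied about the image centre with bilinear
interpolation; all randomness derives from one seed, one child stream per
image, so a batch augmentation is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationConfig", "augment_batch", "augment_image"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges for the random transforms.

    rotation_range — max |rotation| in degrees; shear_range — max |shear|
    in radians; zoom_range — zoom drawn from [1 - z, 1 + z]; rescale —
    deterministic multiplicative intensity factor (1.0 for images already on
    the [0, 1] scale, 1/255 when feeding raw 8-bit values).
    """

    rotation_range: float = 40.0
    rescale: float = 1.0
    shear_range: float = 0.2
    zoom_range: float = 0.2
    horizontal_flip: bool = True

    def __post_init__(self) -> None:
        if self.rotation_range < 0 or self.shear_range < 0 or self.zoom_range < 0:
            raise ValueError("transform ranges must be non-negative")
        if self.rescale <= 0:
            raise ValueError("rescale must be positive")
        if self.zoom_range >= 1:
            raise ValueError("zoom_range must be < 1")


def _transform_matrix(angle_deg: float, shear: float, zoom: float) -> np.ndarray:
    """Coordinate map (output -> input) for rotation, shear, zoom about 0."""
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    sh = np.array([[1.0, -np.sin(shear)], [0.0, np.cos(shear)]])
    zm = np.array([[zoom, 0.0], [0.0, zoom]])
    forward = rot @ sh @ zm
    return np.linalg.inv(forward)


def augment_image(
    image: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one random draw of the configured transforms to a single image."""
    out = np.asarray(image, dtype=np.float32) * np.float32(config.rescale)
    angle = rng.uniform(-config.rotation_range, config.rotation_range)
    shear = rng.uniform(-config.shear_range, config.shear_range)
    zoom = rng.uniform(1.0 - config.zoom_range, 1.0 + config.zoom_range)
    flip = config.horizontal_flip and rng.random() < 0.5

    if angle != 0.0 or shear != 0.0 or zoom != 1.0:
        matrix = _transform_matrix(angle, shear, zoom)
        center = (np.array(out.shape, dtype=float) - 1.0) / 2.0
        offset = center - matrix @ center
        out = ndimage.affine_transform(
            out, matrix, offset=offset, order=1, mode="nearest"
        ).astype(np.float32)
    if flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment_batch(
    images: np.ndarray,
    config: AugmentationConfig,
    seed: int = 0,
) -> np.ndarray:
    """Augment a batch independently per image; shape and order preserved.

    An empty batch returns an empty batch. Labels are never touched — every
    transform in the set is label-preserving for this phenotype.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.size == 0:
        return images.copy()
    if images.ndim != 3:
        raise ValueError("expected a batch of 2-D images (n, h, w)")
    root = np.random.SeedSequence(seed)
    out = np.empty_like(images)
    for i in range(images.shape[0]):
        rng = np.random.default_rng(root.spawn(1)[0])
        out[i] = augment_image(images[i], config, rng)
    return out
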