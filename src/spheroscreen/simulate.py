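"""Class-conditional synthetic brightfield spheroid micrographs.

Hanging-drop spheroids respond to cytotoxic stress with a characteristic
morphological shift: an untreated spheroid is a single round, cohesive cell
mass with a sharp, high-contrast boundary, while increasing apoptosis
disturbs cell-cell cohesion so the mass fragments, the boundary blurs and
becomes irregular, and cellular debris accumulates around it. The simulator
collapses this phenotype onto one *fragmentation* axis in [0, 1]:

* ``fragmentation = 0`` — one connected blob, sharp edge;
* ``fragmentation -> 1`` — the projected cell area splits into up to
  ``n_fragments_max`` displaced, irregular blobs with strongly blurred
  boundaries, reduced intensity and surrounding debris speckle.

Boundary blur is deliberately coupled to fragmentation (effective Gaussian
sigma = ``edge_softness + EDGE_SOFTNESS_PER_FRAGMENTATION * fragmentation``)
so that boundary edge contrast decreases monotonically along the axis —
cohesion loss and edge-contrast loss are two faces of the same phenotype.

Images are single-channel float rasters in [0, 1], dark background and
bright spheroid, 400x320 px by default; every render is a pure function of
its config (bit-identical for identical seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "SpheroidImage",
    "ClassMorphParams",
    "CLASS_NAMES",
    "default_class_params",
    "render_spheroid",
    "render_class",
    "EDGE_SOFTNESS_PER_FRAGMENTATION",
]

CLASS_NAMES = ("unaffected", "mildly_affected", "affected")

# Extra boundary blur (Gaussian sigma, px) contributed by full fragmentation.
EDGE_SOFTNESS_PER_FRAGMENTATION = 2.5

# Foreground intensity falls from FG_INTENSITY_MAX at fragmentation 0 towards
# FG_INTENSITY_MAX - FG_INTENSITY_DROP at fragmentation 1 (a damaged, loose
# cell mass scatters less light than a dense one).
FG_INTENSITY_MAX = 0.85
FG_INTENSITY_DROP = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, phenotype and noise parameters for one rendered micrograph.

    All intensities are on the normalized [0, 1] scale; lengths are pixels.
    ``base_radius=None`` resolves to 22% of the smaller image dimension.
    """

    image_height: int = 400
    image_width: int = 320
    base_radius: Optional[float] = None
    radius_jitter: float = 0.08
    fragmentation: float = 0.0
    edge_softness: float = 1.0
    debris_density: float = 0.0
    texture_noise_sd: float = 0.02
    background_level: float = 0.08
    vignette_strength: float = 0.15
    n_fragments_max: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image dimensions must be at least 8 px")
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation must lie in [0, 1]")
        if self.edge_softness < 0:
            raise ValueError("edge_softness must be >= 0")
        if self.n_fragments_max < 1:
            raise ValueError("n_fragments_max must be >= 1")
        r = self.resolved_radius
        if r <= 0 or r > min(self.image_height, self.image_width) / 2:
            raise ValueError(
                f"base_radius {r} out of range (0, {min(self.image_height, self.image_width) / 2}]"
            )

    @property
    def resolved_radius(self) -> float:
        if self.base_radius is None:
            return 0.22 * min(self.image_height, self.image_width)
        return float(self.base_radius)


@dataclass
class SpheroidImage:
    """A single-channel micrograph plus its identity and (optional) label."""

    pixels: np.ndarray  # (H, W) float in [0, 1]
    id: str
    true_class: str = "unlabeled"
    provenance: str = "simulated"
    fragmentation: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if self.true_class not in CLASS_NAMES + ("unlabeled",):
            raise ValueError(f"unknown class {self.true_class!r}")


@dataclass(frozen=True)
class ClassMorphParams:
    """Per-class morphology ranges; fragmentation ranges must be ordered and
    non-overlapping across the three classes (unaffected < mildly_affected <
    affected)."""

    class_name: str
    fragmentation_range: tuple[float, float]
    edge_softness_range: tuple[float, float]
    debris_density_range: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (
            self.fragmentation_range,
            self.edge_softness_range,
            self.debris_density_range,
        ):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")
        lo, hi = self.fragmentation_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("fragmentation_range must lie within [0, 1]")


def default_class_params(margin: float = 1.0) -> dict[str, ClassMorphParams]:
    """Default, non-overlapping morphology ranges for the three classes.

    ``margin`` in (0, 1] shrinks the gaps between the class fragmentation
    ranges towards a harder benchmark: at 1.0 the defaults apply, at 0 the
    ranges touch.
    """
    if not 0.0 < margin <= 1.0:
        raise ValueError("margin must lie in (0, 1]")
    # centers stay put; widths grow as margin shrinks
    base = {
        "unaffected": ((0.00, 0.12), (0.5, 1.5), (0.00, 0.02)),
        "mildly_affected": ((0.32, 0.52), (1.5, 3.0), (0.05, 0.15)),
        "affected": ((0.72, 0.95), (3.0, 5.0), (0.20, 0.40)),
    }
    out = {}
    for name, (fr, es, dd) in base.items():
        lo, hi = fr
        c, half = (lo + hi) / 2, (hi - lo) / 2
        grow = half / max(margin, 1e-6)
        fr2 = (max(0.0, c - grow), min(1.0, c + grow))
        out[name] = ClassMorphParams(name, fr2, es, dd)
    validate_class_params(out)
    return out


def validate_class_params(params: dict[str, ClassMorphParams]) -> None:
    """Reject overlapping or mis-ordered per-class fragmentation ranges."""
    missing = set(CLASS_NAMES) - set(params)
    if missing:
        raise ValueError(f"missing class params for: {sorted(missing)}")
    ordered = [params[name].fragmentation_range for name in CLASS_NAMES]
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 >= lo2:
            raise ValueError(
                "class fragmentation ranges must be strictly increasing and "
                f"non-overlapping, got {ordered}"
            )


def _blob_mask(
    yy: np.ndarray,
    xx: np.ndarray,
    cy: float,
    cx: float,
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Irregular disc: polar radius modulated by low-order harmonics."""
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    r_theta = np.full_like(theta, radius)
    if irregularity > 0:
        for m in (2, 3, 5):
            amp = irregularity * rng.uniform(0.2, 1.0) / m
            phase = rng.uniform(0, 2 * np.pi)
            r_theta = r_theta + radius * amp * np.cos(m * theta + phase)
    return dist <= r_theta


def render_spheroid(config: SimulationConfig) -> SpheroidImage:
    """Render one synthetic spheroid micrograph from a config.

    The central cell mass has total projected area ~ pi * base_radius**2
    (modulated by ``radius_jitter``). At fragmentation 0 it is a single
    connected component with a sharp boundary; towards 1 it splits into up to
    ``n_fragments_max`` displaced irregular blobs with blurred edges and
    surrounding debris. Gaussian texture noise and a radial droplet vignette
    are added; output is clamped to [0, 1].
    """
    h, w = config.image_height, config.image_width
    f = config.fragmentation
    rng = np.random.default_rng(config.rng_seed)

    r0 = config.resolved_radius
    r_eff = r0 * (1.0 + rng.uniform(-config.radius_jitter, config.radius_jitter))
    total_area = np.pi * r_eff**2

    n_blobs = 1 + int(round(f * (config.n_fragments_max - 1)))
    # split the projected area among blobs (Dirichlet keeps the total fixed)
    weights = rng.dirichlet(np.full(n_blobs, 5.0)) if n_blobs > 1 else np.ones(1)
    radii = np.sqrt(weights * total_area / np.pi)

    cy0 = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx0 = w / 2 + rng.uniform(-0.03, 0.03) * w

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    mask = np.zeros((h, w), dtype=bool)
    irregularity = 0.05 + 0.5 * f
    for k, rk in enumerate(radii):
        if k == 0:
            cy, cx = cy0, cx0
        else:
            ang = rng.uniform(0, 2 * np.pi)
            dist = f * r_eff * rng.uniform(0.8, 1.8)
            cy = np.clip(cy0 + dist * np.sin(ang), rk, h - rk)
            cx = np.clip(cx0 + dist * np.cos(ang), rk, w - rk)
        mask |= _blob_mask(yy, xx, cy, cx, rk, irregularity, rng)

    fg_intensity = FG_INTENSITY_MAX - FG_INTENSITY_DROP * f
    img = np.full((h, w), config.background_level, dtype=np.float32)
    img[mask] = fg_intensity

    # debris speckle: small dim blobs scattered around the cell mass
    if config.debris_density > 0:
        n_debris = rng.poisson(config.debris_density * h * w / 1000.0)
        for _ in range(n_debris):
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.3, 2.2) * r_eff
            dy = np.clip(cy0 + dist * np.sin(ang), 1, h - 2)
            dx = np.clip(cx0 + dist * np.cos(ang), 1, w - 2)
            dr = rng.uniform(1.0, 4.0)
            dmask = (yy - dy) ** 2 + (xx - dx) ** 2 <= dr**2
            img[dmask] = np.maximum(img[dmask], rng.uniform(0.25, 0.55))

    sigma = config.edge_softness + EDGE_SOFTNESS_PER_FRAGMENTATION * f
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=sigma)

    if config.vignette_strength > 0:
        d2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        img = img * (1.0 - config.vignette_strength * np.sqrt(d2) ** 2)

    if config.texture_noise_sd > 0:
        img = img + rng.normal(0.0, config.texture_noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SpheroidImage(
        pixels=img,
        id=f"sim_{config.rng_seed}",
        true_class="unlabeled",
        provenance="simulated",
        fragmentation=f,
        seed=config.rng_seed,
    )


def render_class(
    class_name: str,
    morph: Optional[ClassMorphParams] = None,
    n: int = 1,
    seed: int = 0,
    base_config: Optional[SimulationConfig] = None,
) -> list[SpheroidImage]:
    """Render ``n`` labelled micrographs for one viability class.

    Per-image fragmentation, edge softness and debris density are drawn
    uniformly from the class's ranges; everything else comes from
    ``base_config``. Reproducible under ``seed``.
    """
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}; expected one of {CLASS_NAMES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if morph is None:
        morph = default_class_params()[class_name]
    if morph.class_name != class_name:
        raise ValueError("morph.class_name does not match class_name")
    cfg = base_config or SimulationConfig()

    root = np.random.SeedSequence(seed)
    images: list[SpheroidImage] = []
    for i in range(n):
        child = root.spawn(1)[0]
        rng = np.random.default_rng(child)
        frag = rng.uniform(*morph.fragmentation_range)
        soft = rng.uniform(*morph.edge_softness_range)
        debris = rng.uniform(*morph.debris_density_range)
        img_seed = int(rng.integers(0, 2**31 - 1))
        img = render_spheroid(
            replace(
                cfg,
                fragmentation=float(frag),
                edge_softness=float(soft),
                debris_density=float(debris),
                rng_seed=img_seed,
            )
        )
        img.id = f"{class_name}_{i:04d}"
        img.true_class = class_name
        images.append(img)
    return images
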