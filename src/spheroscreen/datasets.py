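"""Labelled dataset assembly: micrographs + pooled flow-cytometry labels.

A screening dataset couples each class-conditional image batch to the
flow-cytometry readout that justifies its label: spheroid images are pooled
(one cytometry run per pool of equally treated spheroids), a ground-truth
live fraction is drawn inside the class's viability band, an Annexin-V event
table is simulated and gated, and the gated label is applied to every image
of the pool. The default dataset is 400 images per class across the three
classes — 1,200 images total.

Images round-trip through 8- or 16-bit grayscale PNG plus a CSV manifest
(image_path, id, true_class, fragmentation, seed, pool_id, live_fraction).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import flow as flowmod
from .simulate import (
    CLASS_NAMES,
    ClassMorphParams,
    SimulationConfig,
    SpheroidImage,
    default_class_params,
    render_class,
)

__all__ = ["SpheroidDataset", "simulate_dataset", "save_dataset", "load_dataset", "POOL_SIZE"]

POOL_SIZE = 80  # spheroids pooled per simulated cytometry run
EVENTS_PER_POOL = 20_000


@dataclass
class SpheroidDataset:
    """In-memory dataset: image stack, labels, manifest and flow tables."""

    images: list[SpheroidImage]
    manifest: pd.DataFrame
    flow_tables: list[flowmod.FlowEventTable]
    viability: list[flowmod.ViabilityResult]

    @property
    def X(self) -> np.ndarray:
        return np.stack([img.pixels for img in self.images])

    @property
    def y(self) -> np.ndarray:
        return self.manifest["true_class"].to_numpy()


def simulate_dataset(
    per_class: int = 400,
    seed: int = 0,
    base_config: Optional[SimulationConfig] = None,
    class_params: Optional[dict[str, ClassMorphParams]] = None,
    pool_size: int = POOL_SIZE,
    events_per_pool: int = EVENTS_PER_POOL,
) -> SpheroidDataset:
    """Generate a labelled screening dataset (default 400 images/class).

    For every class the images are grouped into pools of ``pool_size``; each
    pool receives a simulated Annexin-V event table whose gated live fraction
    falls in that class's viability band, and the gated label annotates all
    of the pool's images.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    cfg = base_config or SimulationConfig()
    params = class_params or default_class_params()
    root = np.random.SeedSequence(seed)

    images: list[SpheroidImage] = []
    rows: list[dict] = []
    tables: list[flowmod.FlowEventTable] = []
    results: list[flowmod.ViabilityResult] = []

    for ci, cls in enumerate(CLASS_NAMES):
        cls_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        cls_images = render_class(cls, params[cls], n=per_class, seed=cls_seed, base_config=cfg)
        lo, hi = flowmod.CLASS_VIABILITY_RANGES[cls]
        pool_rng = np.random.default_rng(root.spawn(1)[0])
        n_pools = int(np.ceil(per_class / pool_size))
        for p in range(n_pools):
            pool_id = f"{cls}_pool{p:02d}"
            true_lf = float(pool_rng.uniform(lo, hi))
            table = flowmod.simulate_events(
                true_lf,
                events_per_pool,
                seed=int(pool_rng.integers(0, 2**31 - 1)),
                pool_id=pool_id,
            )
            res = flowmod.gate_viability(table)
            tables.append(table)
            results.append(res)
            for img in cls_images[p * pool_size : (p + 1) * pool_size]:
                rows.append(
                    {
                        "image_path": "",
                        "id": img.id,
                        "true_class": res.label,
                        "fragmentation": img.fragmentation,
                        "seed": img.seed,
                        "pool_id": pool_id,
                        "live_fraction": res.live_fraction,
                    }
                )
                img.true_class = res.label
        images.extend(cls_images)

    manifest = pd.DataFrame(rows)
    return SpheroidDataset(images=images, manifest=manifest, flow_tables=tables, viability=results)


def save_dataset(dataset: SpheroidDataset, out_dir: str, bit_depth: int = 8) -> str:
    """Write PNG images, manifest.csv, flow_events.csv and viability.csv.

    Returns the manifest path. ``bit_depth`` is 8 or 16.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    manifest = dataset.manifest.copy()
    scale = (2**bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    for i, img in enumerate(dataset.images):
        arr = np.round(img.pixels * scale).astype(dtype)
        rel = os.path.join("images", f"{img.id}.png")
        Image.fromarray(arr).save(os.path.join(out_dir, rel))
        manifest.loc[manifest["id"] == img.id, "image_path"] = rel
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    if dataset.flow_tables:
        pd.concat([t.to_frame() for t in dataset.flow_tables]).to_csv(
            os.path.join(out_dir, "flow_events.csv"), index=False
        )
        flowmod.viability_results_to_frame(dataset.viability).to_csv(
            os.path.join(out_dir, "viability.csv"), index=False
        )
    return manifest_path


def load_dataset(manifest_path: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load (X, y, manifest) from a manifest CSV with PNG image paths.

    Pixel values are rescaled to [0, 1] from the file's bit depth.
    """
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    stack = []
    for rel in manifest["image_path"]:
        arr = np.asarray(Image.open(os.path.join(base, rel)))
        denom = 255.0 if arr.dtype == np.uint8 else 65535.0
        stack.append(arr.astype(np.float32) / denom)
    X = np.stack(stack) if stack else np.zeros((0, 0, 0), dtype=np.float32)
    y = manifest["true_class"].to_numpy()
    return X, y, manifest
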