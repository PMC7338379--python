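"""Declarative CNN architecture: layer specs, shape inference, parameter counting.

The screening classifier is a small AlexNet-inspired stack: four 3x3
valid-padding convolutions (32/64/64/128 filters), each followed by ReLU and
2x2 max-pooling, then flatten, a 128-unit dense layer with ReLU and dropout,
and a 3-way dense + softmax head. On the default 400x320 single-channel input
this network has exactly 6,913,091 trainable parameters.

Shape arithmetic is the standard one for this layer family:

* valid convolution: ``out = in - kernel + 1`` (stride 1, no padding)
* 2x2 max-pool: ``out = floor(in / 2)`` (pool stride equals pool size)

`infer_shapes` and `count_parameters` are pure functions of the spec so the
architecture can be audited without instantiating any weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "default_model_spec",
    "infer_shapes",
    "count_parameters",
    "build_model",
    "DEFAULT_INPUT_SHAPE",
    "N_CLASSES",
]

DEFAULT_INPUT_SHAPE = (400, 320, 1)
N_CLASSES = 3


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network.

    kind is one of: ``conv2d``, ``activation_relu``, ``maxpool2d``,
    ``flatten``, ``dense``, ``dropout``, ``activation_softmax``.
    ``filters`` is the number of convolution filters or dense output units.
    """

    kind: str
    filters: Optional[int] = None
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.5
    name: str = ""

    _KINDS = frozenset(
        {
            "conv2d",
            "activation_relu",
            "maxpool2d",
            "flatten",
            "dense",
            "dropout",
            "activation_softmax",
        }
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown layer kind: {self.kind!r}")
        if self.kind in ("conv2d", "dense"):
            if self.filters is None or self.filters < 1:
                raise ValueError(f"{self.kind} layer needs a positive 'filters'")
        if self.kind == "dropout" and not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer list plus input geometry.

    The default instance (see `default_model_spec`) is the screening
    network: [conv32, relu, pool], [conv64, relu, pool] x2, [conv128, relu,
    pool], flatten, dense128, relu, dropout, dense3, softmax.
    """

    layers: tuple[LayerSpec, ...] = ()
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        h, w, c = self.input_shape
        if h < 1 or w < 1 or c < 1:
            raise ValueError(f"input_shape must be positive, got {self.input_shape}")


def default_model_spec(
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE,
    n_classes: int = N_CLASSES,
    dropout_rate: float = 0.5,
) -> ModelSpec:
    """The screening classifier architecture at a configurable input size."""
    layers: list[LayerSpec] = []
    for i, nf in enumerate((32, 64, 64, 128), start=1):
        layers.append(LayerSpec("conv2d", filters=nf, name=f"conv2d_{i}"))
        layers.append(LayerSpec("activation_relu", name=f"activation_{i}"))
        layers.append(LayerSpec("maxpool2d", name=f"max_pooling2d_{i}"))
    layers.append(LayerSpec("flatten", name="flatten_1"))
    layers.append(LayerSpec("dense", filters=128, name="dense_1"))
    layers.append(LayerSpec("activation_relu", name="activation_5"))
    layers.append(LayerSpec("dropout", dropout_rate=dropout_rate, name="dropout_1"))
    layers.append(LayerSpec("dense", filters=n_classes, name="dense_2"))
    layers.append(LayerSpec("activation_softmax", name="activation_6"))
    return ModelSpec(layers=tuple(layers), input_shape=input_shape, n_classes=n_classes)


def _layer_name(layer: LayerSpec, index: int) -> str:
    return layer.name or f"{layer.kind}_{index}"


def infer_shapes(spec: ModelSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes (excluding the batch dimension).

    Raises ValueError if a convolution kernel no longer fits the incoming
    spatial extent (the network is too deep for the input), or if a dense
    layer is reached before flattening.
    """
    shape: tuple[int, ...] = tuple(spec.input_shape)
    out: list[tuple[str, tuple[int, ...]]] = []
    for i, layer in enumerate(spec.layers, start=1):
        if layer.kind == "conv2d":
            if len(shape) != 3:
                raise ValueError("conv2d requires a (h, w, c) input")
            h, w, _ = shape
            kh, kw = layer.kernel
            if h < kh or w < kw:
                raise ValueError(
                    f"layer {_layer_name(layer, i)}: kernel {layer.kernel} "
                    f"exceeds input extent {(h, w)}"
                )
            shape = (h - kh + 1, w - kw + 1, layer.filters)
        elif layer.kind == "maxpool2d":
            if len(shape) != 3:
                raise ValueError("maxpool2d requires a (h, w, c) input")
            h, w, c = shape
            ph, pw = layer.pool
            if h < ph or w < pw:
                raise ValueError(
                    f"layer {_layer_name(layer, i)}: pool {layer.pool} "
                    f"exceeds input extent {(h, w)}"
                )
            shape = (h // ph, w // pw, c)
        elif layer.kind == "flatten":
            n = 1
            for d in shape:
                n *= d
            shape = (n,)
        elif layer.kind == "dense":
            if len(shape) != 1:
                raise ValueError("dense requires a flattened input")
            shape = (layer.filters,)
        # relu / softmax / dropout leave the shape untouched
        out.append((_layer_name(layer, i), shape))
    return out


def count_parameters(spec: ModelSpec) -> tuple[list[tuple[str, int]], int]:
    """Per-layer trainable-parameter counts and their total.

    conv2d: ``kh * kw * c_in * c_out + c_out`` (weights + biases);
    dense: ``n_in * n_out + n_out``; every other kind contributes 0.
    """
    shape: tuple[int, ...] = tuple(spec.input_shape)
    counts: list[tuple[str, int]] = []
    shapes = infer_shapes(spec)
    for i, (layer, (name, out_shape)) in enumerate(zip(spec.layers, shapes), start=1):
        if layer.kind == "conv2d":
            kh, kw = layer.kernel
            c_in = shape[-1]
            n = kh * kw * c_in * layer.filters + layer.filters
        elif layer.kind == "dense":
            n = shape[0] * layer.filters + layer.filters
        else:
            n = 0
        counts.append((name, n))
        shape = out_shape
    total = sum(n for _, n in counts)
    return counts, total


def summary_table(spec: ModelSpec) -> list[dict]:
    """Rows of (layer, output_shape, params) suitable for CSV/JSON export."""
    shapes = infer_shapes(spec)
    counts, _ = count_parameters(spec)
    return [
        {"layer": name, "output_shape": shape, "params": n}
        for (name, shape), (_, n) in zip(shapes, counts)
    ]


def build_model(
    spec: ModelSpec,
    dropout_rate: Optional[float] = None,
    seed: int = 0,
    learning_rate: float = 1e-3,
):
    """Instantiate a trainable network from the spec.

    Returns a `spheroscreen.nn.Network` whose reported trainable-parameter
    total equals ``count_parameters(spec)[1]`` and whose forward pass maps a
    batch of rasters to per-sample class probabilities.
    """
    from . import nn

    return nn.network_from_spec(
        spec, dropout_rate=dropout_rate, seed=seed, learning_rate=learning_rate
    )
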