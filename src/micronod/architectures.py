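"""Framework-independent layer specifications for the three CNN models.

M1, M2 and M3 differ in depth (1, 2 and 4 convolutional layers) and are
deliberately small-filter designs: the objects being classified are
micro-nodules under 3 mm across, so fine kernels (down to 2x2 in M2's
second layer) capture the relevant detail.  Each model ends in a 2-unit
dense layer with a softmax over the micro-nodule / non-nodule classes.

Published facts fixed here: M2's convolutions carry 64 kernels of 7x7 and
128 kernels of 2x2; M1's convolution uses a 3x3 kernel.  Filter counts for
M1 (32) and M3 (32/64/128/256 at 3x3), dense width (256), dropout rate
(0.5) and 2x2/stride-2 pooling are this package's defaults, surfaced as
keyword arguments.  M1 and M2 use valid (no) padding; M3's convolutions use
'same' padding so the three stacked poolings remain feasible at all three
input sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ShapeError",
    "build_m1",
    "build_m2",
    "build_m3",
    "build_architecture",
    "propagate_shapes",
    "count_parameters",
    "MODEL_NAMES",
    "PATCH_SIZES",
]

MODEL_NAMES = ("M1", "M2", "M3")
PATCH_SIZES = (16, 32, 64)

_KINDS = {"conv", "relu", "maxpool", "dense", "dropout", "softmax"}


class ShapeError(ValueError):
    """A layer stack collapses to a non-positive spatial dimension."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    kernel: tuple[int, int] | None = None
    filters: int | None = None
    units: int | None = None
    rate: float | None = None
    stride: tuple[int, int] = (1, 1)
    padding: str = "valid"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "maxpool") and self.kernel is None:
            raise ValueError(f"{self.kind} layer requires a kernel")
        if self.kind == "conv" and not self.filters:
            raise ValueError("conv layer requires a filter count")
        if self.kind == "dense" and not self.units:
            raise ValueError("dense layer requires a unit count")
        if self.kind == "dropout" and not (self.rate and 0.0 < self.rate < 1.0):
            raise ValueError("dropout rate must lie in (0, 1)")
        if self.padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {self.padding!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer description of one model at one input size."""

    name: str
    input_size: int
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if self.layers[-1].kind != "softmax":
            raise ValueError("architecture must end in a softmax layer")
        final_dense = [l for l in self.layers if l.kind == "dense"][-1]
        if final_dense.units != 2:
            raise ValueError("final dense layer must have 2 units (two classes)")

    @property
    def n_conv(self) -> int:
        return sum(1 for l in self.layers if l.kind == "conv")

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "input_size": self.input_size,
            "layers": [
                {k: v for k, v in vars(l).items() if v is not None}
                for l in self.layers
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        doc = json.loads(text)
        layers = []
        for entry in doc["layers"]:
            entry = dict(entry)
            for key in ("kernel", "stride"):
                if key in entry:
                    entry[key] = tuple(entry[key])
            layers.append(LayerSpec(**entry))
        return cls(name=doc["name"], input_size=doc["input_size"], layers=tuple(layers))


def _check_input_size(input_size: int) -> None:
    if input_size not in PATCH_SIZES:
        raise ValueError(
            f"input_size must be one of {PATCH_SIZES}, got {input_size!r}"
        )


def _head() -> tuple[LayerSpec, LayerSpec]:
    """The final 2-unit fully connected layer and its softmax."""
    return (LayerSpec("dense", units=2), LayerSpec("softmax"))


def build_m1(
    input_size: int,
    conv_kernel: tuple[int, int] = (3, 3),
    conv_filters: int = 32,
    dense_units: int = 256,
    dropout_rate: float = 0.5,
) -> ArchitectureSpec:
    """One convolutional layer followed by one max-pooling layer.

    Layer order: conv(3x3) -> maxpool -> dense -> dropout -> dense(2) ->
    softmax.  The 3x3 kernel is the published optimum for this model.
    """
    _check_input_size(input_size)
    layers = (
        LayerSpec("conv", kernel=tuple(conv_kernel), filters=conv_filters),
        LayerSpec("maxpool", kernel=(2, 2), stride=(2, 2)),
        LayerSpec("dense", units=dense_units),
        LayerSpec("dropout", rate=dropout_rate),
        *_head(),
    )
    spec = ArchitectureSpec("M1", input_size, layers)
    propagate_shapes(spec)
    return spec


def build_m2(
    input_size: int,
    dense_units: int = 256,
    dropout_rate: float = 0.5,
) -> ArchitectureSpec:
    """Two convolutional layers: 64 kernels of 7x7, then 128 of 2x2.

    Layer order: conv(64@7x7) -> relu -> maxpool -> conv(128@2x2) ->
    dropout -> dense -> dense(2) -> softmax.  The ReLU after the first
    convolution speeds SGD convergence; the 2x2 second-layer kernels
    capture fine detail of the sub-3 mm lesions.
    """
    _check_input_size(input_size)
    layers = (
        LayerSpec("conv", kernel=(7, 7), filters=64),
        LayerSpec("relu"),
        LayerSpec("maxpool", kernel=(2, 2), stride=(2, 2)),
        LayerSpec("conv", kernel=(2, 2), filters=128),
        LayerSpec("dropout", rate=dropout_rate),
        LayerSpec("dense", units=dense_units),
        *_head(),
    )
    spec = ArchitectureSpec("M2", input_size, layers)
    propagate_shapes(spec)
    return spec


def build_m3(
    input_size: int,
    conv_filters: tuple[int, int, int, int] = (32, 64, 128, 256),
    conv_kernel: tuple[int, int] = (3, 3),
    dense_units: int = 256,
    dropout_rate: float = 0.5,
) -> ArchitectureSpec:
    """Four convolutional layers; the first three each feed a max-pool.

    Layer order: [conv -> maxpool] x3 -> conv -> dropout -> dense ->
    dense(2) -> softmax.  Convolutions are 'same'-padded: under valid
    padding the three stacked 2x2 poolings would drive 16x16 (and 32x32)
    inputs to a non-positive size before the fourth convolution.
    """
    _check_input_size(input_size)
    layers: list[LayerSpec] = []
    for filters in conv_filters[:3]:
        layers.append(
            LayerSpec("conv", kernel=tuple(conv_kernel), filters=filters, padding="same")
        )
        layers.append(LayerSpec("maxpool", kernel=(2, 2), stride=(2, 2)))
    layers.append(
        LayerSpec("conv", kernel=tuple(conv_kernel), filters=conv_filters[3], padding="same")
    )
    layers.append(LayerSpec("dropout", rate=dropout_rate))
    layers.append(LayerSpec("dense", units=dense_units))
    layers.extend(_head())
    spec = ArchitectureSpec("M3", input_size, tuple(layers))
    propagate_shapes(spec)
    return spec


_BUILDERS = {"M1": build_m1, "M2": build_m2, "M3": build_m3}


def build_architecture(name: str, input_size: int, **kwargs) -> ArchitectureSpec:
    """Dispatch to build_m1/build_m2/build_m3 by model name."""
    try:
        builder = _BUILDERS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    return builder(input_size, **kwargs)


def _conv_out(n: int, k: int, s: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(n / s)
    return (n - k) // s + 1


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple[int, ...]]:
    """Per-layer output shapes, (H, W, C) spatially and (units,) once dense.

    Valid-padded conv/pool output follows floor((n - k)/s) + 1; 'same'
    padding gives ceil(n/s).  The first dense layer flattens its input.
    Raises ShapeError naming the offending layer if any spatial dimension
    becomes non-positive.
    """
    shape: tuple[int, ...] = (spec.input_size, spec.input_size, 1)
    out: list[tuple[int, ...]] = []
    for i, layer in enumerate(spec.layers):
        if layer.kind in ("conv", "maxpool"):
            if len(shape) != 3:
                raise ShapeError(f"layer {i} ({layer.kind}) after flattening")
            h = _conv_out(shape[0], layer.kernel[0], layer.stride[0], layer.padding)
            w = _conv_out(shape[1], layer.kernel[1], layer.stride[1], layer.padding)
            if h <= 0 or w <= 0:
                raise ShapeError(
                    f"layer {i} ({layer.kind} {layer.kernel}) collapses "
                    f"{shape[0]}x{shape[1]} to {h}x{w} in {spec.name}"
                )
            c = layer.filters if layer.kind == "conv" else shape[2]
            shape = (h, w, c)
        elif layer.kind == "dense":
            n_in = int(math.prod(shape))
            shape = (layer.units,)
        else:  # relu, dropout, softmax preserve shape
            pass
        out.append(shape)
    return out


def count_parameters(spec: ArchitectureSpec) -> tuple[int, list[int]]:
    """Total and per-layer trainable parameter counts.

    Convolutions hold kh*kw*in_ch*out_ch weights + out_ch biases; dense
    layers hold in*out weights + out biases; other layers are parameter
    free.
    """
    shapes = propagate_shapes(spec)
    per_layer: list[int] = []
    in_shape: tuple[int, ...] = (spec.input_size, spec.input_size, 1)
    for layer, out_shape in zip(spec.layers, shapes):
        if layer.kind == "conv":
            kh, kw = layer.kernel
            per_layer.append(kh * kw * in_shape[2] * layer.filters + layer.filters)
        elif layer.kind == "dense":
            n_in = int(math.prod(in_shape))
            per_layer.append(n_in * layer.units + layer.units)
        else:
            per_layer.append(0)
        in_shape = out_shape
    return sum(per_layer), per_layer
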