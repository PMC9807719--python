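"""Declarative specification and exact auditing of sequential CNNs.

A :class:`ModelSpec` is an ordered list of layer specifications plus an input
shape.  From it we derive, without touching any tensor backend, the full
shape chain, the trainable-parameter count of every layer, and the
multiply-accumulate (MAC) cost of every convolution.  The canonical network
built by :func:`fast_tumor_cnn_spec` is a 13-layer model for three-class
brain-tumor MRI classification that interleaves 1x1 "bottleneck"
convolutions with 3x3 convolutions to cut MAC cost.

Conventions
-----------
* All convolutions and pools use valid padding (P=0) unless a padding is
  given: spatial output = floor((in - kernel + 2P) / stride) + 1.
* Parameter counts include biases for conv and dense layers.
* MAC cost counts multiplications only: f_h * f_w * c_in * h_out * w_out *
  n_filters for a convolution, len_in * n_units for a dense layer, zero for
  pooling and flatten.  Bias additions are not counted.
* Network "depth" counts conv + pool + dense layers; flatten is a reshape
  and is not counted.  Under this convention the canonical model has
  depth 13.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from typing import IO, Union

__all__ = [
    "LayerSpec",
    "TensorShape",
    "ModelSpec",
    "LayerAudit",
    "CostReport",
    "InvalidSpecError",
    "conv2d",
    "avgpool2d",
    "flatten",
    "dense",
    "fast_tumor_cnn_spec",
    "infer_output_shape",
    "count_parameters",
    "layer_cost",
    "audit",
]

LAYER_KINDS = ("conv2d", "avgpool2d", "flatten", "dense")
ACTIVATIONS = ("relu", "sigmoid", "tanh", "softmax", "linear")


class InvalidSpecError(ValueError):
    """A layer specification or shape chain is inconsistent."""


# TensorShape is a (height, width, channels) triple through the convolutional
# trunk and a plain int after flatten.
TensorShape = Union[tuple[int, int, int], int]


def _check_shape(shape: TensorShape) -> None:
    if isinstance(shape, int):
        if shape < 1:
            raise InvalidSpecError(f"rank-1 shape must be >= 1, got {shape}")
        return
    if len(shape) != 3 or any(int(d) < 1 for d in shape):
        raise InvalidSpecError(f"rank-3 shape must have positive dims, got {shape}")


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a sequential CNN.

    Exactly the fields relevant to ``kind`` are set; the factory helpers
    :func:`conv2d`, :func:`avgpool2d`, :func:`flatten` and :func:`dense`
    enforce this.
    """

    kind: str
    kernel_h: int | None = None
    kernel_w: int | None = None
    n_filters: int | None = None
    stride: int | None = None
    padding: int = 0
    n_units: int | None = None
    activation: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise InvalidSpecError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise InvalidSpecError(f"unknown activation {self.activation!r}")
        if self.padding < 0:
            raise InvalidSpecError("padding must be >= 0")
        spatial = self.kind in ("conv2d", "avgpool2d")
        if spatial:
            if not (self.kernel_h and self.kernel_w) or self.kernel_h < 1 or self.kernel_w < 1:
                raise InvalidSpecError(f"{self.kind} needs kernel_h, kernel_w >= 1")
            if self.stride is None or self.stride < 1:
                raise InvalidSpecError(f"{self.kind} needs stride >= 1")
        if self.kind == "conv2d" and (self.n_filters is None or self.n_filters < 1):
            raise InvalidSpecError("conv2d needs n_filters >= 1")
        if self.kind == "dense" and (self.n_units is None or self.n_units < 1):
            raise InvalidSpecError("dense needs n_units >= 1")
        if self.kind == "flatten":
            numeric = (self.kernel_h, self.kernel_w, self.n_filters, self.stride, self.n_units)
            if any(v is not None for v in numeric) or self.padding != 0:
                raise InvalidSpecError("flatten takes no numeric fields")
        if self.kind in ("avgpool2d", "flatten") and self.activation != "linear":
            raise InvalidSpecError(f"{self.kind} takes no activation")
        if self.kind in ("avgpool2d", "flatten") and self.n_filters is not None:
            raise InvalidSpecError(f"{self.kind} takes no n_filters")


def conv2d(kernel: int | tuple[int, int], n_filters: int, *, stride: int = 1,
           padding: int = 0, activation: str = "relu") -> LayerSpec:
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    return LayerSpec("conv2d", kernel_h=kh, kernel_w=kw, n_filters=n_filters,
                     stride=stride, padding=padding, activation=activation)


def avgpool2d(kernel: int | tuple[int, int], *, stride: int | None = None,
              padding: int = 0) -> LayerSpec:
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    # pool stride defaults to the pool size (non-overlapping windows)
    return LayerSpec("avgpool2d", kernel_h=kh, kernel_w=kw,
                     stride=kh if stride is None else stride, padding=padding)


def flatten() -> LayerSpec:
    return LayerSpec("flatten")


def dense(n_units: int, activation: str = "linear") -> LayerSpec:
    return LayerSpec("dense", n_units=n_units, activation=activation)


@dataclass(frozen=True)
class ModelSpec:
    """Input shape plus an ordered stack of layers."""

    input_shape: TensorShape
    layers: tuple[LayerSpec, ...]
    name: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        _check_shape(self.input_shape)
        n_flat = sum(1 for l in self.layers if l.kind == "flatten")
        if n_flat > 1:
            raise InvalidSpecError("at most one flatten layer")
        seen_flat = isinstance(self.input_shape, int)
        for i, layer in enumerate(self.layers):
            if layer.kind == "dense" and not seen_flat:
                raise InvalidSpecError(f"layer {i}: dense before flatten")
            if layer.kind in ("conv2d", "avgpool2d", "flatten") and seen_flat:
                raise InvalidSpecError(f"layer {i}: {layer.kind} after flatten")
            if layer.kind == "flatten":
                seen_flat = True
        # walking the chain raises InvalidSpecError on any non-positive dim
        self.output_shapes()

    def output_shapes(self) -> list[TensorShape]:
        shapes: list[TensorShape] = []
        cur = self.input_shape
        for i, layer in enumerate(self.layers):
            try:
                cur = infer_output_shape(layer, cur)
            except InvalidSpecError as e:
                raise InvalidSpecError(f"layer {i} ({layer.kind}): {e}") from None
            shapes.append(cur)
        return shapes

    # ---- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        def layer_doc(l: LayerSpec) -> dict:
            return {k: v for k, v in asdict(l).items() if v is not None}

        doc = {
            "name": self.name,
            "input_shape": list(self.input_shape) if not isinstance(self.input_shape, int)
            else self.input_shape,
            "layers": [layer_doc(l) for l in self.layers],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        doc = json.loads(text)
        ishape = doc["input_shape"]
        if isinstance(ishape, list):
            ishape = tuple(int(d) for d in ishape)
        layers = tuple(LayerSpec(**d) for d in doc["layers"])
        return cls(input_shape=ishape, layers=layers, name=doc.get("name", "model"))


def _spatial_out(n: int, f: int, p: int, s: int) -> int:
    out = (n - f + 2 * p) // s + 1
    if out < 1:
        raise InvalidSpecError(
            f"non-positive spatial output ({out}) for input {n}, kernel {f}, "
            f"padding {p}, stride {s}")
    return out


def infer_output_shape(layer: LayerSpec, in_shape: TensorShape) -> TensorShape:
    """Output shape of ``layer`` applied to ``in_shape``.

    Conv and pool follow floor((n - f + 2P)/s) + 1 on each spatial axis;
    conv sets channels to n_filters, pool keeps them; flatten collapses to
    h*w*c; dense maps any rank-1 length to n_units.
    """
    _check_shape(in_shape)
    if layer.kind == "dense":
        if not isinstance(in_shape, int):
            raise InvalidSpecError("dense expects a rank-1 input (after flatten)")
        return layer.n_units
    if isinstance(in_shape, int):
        raise InvalidSpecError(f"{layer.kind} expects a rank-3 input")
    h, w, c = in_shape
    if layer.kind == "flatten":
        return h * w * c
    ho = _spatial_out(h, layer.kernel_h, layer.padding, layer.stride)
    wo = _spatial_out(w, layer.kernel_w, layer.padding, layer.stride)
    return (ho, wo, layer.n_filters if layer.kind == "conv2d" else c)


def count_parameters(layer: LayerSpec, in_shape: TensorShape) -> int:
    """Trainable parameters of one layer, biases included."""
    if layer.kind == "conv2d":
        _, _, c = in_shape
        return (layer.kernel_h * layer.kernel_w * c + 1) * layer.n_filters
    if layer.kind == "dense":
        if not isinstance(in_shape, int):
            raise InvalidSpecError("dense expects a rank-1 input")
        return (in_shape + 1) * layer.n_units
    return 0


def layer_cost(layer: LayerSpec, in_shape: TensorShape) -> int:
    """Multiply-accumulate cost of one layer (multiplications only).

    Convolution: f_h * f_w * c_in * h_out * w_out * n_filters.  Dense:
    len_in * n_units.  Pooling and flatten are costed at zero; these are
    accounting conventions, biases and additions are never counted.
    """
    if layer.kind == "conv2d":
        out = infer_output_shape(layer, in_shape)
        ho, wo, nf = out
        _, _, c_in = in_shape
        return layer.kernel_h * layer.kernel_w * c_in * ho * wo * nf
    if layer.kind == "dense":
        return int(in_shape) * layer.n_units
    return 0


@dataclass(frozen=True)
class LayerAudit:
    layer_index: int
    kind: str
    n_filters_or_units: int | None
    kernel: str
    output_shape: TensorShape
    n_params: int
    mac_cost: int


@dataclass(frozen=True)
class CostReport:
    """Per-layer audit plus totals.

    ``depth`` counts conv + pool + dense layers (flatten excluded); the
    canonical model audits to depth 13 and 583,613 parameters.
    """

    per_layer: tuple[LayerAudit, ...]
    total_params: int
    total_mac: int
    depth: int

    def to_csv(self, stream: IO[str]) -> None:
        writer = csv.writer(stream)
        writer.writerow(["layer_index", "layer_type", "n_filters_or_units",
                         "kernel", "output_size", "n_params", "mac_cost"])
        for a in self.per_layer:
            writer.writerow([a.layer_index, a.kind,
                             "" if a.n_filters_or_units is None else a.n_filters_or_units,
                             a.kernel, _fmt_shape(a.output_shape),
                             a.n_params, a.mac_cost])
        writer.writerow(["total", "", "", "", "", self.total_params, self.total_mac])


def _fmt_shape(shape: TensorShape) -> str:
    if isinstance(shape, int):
        return str(shape)
    return "(" + ", ".join(str(d) for d in shape) + ")"


def audit(spec: ModelSpec) -> CostReport:
    """Shape, parameter and MAC audit of every layer of ``spec``."""
    audits = []
    cur = spec.input_shape
    for i, layer in enumerate(spec.layers):
        out = infer_output_shape(layer, cur)
        if layer.kind in ("conv2d", "avgpool2d"):
            kernel = f"{layer.kernel_h}x{layer.kernel_w}"
        else:
            kernel = ""
        audits.append(LayerAudit(
            layer_index=i,
            kind=layer.kind,
            n_filters_or_units=layer.n_filters if layer.kind == "conv2d" else layer.n_units,
            kernel=kernel,
            output_shape=out,
            n_params=count_parameters(layer, cur),
            mac_cost=layer_cost(layer, cur),
        ))
        cur = out
    depth = sum(1 for l in spec.layers if l.kind != "flatten")
    return CostReport(
        per_layer=tuple(audits),
        total_params=sum(a.n_params for a in audits),
        total_mac=sum(a.mac_cost for a in audits),
        depth=depth,
    )


def fast_tumor_cnn_spec(include_bottlenecks: bool = True, *,
                        image_size: int = 256, n_classes: int = 3,
                        bottleneck_filters: int = 10) -> ModelSpec:
    """The canonical 13-layer bottleneck CNN for three-class tumor MRI.

    With ``include_bottlenecks`` the stack is: conv 3x3x32, conv 1x1x10,
    avgpool 2x2, then twice [conv 1x1x10, conv 3x3x32, conv 1x1x10,
    avgpool 2x2], flatten, dense 64 (ReLU), dense 3 (softmax).  At the
    production input size of 256x256x1 this audits to 583,613 trainable
    parameters.  ``include_bottlenecks=False`` builds the ablation variant
    with every 1x1 convolution removed.

    ``image_size`` scales the input; ``bottleneck_filters`` varies the 1x1
    channel width (the production model uses 10).
    """
    k = bottleneck_filters
    layers: list[LayerSpec] = [conv2d(3, 32), conv2d(1, k), avgpool2d(2)]
    for _ in range(2):
        layers += [conv2d(1, k), conv2d(3, 32), conv2d(1, k), avgpool2d(2)]
    layers += [flatten(), dense(64, "relu"), dense(n_classes, "softmax")]
    if not include_bottlenecks:
        layers = [l for l in layers if not (l.kind == "conv2d" and l.kernel_h == 1)]
    name = "fast_tumor_cnn" if include_bottlenecks else "fast_tumor_cnn_no_bottleneck"
    return ModelSpec(input_shape=(image_size, image_size, 1),
                     layers=tuple(layers), name=name)
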