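"""Symbolic ResMini architecture: layer plans, parameter counting, depth.

ResMini is a lightweight residual CNN for classifying 2D brain-MRI slices
into age (or dementia-stage) classes.  The network is described here as an
ordered list of :class:`LayerSpec` records; the same plan drives both the
closed-form parameter count (no weights needed) and the construction of a
trainable model (:func:`build_model`).

Structure of the reference plan (base width ``f``, ``K`` classes):

* stem ``Conv_BN_ReLU``: 3x3 conv, stride 1, padding 3, ``f`` filters;
* 3x3 max pooling, stride 2, padding 1;
* four residual modules with output widths ``f, 2f, 4f, 8f`` (the width
  doubles module to module).  Each module has two main-path 3x3
  ``Conv_BN_ReLU`` blocks (the first at the module stride) and a 1x1
  projection shortcut ``Conv_BN`` feeding an elementwise add + ReLU;
* global average pooling, a dense layer ``8f -> K`` with bias, softmax.

Counting only weighted layers (convolutions on the main path plus the dense
layer) the depth is 1 + 4*2 + 1 = 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence


class LayerKind(str, Enum):
    CONV2D = "conv2d"
    BATCHNORM = "batchnorm"
    MAXPOOL = "maxpool"
    AVGPOOL_GLOBAL = "avgpool_global"
    DENSE = "dense"
    ACTIVATION = "activation"
    SOFTMAX = "softmax"
    ADD = "add"


class ShortcutPolicy(str, Enum):
    #: every residual module uses a 1x1 projection shortcut (ResMini default)
    PROJECTION_ALL = "projection_all"
    #: projection only where shape changes; identity otherwise (ResNet-18 style)
    PROJECTION_ON_DOWNSAMPLE = "projection_on_downsample"


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network plan; parameter count is a pure function of it."""

    kind: LayerKind
    name: str
    in_channels: int = 0
    out_channels: int = 0
    kernel_h: int = 0
    kernel_w: int = 0
    stride: int = 1
    padding: int = 0
    has_bias: bool = False
    #: True for convolutions on a projection-shortcut path; these carry
    #: weights but are excluded from the weighted-layer depth convention.
    on_shortcut: bool = False


@dataclass(frozen=True)
class ResMiniConfig:
    """Hyperparameters that determine the ResMini plan.

    ``base_width`` is the stem filter count ``f``; module ``i`` (1-based)
    outputs ``f * 2**(i-1)`` channels.  ``count_bn_statistics`` controls
    whether batch-norm running mean/variance are included in parameter
    totals, mirroring the "Total params" convention of framework summaries.
    """

    input_channels: int = 1
    input_height: int = 95
    input_width: int = 79
    base_width: int = 9
    num_modules: int = 4
    num_classes: int = 3
    shortcut_policy: ShortcutPolicy = ShortcutPolicy.PROJECTION_ALL
    module_strides: Sequence[int] = (1, 2, 2, 2)
    count_bn_statistics: bool = True

    def __post_init__(self) -> None:
        if self.base_width < 1:
            raise ValueError(f"base_width must be >= 1, got {self.base_width}")
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")
        if len(self.module_strides) != self.num_modules:
            raise ValueError(
                f"module_strides must have {self.num_modules} entries, "
                f"got {len(self.module_strides)}"
            )
        if any(s not in (1, 2) for s in self.module_strides):
            raise ValueError("module strides must be 1 or 2")

    def module_widths(self) -> list[int]:
        """Output channel counts of the residual modules (width-doubling)."""
        return [self.base_width * 2 ** i for i in range(self.num_modules)]


@dataclass(frozen=True)
class ModelSummary:
    per_layer: tuple[tuple[str, int], ...]
    total_parameters: int
    weighted_layer_count: int

    def as_dict(self) -> dict:
        return {
            "per_layer": [{"layer": n, "parameters": c} for n, c in self.per_layer],
            "total_parameters": self.total_parameters,
            "weighted_layer_count": self.weighted_layer_count,
        }

    def as_text(self) -> str:
        width = max(len(n) for n, _ in self.per_layer + (("layer", 0),))
        lines = [f"{'layer':<{width}}  parameters"]
        for name, count in self.per_layer:
            lines.append(f"{name:<{width}}  {count:>12,}")
        lines.append(f"{'total':<{width}}  {self.total_parameters:>12,}")
        lines.append(f"weighted layers: {self.weighted_layer_count}")
        return "\n".join(lines)


def _conv_bn(name: str, cin: int, cout: int, k: int, stride: int, padding: int,
             relu: bool = True, on_shortcut: bool = False) -> list[LayerSpec]:
    specs = [
        LayerSpec(LayerKind.CONV2D, f"{name}.conv", cin, cout, k, k, stride,
                  padding, has_bias=False, on_shortcut=on_shortcut),
        LayerSpec(LayerKind.BATCHNORM, f"{name}.bn", cout, cout,
                  on_shortcut=on_shortcut),
    ]
    if relu:
        specs.append(LayerSpec(LayerKind.ACTIVATION, f"{name}.relu", cout, cout))
    return specs


def layer_specs(config: ResMiniConfig) -> list[LayerSpec]:
    """Ordered layer plan of the ResMini network for ``config``."""
    f = config.base_width
    specs: list[LayerSpec] = []
    specs += _conv_bn("stem", config.input_channels, f, k=3, stride=1, padding=3)
    specs.append(LayerSpec(LayerKind.MAXPOOL, "stem.maxpool", f, f, 3, 3,
                           stride=2, padding=1))
    cin = f
    for i, (cout, stride) in enumerate(
            zip(config.module_widths(), config.module_strides), start=1):
        mod = f"module{i}"
        specs += _conv_bn(f"{mod}.block1", cin, cout, k=3, stride=stride, padding=1)
        specs += _conv_bn(f"{mod}.block2", cout, cout, k=3, stride=1, padding=1,
                          relu=False)
        needs_projection = (
            config.shortcut_policy is ShortcutPolicy.PROJECTION_ALL
            or stride != 1 or cin != cout
        )
        if needs_projection:
            specs += _conv_bn(f"{mod}.shortcut", cin, cout, k=1, stride=stride,
                              padding=0, relu=False, on_shortcut=True)
        specs.append(LayerSpec(LayerKind.ADD, f"{mod}.add", cout, cout))
        specs.append(LayerSpec(LayerKind.ACTIVATION, f"{mod}.relu", cout, cout))
        cin = cout
    specs.append(LayerSpec(LayerKind.AVGPOOL_GLOBAL, "avgpool", cin, cin))
    specs.append(LayerSpec(LayerKind.DENSE, "dense", cin, config.num_classes,
                           has_bias=True))
    specs.append(LayerSpec(LayerKind.SOFTMAX, "softmax",
                           config.num_classes, config.num_classes))
    return specs


def layer_parameter_count(spec: LayerSpec, include_bn_statistics: bool = True) -> int:
    """Parameters of one layer.

    Convolution: ``kh*kw*cin*cout`` (+ ``cout`` if biased).  Batch norm:
    scale+shift (2 per channel) plus, when ``include_bn_statistics``, the
    running mean/variance (2 more per channel).  Dense: ``in*out + out``.
    Pooling, activations, softmax and adds carry no parameters.
    """
    k = spec.kind
    if k is LayerKind.CONV2D:
        n = spec.kernel_h * spec.kernel_w * spec.in_channels * spec.out_channels
        return n + (spec.out_channels if spec.has_bias else 0)
    if k is LayerKind.BATCHNORM:
        return (4 if include_bn_statistics else 2) * spec.out_channels
    if k is LayerKind.DENSE:
        return spec.in_channels * spec.out_channels + (
            spec.out_channels if spec.has_bias else 0)
    if k in (LayerKind.MAXPOOL, LayerKind.AVGPOOL_GLOBAL, LayerKind.ACTIVATION,
             LayerKind.SOFTMAX, LayerKind.ADD):
        return 0
    raise ValueError(f"unknown layer kind: {spec.kind!r}")


def weighted_layer_count(specs: Iterable[LayerSpec]) -> int:
    """Network depth in the "N-layer" convention.

    Counts layers with learned multiplicative weights on the main path:
    convolutions (excluding projection shortcuts) and dense layers.  Batch
    norm, pooling, activations, softmax and adds do not count.
    """
    n = 0
    for s in specs:
        if s.kind is LayerKind.CONV2D and not s.on_shortcut:
            n += 1
        elif s.kind is LayerKind.DENSE:
            n += 1
    return n


def count_parameters(specs: Sequence[LayerSpec],
                     include_bn_statistics: bool = True) -> ModelSummary:
    """Closed-form per-layer and total parameter counts for a plan."""
    per_layer = tuple(
        (s.name, layer_parameter_count(s, include_bn_statistics))
        for s in specs
    )
    return ModelSummary(
        per_layer=per_layer,
        total_parameters=sum(c for _, c in per_layer),
        weighted_layer_count=weighted_layer_count(specs),
    )


def summarize(config: ResMiniConfig) -> ModelSummary:
    """Convenience: plan + count for one config."""
    return count_parameters(layer_specs(config), config.count_bn_statistics)


def build_model(config: ResMiniConfig, seed: int = 0):
    """Construct the trainable ResMini network realizing :func:`layer_specs`.

    The realized parameter count (trainable arrays plus batch-norm running
    statistics) equals ``count_parameters(layer_specs(config))`` — asserted
    in the test suite for every tested config.  Weight initialization is
    He-normal, seeded by ``seed``.
    """
    import numpy as np

    from . import engine

    rng = np.random.default_rng(seed)
    f = config.base_width
    layers: list[engine.Layer] = [
        engine.Conv2D(config.input_channels, f, 3, 1, 3, rng),
        engine.BatchNorm2D(f),
        engine.ReLU(),
        engine.MaxPool2D(3, 2, 1),
    ]
    cin = f
    for cout, stride in zip(config.module_widths(), config.module_strides):
        projection = (
            config.shortcut_policy is ShortcutPolicy.PROJECTION_ALL
            or stride != 1 or cin != cout
        )
        layers.append(engine.ResidualBlock(cin, cout, stride, projection, rng))
        cin = cout
    layers.append(engine.GlobalAvgPool())
    layers.append(engine.Dense(cin, config.num_classes, rng))
    return engine.Network(layers, config.num_classes)


# ---------------------------------------------------------------------------
# ResNet-18 baseline plan (parameter-economy comparison only)
# ---------------------------------------------------------------------------

#: Printed reference totals used in comparison reports.  BHCnet is defined in
#: its own publication and is not reimplemented here; only its published
#: parameter count enters the comparison.
BHCNET_TOTAL_PARAMETERS = 196_595
RESNET18_PRINTED_TOTAL_PARAMETERS = 11_181_379
RESMINI_PRINTED_TOTAL_PARAMETERS = 98_907


def resnet18_layer_specs(num_classes: int = 3, input_channels: int = 3) -> list[LayerSpec]:
    """Canonical 18-weighted-layer residual network plan.

    7x7/64 stem, four stages of two basic blocks at widths 64/128/256/512,
    identity shortcuts except a 1x1 projection where the shape changes, and
    a dense head resized to ``num_classes``.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    specs: list[LayerSpec] = []
    specs += _conv_bn("stem", input_channels, 64, k=7, stride=2, padding=3)
    specs.append(LayerSpec(LayerKind.MAXPOOL, "stem.maxpool", 64, 64, 3, 3, 2, 1))
    cin = 64
    for stage, (width, stride) in enumerate(
            zip((64, 128, 256, 512), (1, 2, 2, 2)), start=1):
        for block in (1, 2):
            blk = f"stage{stage}.block{block}"
            s = stride if block == 1 else 1
            specs += _conv_bn(f"{blk}.conv1", cin, width, 3, s, 1)
            specs += _conv_bn(f"{blk}.conv2", width, width, 3, 1, 1, relu=False)
            if s != 1 or cin != width:
                specs += _conv_bn(f"{blk}.shortcut", cin, width, 1, s, 0,
                                  relu=False, on_shortcut=True)
            specs.append(LayerSpec(LayerKind.ADD, f"{blk}.add", width, width))
            specs.append(LayerSpec(LayerKind.ACTIVATION, f"{blk}.relu", width, width))
            cin = width
    specs.append(LayerSpec(LayerKind.AVGPOOL_GLOBAL, "avgpool", cin, cin))
    specs.append(LayerSpec(LayerKind.DENSE, "dense", cin, num_classes, has_bias=True))
    specs.append(LayerSpec(LayerKind.SOFTMAX, "softmax", num_classes, num_classes))
    return specs


def build_resnet18_baseline(num_classes: int = 3,
                            include_bn_statistics: bool = True) -> ModelSummary:
    """Summary of the canonical ResNet-18 plan, for parameter-economy reports."""
    return count_parameters(resnet18_layer_specs(num_classes), include_bn_statistics)
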