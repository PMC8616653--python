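"""Segmentation networks: encoders, GCN/BR blocks, and U-Net assemblies.

Two decoder styles are built from the same encoder families:

* ``GCNUNet`` — the improved U-Net: every encoder stage output is mapped
  to a ``num_classes``-channel score map by a large-kernel Global
  Convolutional Network (GCN) block (optionally followed by a Boundary
  Refinement residual block), and decoding proceeds by repeated x2
  upsampling plus elementwise addition of the next-shallower score map,
  with BR after each fusion.
* ``ClassicUNet`` — the concatenation-skip U-Net used as the ablation
  baseline (``use_gcn=False``); with the ``plain_unet`` encoder it is the
  textbook double-conv U-Net.

Every block records a :class:`LayerSpec` built from its constructor
arguments alone, so parameter counts can be computed analytically and
cross-checked against the instantiated weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._nn import (
    BatchNorm2d,
    BilinearUp2x,
    Conv2d,
    ConvTranspose2x,
    DepthwiseConv2d,
    MaxPool2x2,
    Module,
    ReLU,
    Sequential,
    count_params,
)
from ._nn import autodiff as F
from ._nn.autodiff import Tensor

__all__ = [
    "ModelConfig",
    "LayerSpec",
    "spec_of",
    "gcn_param_count",
    "full_conv_param_count",
    "InceptionBlock",
    "ResidualBlock",
    "SEBlock",
    "GCNBlock",
    "BRBlock",
    "build_encoder",
    "build_improved_unet",
    "predict",
]

ENCODERS = ("googlenet", "vgg", "seresnet", "plain_unet")


@dataclass
class ModelConfig:
    """Everything needed to build a network deterministically."""

    encoder: str = "googlenet"
    use_gcn: bool = True
    gcn_kernel_size: int = 7
    gcn_variant: str = "dense"
    use_br: bool = True
    num_classes: int = 2
    base_channels: int = 32
    input_size: Tuple[int, int] = (256, 256)
    in_channels: int = 3
    upsample: str = "deconv"  # or "bilinear"
    fusion: str = "add"  # or "concat"

    def __post_init__(self):
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder '{self.encoder}'; choose from {ENCODERS}")
        if self.gcn_kernel_size % 2 == 0 or self.gcn_kernel_size < 3:
            raise ValueError("gcn_kernel_size must be an odd integer >= 3")
        if self.gcn_variant not in ("dense", "separable"):
            raise ValueError("gcn_variant must be 'dense' or 'separable'")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.base_channels % 8 != 0 or self.base_channels <= 0:
            raise ValueError("base_channels must be a positive multiple of 8")
        if self.upsample not in ("deconv", "bilinear"):
            raise ValueError("upsample must be 'deconv' or 'bilinear'")
        if self.fusion not in ("add", "concat"):
            raise ValueError("fusion must be 'add' or 'concat'")


# ---------------------------------------------------------------------------
# Analytic parameter bookkeeping


@dataclass
class LayerSpec:
    """Structural description sufficient to count parameters analytically.

    ``convs`` entries are (kh, kw, c_in, c_out, bias); ``bn_channels`` and
    ``linear`` entries contribute 2c and (c_in*c_out + bias*c_out).
    """

    kind: str = "block"
    convs: List[Tuple[int, int, int, int, bool]] = field(default_factory=list)
    bn_channels: List[int] = field(default_factory=list)
    linears: List[Tuple[int, int, bool]] = field(default_factory=list)

    @property
    def param_count(self) -> int:
        total = 0
        for kh, kw, cin, cout, bias in self.convs:
            total += kh * kw * cin * cout + (cout if bias else 0)
        total += sum(2 * c for c in self.bn_channels)
        for cin, cout, bias in self.linears:
            total += cin * cout + (cout if bias else 0)
        return total

    def __add__(self, other: "LayerSpec") -> "LayerSpec":
        return LayerSpec(
            kind=self.kind,
            convs=self.convs + other.convs,
            bn_channels=self.bn_channels + other.bn_channels,
            linears=self.linears + other.linears,
        )


def spec_of(module: Module) -> LayerSpec:
    """Aggregate the analytic LayerSpec of a module tree.

    Blocks that define a formula-level ``spec`` report it directly; other
    modules are summed from their children's structural records (`struct`
    tuples stored at construction from the constructor arguments).
    """
    own = getattr(module, "spec", None)
    if own is not None:
        return own
    total = LayerSpec()
    struct = getattr(module, "struct", None)
    if struct is not None:
        if struct[0] == "conv":
            total.convs.append(tuple(struct[1:]))
        elif struct[0] == "bn":
            total.bn_channels.append(struct[1])
        elif struct[0] == "linear":
            total.linears.append(tuple(struct[1:]))
    for _, child in module._children():
        total = total + spec_of(child)
    return total


def full_conv_param_count(k: int, c_in: int, c_out: int, bias: bool = False) -> int:
    """Weights of a plain k x k convolution (the GCN's dense reference)."""
    return k * k * c_in * c_out + (c_out if bias else 0)


def gcn_param_count(k: int, c_in: int, c_out: int, variant: str = "dense") -> int:
    """Weights of a (bias-free) GCN block from its structural formula.

    dense: two branches of (k x 1, c_in->c_out) then (1 x k, c_out->c_out)
    (and the transpose order), i.e. 2(k c_in c_out + k c_out^2).
    separable: each constituent conv factorizes into a depthwise (k taps per
    channel) plus pointwise (c_in x c_out) convolution.
    """
    if variant == "dense":
        return 2 * (k * c_in * c_out + k * c_out * c_out)
    if variant == "separable":
        per_first = k * c_in + c_in * c_out  # depthwise on c_in, then pointwise
        per_second = k * c_out + c_out * c_out
        return 2 * (per_first + per_second)
    raise ValueError(f"unknown GCN variant '{variant}'")


# ---------------------------------------------------------------------------
# Blocks


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=0):
        super().__init__()
        if isinstance(k, int):
            k = (k, k)
        self.spec = LayerSpec("conv_bn_relu", convs=[(k[0], k[1], cin, cout, True)],
                              bn_channels=[cout])
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, padding=padding)
        self.bn = BatchNorm2d(cout)
        self.act = ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class InceptionBlock(Module):
    """Inception module with dimensionality reduction.

    Four parallel branches — 1x1; 1x1 reduce then 3x3; 1x1 reduce then
    5x5; 3x3 max-pool then 1x1 — concatenated along channels. Branch
    output widths are given by ``branch_channels = (b1, b3, b5, bp)``;
    reduce widths are half the branch output (at least 1).
    """

    def __init__(self, cin, branch_channels, rng):
        super().__init__()
        b1, b3, b5, bp = branch_channels
        r3 = max(b3 // 2, 1)
        r5 = max(b5 // 2, 1)
        self.out_channels = b1 + b3 + b5 + bp
        self.branch1 = ConvBNReLU(cin, b1, 1, rng)
        self.branch3 = Sequential(ConvBNReLU(cin, r3, 1, rng), ConvBNReLU(r3, b3, 3, rng, padding=1))
        self.branch5 = Sequential(ConvBNReLU(cin, r5, 1, rng), ConvBNReLU(r5, b5, 5, rng, padding=2))
        self.branch_pool = Sequential(_PadPool3(), ConvBNReLU(cin, bp, 1, rng))

    def forward(self, x):
        return F.concat(
            [self.branch1(x), self.branch3(x), self.branch5(x), self.branch_pool(x)], axis=1
        )


class _PadPool3(Module):
    """3x3 max pooling with stride 1 (spatial size preserved)."""

    def forward(self, x):
        a = x.data
        n, c, h, w = a.shape
        ap = np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
        windows = np.empty((n, c, h, w, 9), dtype=a.dtype)
        idx = 0
        for i in range(3):
            for j in range(3):
                windows[..., idx] = ap[:, :, i : i + h, j : j + w]
                idx += 1
        amax = windows.argmax(axis=-1)
        out_data = np.take_along_axis(windows, amax[..., None], axis=-1)[..., 0]

        def backward(g):
            if not x.requires_grad:
                return
            dxp = np.zeros((n, c, h + 2, w + 2), dtype=a.dtype)
            for k in range(9):
                i, j = divmod(k, 3)
                sel = amax == k
                dxp[:, :, i : i + h, j : j + w] += np.where(sel, g, 0.0)
            x._accumulate(dxp[:, :, 1 : 1 + h, 1 : 1 + w])

        return Tensor(out_data, parents=(x,), backward=backward)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate: global pool -> 2-layer MLP -> sigmoid."""

    def __init__(self, channels, rng, reduction=8):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.spec = LayerSpec(
            "se", linears=[(channels, hidden, True), (hidden, channels, True)]
        )
        from ._nn import Linear

        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x):
        s = F.global_avg_pool(x)
        s = F.relu(self.fc1(s))
        s = F.sigmoid(self.fc2(s))
        n, c = s.data.shape
        return F.mul(x, F.reshape(s, (n, c, 1, 1)))


class ResidualBlock(Module):
    """Pre-activation-free residual block: out = relu(f(x) + shortcut(x)).

    ``f`` is conv3x3-BN-relu-conv3x3-BN; the shortcut is the identity when
    channel counts match, else a 1x1 projection with BN. With ``use_se``
    the SE gate recalibrates ``f(x)`` before the addition.
    """

    def __init__(self, cin, cout, rng, use_se=False):
        super().__init__()
        self.conv1 = ConvBNReLU(cin, cout, 3, rng, padding=1)
        self.conv2 = Conv2d(cout, cout, 3, rng, padding=1)
        self.bn2 = BatchNorm2d(cout)
        self.se = SEBlock(cout, rng) if use_se else None
        if cin != cout:
            self.shortcut = Conv2d(cin, cout, 1, rng)
            self.shortcut_bn = BatchNorm2d(cout)
        else:
            self.shortcut = None

    def forward(self, x):
        f = self.bn2(self.conv2(self.conv1(x)))
        if self.se is not None:
            f = self.se(f)
        sc = x if self.shortcut is None else self.shortcut_bn(self.shortcut(x))
        return F.relu(F.add(f, sc))


class GCNBlock(Module):
    """Large-kernel Global Convolutional Network block.

    Approximates a dense k x k convolution by the sum of two separable
    branches — (k x 1 then 1 x k) and (1 x k then k x 1) — densely
    connecting a k x k receptive field to per-pixel classifiers at cost
    linear (not quadratic) in k. The ``separable`` variant further
    factorizes each constituent convolution into depthwise + pointwise.
    The block is purely linear: no bias, normalization, or nonlinearity.
    """

    def __init__(self, cin, cout, k, rng, variant="dense"):
        super().__init__()
        if k % 2 == 0:
            raise ValueError(f"GCN kernel size must be odd, got {k}")
        if variant not in ("dense", "separable"):
            raise ValueError(f"unknown GCN variant '{variant}'")
        self.k = k
        self.variant = variant
        p = (k - 1) // 2
        if variant == "dense":
            self.spec = LayerSpec(
                "gcn_dense",
                convs=[
                    (k, 1, cin, cout, False),
                    (1, k, cout, cout, False),
                    (1, k, cin, cout, False),
                    (k, 1, cout, cout, False),
                ],
            )
            self.a1 = Conv2d(cin, cout, (k, 1), rng, padding=(p, 0), bias=False)
            self.a2 = Conv2d(cout, cout, (1, k), rng, padding=(0, p), bias=False)
            self.b1 = Conv2d(cin, cout, (1, k), rng, padding=(0, p), bias=False)
            self.b2 = Conv2d(cout, cout, (k, 1), rng, padding=(p, 0), bias=False)
        else:
            self.spec = LayerSpec(
                "gcn_separable",
                convs=[
                    (k, 1, cin, 1, False), (1, 1, cin, cout, False),
                    (1, k, cout, 1, False), (1, 1, cout, cout, False),
                    (1, k, cin, 1, False), (1, 1, cin, cout, False),
                    (k, 1, cout, 1, False), (1, 1, cout, cout, False),
                ],
            )
            self.a1 = _SeparableConv(cin, cout, (k, 1), rng, padding=(p, 0))
            self.a2 = _SeparableConv(cout, cout, (1, k), rng, padding=(0, p))
            self.b1 = _SeparableConv(cin, cout, (1, k), rng, padding=(0, p))
            self.b2 = _SeparableConv(cout, cout, (k, 1), rng, padding=(p, 0))

    def forward(self, x):
        return F.add(self.a2(self.a1(x)), self.b2(self.b1(x)))


class _SeparableConv(Module):
    """Depthwise spatial convolution followed by a pointwise 1x1, bias-free."""

    def __init__(self, cin, cout, k, rng, padding):
        super().__init__()
        self.depthwise = DepthwiseConv2d(cin, k, rng, padding=padding, bias=False)
        self.pointwise = Conv2d(cin, cout, 1, rng, bias=False)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class BRBlock(Module):
    """Boundary Refinement: x + conv3x3(relu(conv3x3(x))), channels preserved.

    The second convolution is zero-initialized, so the block is the exact
    identity at initialization and learns a residual boundary correction.
    """

    def __init__(self, channels, rng):
        super().__init__()
        self.spec = LayerSpec(
            "br", convs=[(3, 3, channels, channels, True), (3, 3, channels, channels, True)]
        )
        self.conv1 = Conv2d(channels, channels, 3, rng, padding=1)
        self.conv2 = Conv2d(channels, channels, 3, rng, padding=1, zero_init=True)

    def forward(self, x):
        return F.add(x, self.conv2(F.relu(self.conv1(x))))


class DoubleConv(Module):
    """The classic U-Net stage block: two 3x3 conv-BN-relu layers."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = ConvBNReLU(cin, cout, 3, rng, padding=1)
        self.conv2 = ConvBNReLU(cout, cout, 3, rng, padding=1)

    def forward(self, x):
        return self.conv2(self.conv1(x))


# ---------------------------------------------------------------------------
# Encoders


class Encoder(Module):
    """Base encoder: a stem plus four stages; forward returns all features.

    ``stage_channels`` / ``stage_strides`` describe the four stage outputs;
    ``stem_channels`` / ``stem_stride`` the stem output used by
    concatenation decoders.
    """

    stage_channels: Tuple[int, int, int, int]
    stage_strides: Tuple[int, int, int, int]
    stem_channels: int
    stem_stride: int

    def forward(self, x):
        s = self.stem(x)
        feats = []
        f = s
        for stage in self.stages:
            f = stage(f)
            feats.append(f)
        return s, feats


class GoogLeNetEncoder(Encoder):
    def __init__(self, base, rng, in_channels=3):
        super().__init__()
        b = base
        self.stem = Sequential(
            ConvBNReLU(in_channels, b, 3, rng, stride=2, padding=1),
            ConvBNReLU(b, b, 3, rng, stride=2, padding=1),
        )
        def inception(cin, cout):
            return InceptionBlock(cin, (cout // 4, cout // 2, cout // 8, cout // 8), rng)

        self.stages = [
            inception(b, 2 * b),
            Sequential(MaxPool2x2(), inception(2 * b, 4 * b)),
            Sequential(MaxPool2x2(), inception(4 * b, 8 * b)),
            Sequential(MaxPool2x2(), inception(8 * b, 16 * b)),
        ]
        self.stem_channels, self.stem_stride = b, 4
        self.stage_channels = (2 * b, 4 * b, 8 * b, 16 * b)
        self.stage_strides = (4, 8, 16, 32)


class VGGEncoder(Encoder):
    def __init__(self, base, rng, in_channels=3):
        super().__init__()
        b = base
        self.stem = Sequential(
            ConvBNReLU(in_channels, b, 3, rng, padding=1), MaxPool2x2(),
            ConvBNReLU(b, b, 3, rng, padding=1), MaxPool2x2(),
        )
        def pair(cin, cout):
            return Sequential(
                ConvBNReLU(cin, cout, 3, rng, padding=1),
                ConvBNReLU(cout, cout, 3, rng, padding=1),
            )

        self.stages = [
            pair(b, 2 * b),
            Sequential(MaxPool2x2(), pair(2 * b, 4 * b)),
            Sequential(MaxPool2x2(), pair(4 * b, 8 * b)),
            Sequential(MaxPool2x2(), pair(8 * b, 16 * b)),
        ]
        self.stem_channels, self.stem_stride = b, 4
        self.stage_channels = (2 * b, 4 * b, 8 * b, 16 * b)
        self.stage_strides = (4, 8, 16, 32)


class SEResNetEncoder(Encoder):
    def __init__(self, base, rng, in_channels=3):
        super().__init__()
        b = base
        self.stem = Sequential(
            ConvBNReLU(in_channels, b, 3, rng, stride=2, padding=1),
            ConvBNReLU(b, b, 3, rng, stride=2, padding=1),
        )
        self.stages = [
            ResidualBlock(b, 2 * b, rng, use_se=True),
            Sequential(MaxPool2x2(), ResidualBlock(2 * b, 4 * b, rng, use_se=True)),
            Sequential(MaxPool2x2(), ResidualBlock(4 * b, 8 * b, rng, use_se=True)),
            Sequential(MaxPool2x2(), ResidualBlock(8 * b, 16 * b, rng, use_se=True)),
        ]
        self.stem_channels, self.stem_stride = b, 4
        self.stage_channels = (2 * b, 4 * b, 8 * b, 16 * b)
        self.stage_strides = (4, 8, 16, 32)


class PlainUNetEncoder(Encoder):
    """Classic U-Net contracting path: double-conv blocks with 2x2 pooling."""

    def __init__(self, base, rng, in_channels=3):
        super().__init__()
        b = base
        self.stem = DoubleConv(in_channels, b, rng)
        self.stages = [
            Sequential(MaxPool2x2(), DoubleConv(b, 2 * b, rng)),
            Sequential(MaxPool2x2(), DoubleConv(2 * b, 4 * b, rng)),
            Sequential(MaxPool2x2(), DoubleConv(4 * b, 8 * b, rng)),
            Sequential(MaxPool2x2(), DoubleConv(8 * b, 16 * b, rng)),
        ]
        self.stem_channels, self.stem_stride = b, 1
        self.stage_channels = (2 * b, 4 * b, 8 * b, 16 * b)
        self.stage_strides = (2, 4, 8, 16)


_ENCODER_CLASSES = {
    "googlenet": GoogLeNetEncoder,
    "vgg": VGGEncoder,
    "seresnet": SEResNetEncoder,
    "plain_unet": PlainUNetEncoder,
}


def build_encoder(name: str, base_channels: int, rng=None, in_channels: int = 3) -> Encoder:
    """Construct one of the four encoder families, seeded via `rng`."""
    if name not in _ENCODER_CLASSES:
        raise ValueError(f"unknown encoder '{name}'; choose from {ENCODERS}")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(0 if rng is None else rng)
    return _ENCODER_CLASSES[name](base_channels, rng, in_channels=in_channels)


# ---------------------------------------------------------------------------
# Assemblies


class _Up2(Module):
    def __init__(self, cin, cout, rng, mode="deconv"):
        super().__init__()
        if mode == "deconv":
            self.up = ConvTranspose2x(cin, cout, rng)
        else:
            if cin != cout:
                raise ValueError("bilinear upsampling requires cin == cout")
            self.up = BilinearUp2x()

    def forward(self, x):
        return self.up(x)


class GCNUNet(Module):
    """The improved U-Net: GCN score maps on skips, additive decoding, BR."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.config = config
        c = config.num_classes
        self.encoder = build_encoder(
            config.encoder, config.base_channels, rng, in_channels=config.in_channels
        )
        k, variant = config.gcn_kernel_size, config.gcn_variant
        self.gcns = [
            GCNBlock(ch, c, k, rng, variant=variant) for ch in self.encoder.stage_channels
        ]
        self.use_br = config.use_br
        if config.use_br:
            self.skip_brs = [BRBlock(c, rng) for _ in range(4)]
        self.ups = [_Up2(c, c, rng, config.upsample) for _ in range(3)]
        self.fusion = config.fusion
        if config.fusion == "concat":
            self.fuse_convs = [Conv2d(2 * c, c, 1, rng) for _ in range(3)]
        n_final = int(np.log2(self.encoder.stage_strides[0]))
        self.final_ups = [_Up2(c, c, rng, config.upsample) for _ in range(n_final)]
        if config.use_br:
            self.fuse_brs = [BRBlock(c, rng) for _ in range(3)]
            self.final_brs = [BRBlock(c, rng) for _ in range(n_final)]

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        deepest = self.encoder.stage_strides[-1]
        if x.data.shape[2] % deepest or x.data.shape[3] % deepest:
            raise ValueError(
                f"input spatial size {x.data.shape[2:]} must be divisible by {deepest}"
            )
        _, feats = self.encoder(x)
        maps = []
        for i, f in enumerate(feats):
            m = self.gcns[i](f)
            if self.use_br:
                m = self.skip_brs[i](m)
            maps.append(m)
        d = maps[-1]
        for i in reversed(range(3)):
            d = self.ups[i](d)
            if self.fusion == "add":
                d = F.add(d, maps[i])
            else:
                d = self.fuse_convs[i](F.concat([d, maps[i]], axis=1))
            if self.use_br:
                d = self.fuse_brs[i](d)
        for j, up in enumerate(self.final_ups):
            d = up(d)
            if self.use_br:
                d = self.final_brs[j](d)
        return d


class ClassicUNet(Module):
    """Concatenation-skip U-Net over any of the encoder families."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.config = config
        self.encoder = build_encoder(
            config.encoder, config.base_channels, rng, in_channels=config.in_channels
        )
        chans = self.encoder.stage_channels
        mode = config.upsample
        self.ups = []
        self.blocks = []
        # decode across stages: deepest -> shallowest (channel changes force deconv)
        for i in reversed(range(3)):
            self.ups.append(_Up2(chans[i + 1], chans[i], rng, "deconv"))
            self.blocks.append(DoubleConv(2 * chans[i], chans[i], rng))
        # decode from stage-1 stride down to full resolution
        stem_ch = self.encoder.stem_channels
        self.final_ups = []
        self.final_blocks = []
        cur = chans[0]
        stride = self.encoder.stage_strides[0]
        if self.encoder.stem_stride == 1:
            # classic U-Net: one up-step fuses the stride-1 stem features
            self.final_ups.append(_Up2(cur, stem_ch, rng, "deconv"))
            self.final_blocks.append(DoubleConv(2 * stem_ch, stem_ch, rng))
            cur = stem_ch
        else:
            steps = int(np.log2(stride))
            for _ in range(steps):
                nxt = max(cur // 2, 8)
                self.final_ups.append(_Up2(cur, nxt, rng, "deconv"))
                self.final_blocks.append(DoubleConv(nxt, nxt, rng))
                cur = nxt
        self.head = Conv2d(cur, config.num_classes, 1, rng)
        self.out_br = BRBlock(config.num_classes, rng) if config.use_br else None

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        deepest = self.encoder.stage_strides[-1]
        if x.data.shape[2] % deepest or x.data.shape[3] % deepest:
            raise ValueError(
                f"input spatial size {x.data.shape[2:]} must be divisible by {deepest}"
            )
        stem_feat, feats = self.encoder(x)
        d = feats[3]
        for j, i in enumerate(reversed(range(3))):
            d = self.ups[j](d)
            d = self.blocks[j](F.concat([d, feats[i]], axis=1))
        if self.encoder.stem_stride == 1:
            d = self.final_ups[0](d)
            d = self.final_blocks[0](F.concat([d, stem_feat], axis=1))
        else:
            for up, block in zip(self.final_ups, self.final_blocks):
                d = block(up(d))
        d = self.head(d)
        if self.out_br is not None:
            d = self.out_br(d)
        return d


def build_improved_unet(config: ModelConfig, seed: int = 0) -> Module:
    """Build the network described by `config` with seeded initialization.

    ``use_gcn=True`` gives the improved U-Net (GCN skips, additive decoder,
    optional BR); ``use_gcn=False`` gives the concatenation-skip baseline,
    which with the ``plain_unet`` encoder is the classic U-Net.
    """
    rng = np.random.default_rng(seed)
    if config.use_gcn:
        return GCNUNet(config, rng)
    return ClassicUNet(config, rng)


def predict(model: Module, images: np.ndarray) -> np.ndarray:
    """Per-pixel argmax prediction for a batch of preprocessed images.

    ``images`` is (N, C, H, W) float; returns (N, H, W) uint8 labels. Ties
    break toward the lower class index (background).
    """
    was_training = model.training
    model.eval()
    scores = model(Tensor(np.ascontiguousarray(images)))
    if was_training:
        model.train()
    return scores.data.argmax(axis=1).astype(np.uint8)
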