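"""V-Net-style 3D encoder-decoder with bottleneck blocks and channel attention.

The architecture is a five-level volumetric encoder-decoder in the V-Net
family.  Its two structural modifications, both aimed at a lightweight
deployable model, are:

* **bottleneck residual blocks** — a 1x1x1 convolution reduces channels by a
  factor ``r_b``, a central 3x3x3 convolution does the spatial processing at
  the reduced width, and a second 1x1x1 convolution restores the width; a
  shortcut branch (identity, or a 1x1x1 projection on width change) is added
  before the final activation.  This cuts parameters by roughly an order of
  magnitude versus plain 3x3x3 blocks of the same width.
* **squeeze-and-excitation (SE) recalibration** — per-channel global average
  pooling (squeeze), two fully connected layers with a sigmoid gate
  (excitation), and channel-wise rescaling of the feature map.

Downsampling uses stride-2 2x2x2 convolutions, upsampling stride-2 2x2x2
transposed convolutions with skip concatenation; the head is a 1x1x1
convolution to two classes followed by a channel softmax.  A plain-convolution
variant (``use_bottleneck=False, use_se=False``) is provided for ablations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkConfig",
    "ComplexityReport",
    "ShapeError",
    "build_bottleneck_block",
    "build_se_block",
    "build_network",
    "SegmentationNet",
    "complexity_report",
]


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the network stride."""


def _default_encoder_blocks(levels: int) -> Tuple[int, ...]:
    return (1, 2, 3, 3, 3)[:levels]


def _default_decoder_blocks(levels: int) -> Tuple[int, ...]:
    # ordered from the deepest decoder stage to the shallowest
    return (3, 3, 2, 1)[-(levels - 1):]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the segmentation network.

    ``levels`` encoder stages with channel widths ``base_width * 2**i``; the
    coarsest feature map is ``2**(levels-1)`` times smaller than the input
    (max stride 16 for the default 5 levels).  ``bottleneck_reduction`` is the
    channel-reduction factor inside bottleneck blocks (mid width floor 4);
    ``se_reduction`` the excitation bottleneck.  The exact widths and
    block counts are reconstruction choices — only the stride structure and
    the bottleneck/SE mechanics are fixed by the design.
    """

    levels: int = 5
    base_width: int = 16
    encoder_blocks: Optional[Tuple[int, ...]] = None
    decoder_blocks: Optional[Tuple[int, ...]] = None
    bottleneck_reduction: int = 4
    se_reduction: int = 2
    use_bottleneck: bool = True
    use_se: bool = True
    in_channels: int = 1
    out_channels: int = 2
    norm: str = "instance"  # "instance" | "none"
    activation: str = "prelu"  # "prelu" | "relu"

    @property
    def max_stride(self) -> int:
        return 2 ** (self.levels - 1)

    @property
    def widths(self) -> Tuple[int, ...]:
        return tuple(self.base_width * 2 ** i for i in range(self.levels))

    def enc_blocks(self) -> Tuple[int, ...]:
        return self.encoder_blocks or _default_encoder_blocks(self.levels)

    def dec_blocks(self) -> Tuple[int, ...]:
        return self.decoder_blocks or _default_decoder_blocks(self.levels)


def _norm_layer(kind: str, channels: int) -> nn.Module:
    if kind == "instance":
        return nn.InstanceNorm3d(channels)
    if kind == "none":
        return nn.Identity()
    raise ValueError(f"unknown norm {kind!r}")


def _act_layer(kind: str, channels: int) -> nn.Module:
    if kind == "prelu":
        return nn.PReLU(channels)
    if kind == "relu":
        return nn.ReLU()
    raise ValueError(f"unknown activation {kind!r}")


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel recalibration."""

    def __init__(self, channels: int, r_se: int = 2, rng: Optional[np.random.Generator] = None):
        if channels // r_se < 1:
            raise ValueError(f"channels/r_se must be >= 1, got {channels}/{r_se}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // r_se, rng=rng)
        self.fc2 = nn.Linear(channels // r_se, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=(2, 3, 4))  # (N, C)
        gate = nn.sigmoid(self.fc2(nn.relu(self.fc1(squeezed))))
        gate = gate.reshape((x.shape[0], self.channels, 1, 1, 1))
        return x * gate


def build_se_block(channels: int, r_se: int = 2, rng: Optional[np.random.Generator] = None) -> SEBlock:
    return SEBlock(channels, r_se, rng)


class BottleneckBlock(nn.Module):
    """reduce(1x1x1) -> conv(3x3x3) -> expand(1x1x1), SE gate, shortcut add."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        r_b: int = 4,
        use_se: bool = False,
        r_se: int = 2,
        norm: str = "instance",
        activation: str = "prelu",
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        mid = out_ch // r_b
        if mid < 1:
            warnings.warn(f"bottleneck mid channels clamped to 1 (out={out_ch}, r_b={r_b})", stacklevel=2)
            mid = 1
        mid = max(mid, min(4, out_ch))  # keep at least 4 mid channels when possible
        self.reduce = nn.Conv3d(in_ch, mid, 1, rng=rng)
        self.n1 = _norm_layer(norm, mid)
        self.a1 = _act_layer(activation, mid)
        self.conv = nn.Conv3d(mid, mid, 3, padding=1, rng=rng)
        self.n2 = _norm_layer(norm, mid)
        self.a2 = _act_layer(activation, mid)
        self.expand = nn.Conv3d(mid, out_ch, 1, rng=rng)
        self.n3 = _norm_layer(norm, out_ch)
        self.se = SEBlock(out_ch, r_se, rng) if use_se else None
        self.shortcut = nn.Conv3d(in_ch, out_ch, 1, rng=rng) if in_ch != out_ch else None
        self.act = _act_layer(activation, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.a1(self.n1(self.reduce(x)))
        h = self.a2(self.n2(self.conv(h)))
        h = self.n3(self.expand(h))
        if self.se is not None:
            h = self.se(h)
        s = self.shortcut(x) if self.shortcut is not None else x
        return self.act(h + s)


def build_bottleneck_block(
    in_ch: int,
    out_ch: int,
    r_b: int = 4,
    norm: str = "none",
    activation: str = "relu",
    rng: Optional[np.random.Generator] = None,
) -> BottleneckBlock:
    """Standalone bottleneck residual block (no SE, bare convs by default)."""
    if in_ch < 1 or out_ch < 1:
        raise ValueError("channel counts must be >= 1")
    return BottleneckBlock(in_ch, out_ch, r_b, use_se=False, norm=norm, activation=activation, rng=rng)


class PlainBlock(nn.Module):
    """Ablation block: one full-width 3x3x3 convolution with residual add."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        use_se: bool = False,
        r_se: int = 2,
        norm: str = "instance",
        activation: str = "prelu",
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.conv = nn.Conv3d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.n1 = _norm_layer(norm, out_ch)
        self.se = SEBlock(out_ch, r_se, rng) if use_se else None
        self.shortcut = nn.Conv3d(in_ch, out_ch, 1, rng=rng) if in_ch != out_ch else None
        self.act = _act_layer(activation, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.n1(self.conv(x))
        if self.se is not None:
            h = self.se(h)
        s = self.shortcut(x) if self.shortcut is not None else x
        return self.act(h + s)


def _make_block(cfg: NetworkConfig, in_ch: int, out_ch: int, rng) -> nn.Module:
    if cfg.use_bottleneck:
        return BottleneckBlock(
            in_ch, out_ch, cfg.bottleneck_reduction, cfg.use_se, cfg.se_reduction,
            cfg.norm, cfg.activation, rng,
        )
    return PlainBlock(in_ch, out_ch, cfg.use_se, cfg.se_reduction, cfg.norm, cfg.activation, rng)


class SegmentationNet(nn.Module):
    """Encoder-decoder with skip connections and channel-softmax head."""

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        widths = config.widths
        enc_blocks = config.enc_blocks()
        dec_blocks = config.dec_blocks()
        if len(enc_blocks) != config.levels or len(dec_blocks) != config.levels - 1:
            raise ValueError("block lists must have `levels` / `levels-1` entries")

        self.encoder_stages: List[List[nn.Module]] = []
        self.down_convs: List[nn.Module] = []
        in_ch = config.in_channels
        for lvl in range(config.levels):
            stage = []
            for b in range(enc_blocks[lvl]):
                stage.append(_make_block(config, in_ch if b == 0 else widths[lvl], widths[lvl], rng))
                in_ch = widths[lvl]
            self.encoder_stages.append(stage)
            if lvl < config.levels - 1:
                self.down_convs.append(nn.Conv3d(widths[lvl], widths[lvl + 1], 2, stride=2, rng=rng))
                in_ch = widths[lvl + 1]

        self.up_convs: List[nn.Module] = []
        self.decoder_stages: List[List[nn.Module]] = []
        for i, lvl in enumerate(range(config.levels - 2, -1, -1)):
            self.up_convs.append(nn.ConvTranspose3d(widths[lvl + 1], widths[lvl], rng=rng))
            stage = []
            for b in range(dec_blocks[i]):
                stage.append(_make_block(config, 2 * widths[lvl] if b == 0 else widths[lvl], widths[lvl], rng))
            self.decoder_stages.append(stage)

        self.head = nn.Conv3d(widths[0], config.out_channels, 1, rng=rng)

    def _check_shape(self, x_shape: Sequence[int]) -> None:
        stride = self.config.max_stride
        for axis, n in enumerate(x_shape[2:]):
            if n % stride != 0:
                raise ShapeError(
                    f"spatial axis {axis} has size {n}, not divisible by max stride {stride}"
                )

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_shape(x.shape)
        skips = []
        h = x
        for lvl, stage in enumerate(self.encoder_stages):
            for block in stage:
                h = block(h)
            if lvl < self.config.levels - 1:
                skips.append(h)
                h = self.down_convs[lvl](h)
        for i, (up, stage) in enumerate(zip(self.up_convs, self.decoder_stages)):
            h = up(h)
            h = nn.concat([h, skips[-(i + 1)]], axis=1)
            for block in stage:
                h = block(h)
        return nn.softmax(self.head(h), axis=1)

    def __call__(self, x) -> Tensor:
        return self.forward(x)


def build_network(config: NetworkConfig = NetworkConfig(), seed: int = 0) -> SegmentationNet:
    """Build the bottleneck+SE network (or its plain ablation variant)."""
    return SegmentationNet(config, seed)


@dataclass(frozen=True)
class ComplexityReport:
    """Parameter, layer and multiply-accumulate accounting for one model."""

    parameters: int
    conv_layers: int
    macs: int
    deployment_bytes: int
    input_size: Tuple[int, int, int]

    def as_row(self) -> str:
        return (
            f"Parameters (M): {self.parameters / 1e6:.2f} | "
            f"Conv layers: {self.conv_layers} | "
            f"GMac @ {self.input_size}: {self.macs / 1e9:.2f} | "
            f"Deployment size (MB): {self.deployment_bytes / 2**20:.2f}"
        )


def complexity_report(model: SegmentationNet, input_size: Sequence[int]) -> ComplexityReport:
    """Count trainable parameters, convolution layers and MACs at a given input.

    MACs follow the convolution closed form ``kernel_volume * C_in * C_out *
    output_voxels`` summed over all (transposed) convolutions, measured by a
    recording forward pass on a zero input.
    """
    input_size = tuple(int(v) for v in input_size)
    x = np.zeros((1, model.config.in_channels) + input_size, dtype=np.float32)
    model.forward(x)
    params = sum(int(p.data.size) for p in model.parameters())
    convs = [m for m in model.modules() if isinstance(m, (nn.Conv3d, nn.ConvTranspose3d))]
    macs = 0
    for conv in convs:
        if conv.last_output_voxels is None:
            continue
        k3 = conv.kernel_size ** 3
        macs += k3 * conv.in_channels * conv.out_channels * conv.last_output_voxels
    return ComplexityReport(
        parameters=params,
        conv_layers=len(convs),
        macs=int(macs),
        deployment_bytes=params * 4,
        input_size=input_size,
    )
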