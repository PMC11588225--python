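"""Assembly of the full segmentation network and its complexity profile.

The architecture is an asymmetric U-shaped encoder-decoder for binary
lesion segmentation, deliberately narrow (default stage widths
4-8-16-32-64) so that the whole model stays around 0.4M parameters:

* encoder: four stages of ``conv3 -> second conv`` (the second conv is a
  :class:`~lesionseg.blocks.CalibratedConv` when enabled) followed by 2x2
  max pooling;
* bottleneck: the same two-conv stage at the widest width, wrapped by a
  :class:`~lesionseg.blocks.DilatedAttention` module when enabled;
* skip connections: plain identity, or a
  :class:`~lesionseg.blocks.FusionSkip` fusing the encoder feature with the
  (pre-upsampling) decoder-side feature when enabled;
* decoder: bilinear x2 upsampling, a 1x1 convolution halving the channel
  count, concatenation with the (possibly fused) skip, then the two-conv
  stage mirroring the encoder;
* aggregation: an optional second decoder that gates the three deepest
  decoder outputs with channel attention, upsamples them to full
  resolution, fuses them by 1x1 convolution and adds them to the final
  decoder feature;
* head: 1x1 convolution to the output channels + sigmoid, yielding a
  probability map the size of the input.

Multiply-accumulate (MAC) counting uses the convention of the common FLOP
profilers: convolutions and matrix products only (one MAC per reported
FLOP); normalisation, activations, pooling and interpolation are excluded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import (CalibratedConv, DilatedAttention, EcaGate, FusionSkip,
                     check_feature_map)
from .nn import Conv2d, ConvUnit, Module

__all__ = [
    "NetworkConfig",
    "ComplexityReport",
    "SegmentationNetwork",
    "build_network",
    "count_params",
    "count_macs",
    "complexity",
    "VARIANTS",
    "variant_config",
    "save_checkpoint",
    "load_checkpoint",
]

_DOWNSAMPLE_FACTOR = 16  # four 2x2 pooling stages


@dataclass
class NetworkConfig:
    """All architecture hyperparameters in one place."""

    stage_widths: tuple[int, int, int, int, int] = (4, 8, 16, 32, 64)
    in_channels: int = 3
    out_channels: int = 1
    input_size: tuple[int, int] = (256, 256)
    use_calibrated: bool = True   # calibrated split conv as second conv of each stage
    use_fusion: bool = True       # symmetric fusion block on every skip connection
    use_attention: bool = True    # dilated-attention module at the bottleneck
    use_aggregation: bool = True  # multi-level aggregation second decoder
    calib_dilation: int = 7
    attention_dilations: tuple[int, int, int] = (2, 4, 6)
    attention_reduction: int = 4
    eca_kernel_size: int = 3

    def __post_init__(self) -> None:
        widths = tuple(int(w) for w in self.stage_widths)
        if len(widths) != 5 or any(w < 1 for w in widths):
            raise ValueError("stage_widths must be five positive integers")
        if self.use_calibrated and any(w % 2 for w in widths):
            raise ValueError(
                "stage_widths must all be even when the calibrated conv is "
                "enabled (it splits channels in half)")
        if self.use_fusion and any(b != 2 * a for a, b in zip(widths, widths[1:])):
            raise ValueError(
                "fusion skips require each stage width to double the previous one")
        self.stage_widths = widths
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        rows, cols = self.input_size
        if rows % _DOWNSAMPLE_FACTOR or cols % _DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"input_size must be divisible by {_DOWNSAMPLE_FACTOR}")
        self.input_size = (int(rows), int(cols))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        d["input_size"] = list(self.input_size)
        d["attention_dilations"] = list(self.attention_dilations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("stage_widths", "input_size", "attention_dilations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


#: The ablation variants: which component toggles each named variant enables,
#: ordered from the plain reduced-width U-Net to the full network.
VARIANTS: dict[str, dict[str, bool]] = {
    "baseline": {},
    "calib": {"use_calibrated": True},
    "fusion": {"use_fusion": True},
    "attention": {"use_attention": True},
    "calib+fusion": {"use_calibrated": True, "use_fusion": True},
    "calib+attention": {"use_calibrated": True, "use_attention": True},
    "fusion+attention": {"use_fusion": True, "use_attention": True},
    "calib+fusion+attention": {"use_calibrated": True, "use_fusion": True,
                               "use_attention": True},
    "full": {"use_calibrated": True, "use_fusion": True, "use_attention": True,
             "use_aggregation": True},
}


def variant_config(name: str, base: NetworkConfig | None = None) -> NetworkConfig:
    """Config for a named ablation variant (all toggles off, then enable)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    base = base or NetworkConfig()
    toggles = {"use_calibrated": False, "use_fusion": False,
               "use_attention": False, "use_aggregation": False}
    toggles.update(VARIANTS[name])
    return replace(base, **toggles)


@dataclass
class ComplexityReport:
    """Trainable parameter count and forward-pass MAC count."""

    param_count: int
    mac_count: int
    input_size: tuple[int, int]

    @property
    def params_millions(self) -> float:
        return round(self.param_count / 1e6, 2)

    @property
    def macs_billions(self) -> float:
        return round(self.mac_count / 1e9, 2)

    def to_dict(self) -> dict:
        return {
            "param_count": int(self.param_count),
            "mac_count": int(self.mac_count),
            "input_size": list(self.input_size),
            "params_M": self.params_millions,
            "flops_G": self.macs_billions,
        }


class _Stage(Module):
    """conv3 -> (calibrated conv | conv3): the repeated two-conv unit."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, *,
                 use_calibrated: bool, calib_dilation: int):
        super().__init__()
        self.first = ConvUnit(cin, cout, 3, rng)
        if use_calibrated:
            self.second: Module = CalibratedConv(cout, rng, dilation=calib_dilation)
        else:
            self.second = ConvUnit(cout, cout, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.second(self.first(x))


class _DecoderStage(Module):
    """bilinear x2 -> 1x1 reduce -> concat skip -> conv3 -> second conv."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, *,
                 use_calibrated: bool, calib_dilation: int):
        super().__init__()
        self.reduce = ConvUnit(cin, cout, 1, rng)
        self.merge = ConvUnit(2 * cout, cout, 3, rng)
        if use_calibrated:
            self.second: Module = CalibratedConv(cout, rng, dilation=calib_dilation)
        else:
            self.second = ConvUnit(cout, cout, 3, rng)

    def forward(self, below: Tensor, skip: Tensor) -> Tensor:
        up = ag.bilinear_resize(below, (skip.shape[2], skip.shape[3]))
        merged = self.merge(ag.concat([self.reduce(up), skip], axis=1))
        return self.second(merged)


class SegmentationNetwork(Module):
    """The assembled encoder-decoder with optional components."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w = cfg.stage_widths
        kw = dict(use_calibrated=cfg.use_calibrated, calib_dilation=cfg.calib_dilation)

        chans = (cfg.in_channels,) + w[:4]
        self.encoder = [_Stage(chans[i], chans[i + 1], rng, **kw) for i in range(4)]
        self.bottleneck = _Stage(w[3], w[4], rng, **kw)
        self.bottleneck_attention = (
            DilatedAttention(w[4], rng, dilations=cfg.attention_dilations,
                             reduction=cfg.attention_reduction)
            if cfg.use_attention else None)

        # decoder runs deepest -> shallowest: widths 32, 16, 8, 4 by default
        self.fusion_skips = (
            [FusionSkip(w[i], rng) for i in (3, 2, 1, 0)] if cfg.use_fusion else None)
        self.decoder = [_DecoderStage(w[i + 1], w[i], rng, **kw) for i in (3, 2, 1, 0)]

        if cfg.use_aggregation:
            self.eca_gates = [EcaGate(cfg.eca_kernel_size, rng) for _ in range(3)]
            agg_in = w[3] + w[2] + w[1]
            self.agg_fuse = ConvUnit(agg_in, w[0], 1, rng)
        else:
            self.eca_gates = None
            self.agg_fuse = None

        self.head = Conv2d(w[0], cfg.out_channels, 1, rng)

    # -- forward -------------------------------------------------------------
    def forward(self, images: Tensor) -> Tensor:
        images = ag.as_tensor(images)
        check_feature_map(images, "images")
        b, c, h, w = images.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % _DOWNSAMPLE_FACTOR or w % _DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"spatial dims must be divisible by {_DOWNSAMPLE_FACTOR}, "
                f"got {h}x{w}")

        skips: list[Tensor] = []
        cur = images
        for stage in self.encoder:
            f = stage(cur)
            skips.append(f)
            cur = ag.max_pool2(f)

        cur = self.bottleneck(cur)
        if self.bottleneck_attention is not None:
            cur = self.bottleneck_attention(cur)

        dec_outs: list[Tensor] = []
        for level, stage in enumerate(self.decoder):
            skip = skips[3 - level]
            if self.fusion_skips is not None:
                skip = self.fusion_skips[level](cur, skip)
            cur = stage(cur, skip)
            dec_outs.append(cur)

        d1, d2, d3, d4 = dec_outs
        feat = self.aggregate(d1, d2, d3, d4) if self.agg_fuse is not None else d4
        return ag.sigmoid(self.head(feat))

    def aggregate(self, d1: Tensor, d2: Tensor, d3: Tensor, d4: Tensor) -> Tensor:
        """Second-decoder fusion of the three deepest decoder outputs into d4.

        d1..d3 sit at 1/8, 1/4 and 1/2 of d4's resolution.  Each is gated by
        channel attention (applied once, no residual), bilinearly upsampled
        to full resolution, concatenated, mapped to d4's width by a 1x1
        convolution and added to d4.
        """
        if self.agg_fuse is None:
            raise RuntimeError("aggregation branch is disabled in this config")
        full = (d4.shape[2], d4.shape[3])
        for name, d, factor in (("d1", d1, 8), ("d2", d2, 4), ("d3", d3, 2)):
            if d.shape[2] * factor != full[0] or d.shape[3] * factor != full[1]:
                raise ValueError(
                    f"{name} must sit at 1/{factor} of d4's resolution")
        gated = [gate.apply(d) for gate, d in zip(self.eca_gates, (d1, d2, d3))]
        upsampled = [ag.bilinear_resize(g, full) for g in gated]
        fused = self.agg_fuse(ag.concat(upsampled, axis=1))
        return d4 + fused


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> SegmentationNetwork:
    """Construct a seeded network from `cfg` (default: full architecture)."""
    cfg = cfg or NetworkConfig()
    rng = np.random.default_rng(seed)
    return SegmentationNetwork(cfg, rng)


# ---------------------------------------------------------------------------
# complexity profiling
# ---------------------------------------------------------------------------

def count_params(net: SegmentationNetwork) -> int:
    """Exact count of trainable scalars (conv kernels, biases, BN affine)."""
    return int(sum(p.size for p in net.parameters()))


def count_macs(net: SegmentationNetwork,
               input_size: tuple[int, int] | None = None) -> int:
    """Multiply-accumulate count of one forward pass at `input_size`.

    Counts convolution and matrix-product operations only (one MAC per
    reported FLOP); batch normalisation, activations, pooling and
    interpolation are excluded.
    """
    rows, cols = input_size or net.cfg.input_size
    was_training = net.training
    net.eval()
    dummy = Tensor(np.zeros((1, net.cfg.in_channels, rows, cols)))
    with ag.profiling() as counter:
        net.forward(dummy)
        total = counter.total
    if was_training:
        net.train()
    return int(total)


def complexity(cfg: NetworkConfig | None = None, seed: int = 0,
               input_size: tuple[int, int] | None = None) -> ComplexityReport:
    cfg = cfg or NetworkConfig()
    net = build_network(cfg, seed)
    size = input_size or cfg.input_size
    return ComplexityReport(param_count=count_params(net),
                            mac_count=count_macs(net, size),
                            input_size=size)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(net: SegmentationNetwork, path) -> None:
    """Write weights, running statistics and the full config to one file."""
    state = net.state_dict()
    np.savez(path, __config__=json.dumps(net.cfg.to_dict()), **state)


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path, allow_pickle=False) as archive:
        cfg = NetworkConfig.from_dict(json.loads(str(archive["__config__"])))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    net = build_network(cfg, seed=0)
    net.load_state_dict(state)
    return net
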