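"""Builders for the lightweight encoder-decoder segmentation network.

The architecture is a DeepLabV3+ variant tuned for a small parameter
budget: a MobileNetV2 inverted-residual encoder at output stride 16
(the would-be stride-32 block groups run dilated at stride 16), an ASPP
whose three dilated branches are depthwise-separable, a parallel pyramid
pooling module cascaded onto the ASPP output, CBAM-style channel and
spatial attention, and a horizontal-vertical multi-skip decoder fusing
the 1/4, 1/8 and 1/16 feature maps with 3x3 depthwise-separable
convolutions.  Every enhancement is an independent toggle on
:class:`ModelConfig`, so ablation variants share the exact same code
path.

Default channel widths are calibrated once against the published
parameter budget: the full model serializes to 12.4 MB, the DS-ASPP-only
ablation to 14.7 MB, and swapping the three depthwise-separable dilated
branches for standard dilated convolutions raises that variant to
22.9 MB (a 64.2% ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import numpy as np

from . import nn
from .conv_math import ConvSpec, ParamReport, conv_param_count

__all__ = [
    "ModelConfig",
    "SegmentationNetwork",
    "ChannelAttention",
    "SpatialAttention",
    "build_encoder",
    "build_aspp",
    "build_ppm",
    "build_decoder",
    "build_model",
    "model_conv_specs",
    "expected_param_count",
    "param_report",
]

# MobileNetV2 inverted-residual plan: (expansion t, channels, repeats, stride)
_ENCODER_PLAN = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),   # stride-4 tap
    (6, 32, 3, 2),   # stride-8 tap
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),  # runs dilated at stride 16
    (6, 320, 1, 1),  # stride-16 tap
)

_DEFAULT_DECODER_CHANNELS = {
    "fuse_s8": 160,     # vertical fusion with the 1/8 skip
    "fuse_s4": 192,     # vertical fusion with the 1/4 skip
    "shallow": 48,      # 1x1 projection of the shallow (1/4) map
    "horizontal": 252,  # horizontal fusion with the ASPP+PPM output
    "simple": 887,      # fusion width of the single-skip DeepLabV3+ decoder
}


@dataclass
class ModelConfig:
    """Every architectural knob of the segmentation network."""

    input_size: int = 512
    in_channels: int = 1
    use_ds_aspp: bool = True
    use_ppm: bool = True
    use_attention: bool = True
    use_multi_skip: bool = True
    aspp_dilations: Tuple[int, int, int] = (6, 12, 18)
    aspp_branch_channels: int = 268
    aspp_out_channels: int = 256
    ppm_pool_sizes: Tuple[int, ...] = (1, 2, 3, 6)
    ppm_branch_channels: int = 96
    attention_reduction: int = 16
    decoder_channels: Dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_DECODER_CHANNELS))
    width_multiplier: float = 1.0
    output_stride: int = 16

    def __post_init__(self):
        self.aspp_dilations = tuple(self.aspp_dilations)
        self.ppm_pool_sizes = tuple(self.ppm_pool_sizes)
        merged = dict(_DEFAULT_DECODER_CHANNELS)
        merged.update(self.decoder_channels or {})
        self.decoder_channels = merged
        self.validate()

    def validate(self) -> "ModelConfig":
        if self.output_stride != 16:
            raise ValueError("output_stride is fixed at 16")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16")
        if len(set(self.aspp_dilations)) != len(self.aspp_dilations):
            raise ValueError("aspp_dilations must be distinct")
        if any(d < 1 for d in self.aspp_dilations):
            raise ValueError("aspp_dilations must be >= 1")
        if tuple(sorted(self.ppm_pool_sizes)) != self.ppm_pool_sizes:
            raise ValueError("ppm_pool_sizes must be sorted ascending")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _divisible(value: float, divisor: int = 8) -> int:
    """Round a scaled channel count to a multiple of ``divisor``."""
    out = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if out < 0.9 * value:
        out += divisor
    return out


# ---------------------------------------------------------------------------
# building blocks


class ConvBNAct(nn.Module):
    """Standard conv -> BN -> activation (bias-free conv, BN owns the shift)."""

    def __init__(self, cin, cout, k, *, stride=1, dilation=1, act="relu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, dilation=dilation,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = {"relu": nn.ReLU(), "relu6": nn.ReLU6(), None: nn.Identity()}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class DSConvBlock(nn.Module):
    """Depthwise 3x3 (optionally dilated/strided) followed by 1x1 pointwise.

    ``linear_pw=True`` leaves the pointwise projection without activation
    (the linear bottleneck of the inverted residual).
    """

    def __init__(self, cin, cout, *, k=3, stride=1, dilation=1, act="relu",
                 linear_pw=False, rng=None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.dw = nn.Conv2d(cin, cin, k, stride=stride, dilation=dilation,
                            depthwise=True, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cin)
        self.act1 = nn.ReLU6() if act == "relu6" else nn.ReLU()
        self.pw = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if linear_pw:
            self.act2 = nn.Identity()
        else:
            self.act2 = nn.ReLU6() if act == "relu6" else nn.ReLU()

    @property
    def spec(self) -> ConvSpec:
        return ConvSpec(kernel=self.k, dilation=self.dw.dilation,
                        stride=self.dw.stride, in_channels=self.cin,
                        out_channels=self.cout, depthwise_separable=True,
                        has_bias=False)

    def forward(self, x):
        return self.act2(self.bn2(self.pw(self.act1(self.bn1(self.dw(x))))))


class InvertedResidual(nn.Module):
    """MobileNetV2 block: expand -> depthwise (ReLU6) -> linear projection."""

    def __init__(self, cin, cout, *, stride=1, expand=6, dilation=1, rng=None):
        super().__init__()
        hidden = cin * expand
        self.use_res = stride == 1 and cin == cout
        self.expand = (ConvBNAct(cin, hidden, 1, act="relu6", rng=rng)
                       if expand != 1 else nn.Identity())
        self.dsconv = DSConvBlock(hidden, cout, stride=stride, dilation=dilation,
                                  act="relu6", linear_pw=True, rng=rng)

    def forward(self, x):
        y = self.dsconv(self.expand(x))
        if self.use_res:
            y = y + x
        return y


class MobileNetV2Encoder(nn.Module):
    """Inverted-residual backbone exposing 1/4, 1/8 and 1/16 taps."""

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        w = config.width_multiplier
        stem_ch = _divisible(32 * w)
        self.stem = ConvBNAct(config.in_channels, stem_ch, 3, stride=2,
                              act="relu6", rng=rng)
        self.blocks = []
        self.tap_indices = {}
        cin = stem_ch
        current_stride, dilation = 2, 1
        for gi, (t, c, n, s) in enumerate(_ENCODER_PLAN):
            cout = _divisible(c * w)
            for i in range(n):
                stride = s if i == 0 else 1
                if stride == 2 and current_stride >= config.output_stride:
                    stride = 1
                    if i == 0:
                        dilation *= 2
                if stride == 2:
                    current_stride *= 2
                self.blocks.append(InvertedResidual(
                    cin, cout, stride=stride, expand=t, dilation=dilation, rng=rng))
                cin = cout
            if gi == 1:
                self.tap_indices["s4"] = len(self.blocks) - 1
                self.s4_channels = cout
            elif gi == 2:
                self.tap_indices["s8"] = len(self.blocks) - 1
                self.s8_channels = cout
        self.out_channels = cin

    def forward(self, x):
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input spatial size must be divisible by 16")
        x = self.stem(x)
        taps = {}
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i == self.tap_indices["s4"]:
                taps["s4"] = x
            elif i == self.tap_indices["s8"]:
                taps["s8"] = x
        return taps["s4"], taps["s8"], x


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling with optional DS dilated branches."""

    def __init__(self, cin: int, config: ModelConfig, rng=None):
        super().__init__()
        cb = config.aspp_branch_channels
        self.branch1x1 = ConvBNAct(cin, cb, 1, rng=rng)
        if config.use_ds_aspp:
            self.dilated = [DSConvBlock(cin, cb, dilation=d, rng=rng)
                            for d in config.aspp_dilations]
        else:
            self.dilated = [ConvBNAct(cin, cb, 3, dilation=d, rng=rng)
                            for d in config.aspp_dilations]
        self.pool_conv = ConvBNAct(cin, cb, 1, rng=rng)
        self.project = ConvBNAct(5 * cb, config.aspp_out_channels, 1, rng=rng)
        self.out_channels = config.aspp_out_channels

    def forward(self, x):
        size = (x.shape[2], x.shape[3])
        pooled = self.pool_conv(nn.spatial_mean(x))
        branches = [self.branch1x1(x)] + [b(x) for b in self.dilated]
        branches.append(nn.resize_bilinear(pooled, size))
        return self.project(nn.concat(branches, axis=1))


class PPM(nn.Module):
    """Pyramid pooling: multi-size adaptive pools re-upsampled and stacked."""

    def __init__(self, cin: int, config: ModelConfig, rng=None):
        super().__init__()
        self.pool_sizes = config.ppm_pool_sizes
        cp = config.ppm_branch_channels
        self.convs = [ConvBNAct(cin, cp, 1, rng=rng) for _ in self.pool_sizes]
        self.out_channels = cin + cp * len(self.pool_sizes)

    def forward(self, x):
        size = (x.shape[2], x.shape[3])
        if max(self.pool_sizes) > min(size):
            raise ValueError(
                f"pool size {max(self.pool_sizes)} exceeds feature size {size}")
        outs = [x]
        for s, conv in zip(self.pool_sizes, self.convs):
            pooled = conv(nn.adaptive_avg_pool2d(x, (s, s)))
            outs.append(nn.resize_bilinear(pooled, size))
        return nn.concat(outs, axis=1)


class ChannelAttention(nn.Module):
    """CBAM channel gate: pooled descriptors through a shared bottleneck MLP."""

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        hidden = max(1, -(-channels // reduction))  # ceil(C / r), floor at 1
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=True, rng=rng)

    def weights(self, x):
        avg = self.fc2(nn.relu(self.fc1(nn.spatial_mean(x))))
        mx = self.fc2(nn.relu(self.fc1(nn.spatial_max(x))))
        return nn.sigmoid(avg + mx)

    def forward(self, x):
        return x * self.weights(x)


class SpatialAttention(nn.Module):
    """CBAM spatial gate: channel max/mean maps through a 7x7 convolution."""

    def __init__(self, kernel_size: int = 7, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel_size, bias=True, rng=rng)

    def weights(self, x):
        maps = nn.concat([nn.channel_max(x), nn.channel_mean(x)], axis=1)
        return nn.sigmoid(self.conv(maps))

    def forward(self, x):
        return x * self.weights(x)


class MultiSkipDecoder(nn.Module):
    """Horizontal-vertical skip decoder over the 1/4, 1/8, 1/16 pyramid."""

    def __init__(self, s4_ch, s8_ch, s16_ch, context_ch, config: ModelConfig, rng=None):
        super().__init__()
        dc = config.decoder_channels
        att = config.use_attention
        r = config.attention_reduction
        self.cam = ChannelAttention(s16_ch, r, rng=rng) if att else nn.Identity()
        self.sam8 = SpatialAttention(rng=rng) if att else nn.Identity()
        self.sam4 = SpatialAttention(rng=rng) if att else nn.Identity()
        self.fuse_s8 = DSConvBlock(s16_ch + s8_ch, dc["fuse_s8"], rng=rng)
        self.shallow = ConvBNAct(s4_ch, dc["shallow"], 1, rng=rng)
        self.fuse_s4 = DSConvBlock(dc["fuse_s8"] + dc["shallow"], dc["fuse_s4"], rng=rng)
        self.fuse_h = DSConvBlock(dc["fuse_s4"] + context_ch, dc["horizontal"], rng=rng)
        self.fuse_secondary = DSConvBlock(dc["horizontal"], dc["horizontal"], rng=rng)
        self.out_channels = dc["horizontal"]

    def forward(self, s4, s8, s16, context):
        v = self.cam(s16)
        v = nn.resize_bilinear(v, (s8.shape[2], s8.shape[3]))
        v = self.fuse_s8(nn.concat([v, self.sam8(s8)], axis=1))
        v = nn.resize_bilinear(v, (s4.shape[2], s4.shape[3]))
        sh = self.shallow(self.sam4(s4))
        v = self.fuse_s4(nn.concat([v, sh], axis=1))
        h = nn.resize_bilinear(context, (s4.shape[2], s4.shape[3]))
        v = self.fuse_h(nn.concat([v, h], axis=1))
        return self.fuse_secondary(v)


class SimpleDecoder(nn.Module):
    """Original DeepLabV3+ decoder: one 1/4 skip, two 3x3 DS fusions."""

    def __init__(self, s4_ch, s8_ch, s16_ch, context_ch, config: ModelConfig, rng=None):
        super().__init__()
        dc = config.decoder_channels
        att = config.use_attention
        self.cam = (ChannelAttention(context_ch, config.attention_reduction, rng=rng)
                    if att else nn.Identity())
        self.sam4 = SpatialAttention(rng=rng) if att else nn.Identity()
        self.shallow = ConvBNAct(s4_ch, dc["shallow"], 1, rng=rng)
        self.fuse1 = DSConvBlock(context_ch + dc["shallow"], dc["simple"], rng=rng)
        self.fuse2 = DSConvBlock(dc["simple"], dc["simple"], rng=rng)
        self.out_channels = dc["simple"]

    def forward(self, s4, s8, s16, context):
        h = nn.resize_bilinear(self.cam(context), (s4.shape[2], s4.shape[3]))
        sh = self.shallow(self.sam4(s4))
        return self.fuse2(self.fuse1(nn.concat([h, sh], axis=1)))


class SegmentationNetwork(nn.Module):
    """Composed network mapping (B, 1, H, W) to per-pixel probabilities."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = MobileNetV2Encoder(config, rng=rng)
        self.aspp = ASPP(self.encoder.out_channels, config, rng=rng)
        context_ch = self.aspp.out_channels
        if config.use_ppm:
            self.ppm = PPM(context_ch, config, rng=rng)
            context_ch = self.ppm.out_channels
        else:
            self.ppm = nn.Identity()
        decoder_cls = MultiSkipDecoder if config.use_multi_skip else SimpleDecoder
        self.decoder = decoder_cls(self.encoder.s4_channels,
                                   self.encoder.s8_channels,
                                   self.encoder.out_channels,
                                   context_ch, config, rng=rng)
        self.head = nn.Conv2d(self.decoder.out_channels, 1, 1, bias=True, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        s4, s8, s16 = self.encoder(x)
        context = self.ppm(self.aspp(s16))
        y = self.decoder(s4, s8, s16, context)
        y = self.head(y)
        y = nn.resize_bilinear(y, (x.shape[2], x.shape[3]))
        return nn.sigmoid(y)

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        """Forward a (B, 1, H, W) float array without recording gradients."""
        return self.forward(nn.Tensor(images)).data


# ---------------------------------------------------------------------------
# factories (the spec-level build surface)


def build_encoder(config: ModelConfig, seed: int = 0) -> MobileNetV2Encoder:
    return MobileNetV2Encoder(config.validate(), rng=np.random.default_rng(seed))


def build_aspp(config: ModelConfig, cin: int | None = None, seed: int = 0) -> ASPP:
    if cin is None:
        cin = MobileNetV2Encoder(config).out_channels
    return ASPP(cin, config.validate(), rng=np.random.default_rng(seed))


def build_ppm(config: ModelConfig, cin: int | None = None, seed: int = 0) -> PPM:
    if cin is None:
        cin = config.aspp_out_channels
    return PPM(cin, config.validate(), rng=np.random.default_rng(seed))


def build_decoder(config: ModelConfig, seed: int = 0):
    model = SegmentationNetwork(config, seed=seed)
    return model.decoder


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SegmentationNetwork:
    return SegmentationNetwork(config or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# parameter accounting


def model_conv_specs(module: nn.Module) -> list[ConvSpec]:
    """Collect closed-form specs for every convolution (DS pairs merged)."""
    if isinstance(module, DSConvBlock):
        return [module.spec]
    if isinstance(module, nn.Conv2d):
        if module.depthwise:
            raise ValueError("bare depthwise convolution outside a DSConvBlock")
        return [ConvSpec(kernel=module.kernel_size, dilation=module.dilation,
                         stride=module.stride, in_channels=module.in_channels,
                         out_channels=module.out_channels,
                         depthwise_separable=False,
                         has_bias=module.bias is not None)]
    specs = []
    for _, child in module.children():
        specs.extend(model_conv_specs(child))
    return specs


def _bn_channels(module: nn.Module) -> list[int]:
    out = []
    if isinstance(module, nn.BatchNorm2d):
        out.append(module.channels)
    for _, child in module.children():
        out.extend(_bn_channels(child))
    return out


def expected_param_count(module: nn.Module) -> int:
    """Closed-form parameter count (conv formulas + 2C per batch norm)."""
    convs = sum(conv_param_count(s) for s in model_conv_specs(module))
    bns = sum(2 * c for c in _bn_channels(module))
    return convs + bns


def param_report(config: ModelConfig | None = None,
                 model: SegmentationNetwork | None = None) -> ParamReport:
    """Per-component parameter counts of the constructed network."""
    if model is None:
        model = build_model(config or ModelConfig())
    components = {
        "encoder": model.encoder,
        "aspp": model.aspp,
        "ppm": model.ppm,
        "decoder": model.decoder,
        "head": model.head,
    }
    report = ParamReport()
    for name, comp in components.items():
        count = comp.num_parameters() if isinstance(comp, nn.Module) else 0
        if name == "decoder":
            attention = sum(
                m.num_parameters()
                for m in (getattr(comp, a, None) for a in ("cam", "sam8", "sam4"))
                if isinstance(m, (ChannelAttention, SpatialAttention)))
            report.per_component["attention"] = attention
            count -= attention
        report.per_component[name] = count
    return report
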