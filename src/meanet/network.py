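"""The multilayer edge-attention segmentation network (MEA-Net).

The architecture has three parts:

* a **feature encoder** of four encoding blocks (asymmetric-convolution
  residual blocks) separated by 2x2 max pooling, producing features
  E1..E4 at full, 1/2, 1/4 and 1/8 resolution;
* an **edge module**: edge feature extraction (EFE) fuses shallow
  encoder stages into a stack of N edge-attention maps, and multilayer
  attention guidance (MAG) multiplies each map into the shallow
  features, sums the products, gates channels with a squeeze-and-
  excitation (SE) block and emits decoder-bound edge features Y1 plus a
  one-channel edge prediction Y2 for early supervision;
* a **feature decoder** of three cascaded decoding blocks with a
  channel-attention gate on the upsampled high-level branch, followed
  by a fusion convolution that combines the last decoder output with Y1
  into the final segmentation probability map.

Every block is seedable, so two networks built from the same
configuration and seed are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import tensor as T
from .nn import BatchNorm2d, Conv2d, ConvReLUBN, Linear, Module
from .tensor import Tensor

STAGE_NAMES = ("E1", "E2", "E3", "E4")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Parameters
    ----------
    input_channels : number of image channels (1 grayscale, 3 RGB).
    stage_widths : channel widths of encoder stages E1..E4.
    attention_maps : N, the number of edge-attention maps the EFE emits.
    se_reduction : bottleneck divisor of the SE gate (floor, minimum 1).
    efe_stages : which encoder stages feed the EFE; deeper stages are
        bilinearly upsampled back to E1 resolution.
    use_efe / use_mag : ablation switches for the two edge submodules.
    y1_fusion : how Y1 joins the last decoder output ("concat" | "add").
    decoder_merge : how a decoding block combines its two branches
        ("add" | "concat").
    input_size : optional (H, W) the pipeline resizes images to.
    """

    input_channels: int = 3
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    attention_maps: int = 16
    se_reduction: int = 16
    efe_stages: tuple[str, ...] = ("E1", "E2")
    use_efe: bool = True
    use_mag: bool = True
    y1_fusion: str = "concat"
    decoder_merge: str = "add"
    input_size: tuple[int, int] | None = None

    def __post_init__(self):
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        self.efe_stages = tuple(self.efe_stages)
        if len(self.stage_widths) != 4 or any(w <= 0 for w in self.stage_widths):
            raise ValueError(f"stage_widths must be 4 positive ints, got {self.stage_widths}")
        if self.attention_maps < 1:
            raise ValueError("attention_maps must be >= 1")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        bad = set(self.efe_stages) - set(STAGE_NAMES)
        if bad:
            raise ValueError(f"unknown efe_stages {sorted(bad)}; valid: {STAGE_NAMES}")
        if self.use_efe and not self.efe_stages:
            raise ValueError("efe_stages must be non-empty when use_efe is on")
        if self.y1_fusion not in ("concat", "add"):
            raise ValueError(f"y1_fusion must be 'concat' or 'add', got {self.y1_fusion!r}")
        if self.decoder_merge not in ("add", "concat"):
            raise ValueError(f"decoder_merge must be 'add' or 'concat', got {self.decoder_merge!r}")
        if self.input_size is not None:
            self.input_size = (int(self.input_size[0]), int(self.input_size[1]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        d["efe_stages"] = list(self.efe_stages)
        d["input_size"] = list(self.input_size) if self.input_size else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if d.get("input_size"):
            d["input_size"] = tuple(d["input_size"])
        return cls(**d)


@dataclass
class EdgeOutputs:
    """The edge module's two products."""

    y1: Tensor          # decoder-bound edge features, E1 resolution
    y2_logits: Tensor   # 1-channel edge logits, E1 resolution


@dataclass
class NetworkOutputs:
    seg_prob: Tensor                # (B, 1, H, W) in [0, 1]
    edge_prob: Tensor | None = None  # (B, 1, H, W) in [0, 1], None for baseline


def _ensure_batched(x) -> tuple[Tensor, bool]:
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), True
    if t.ndim != 4:
        raise ValueError(f"expected (C,H,W) or (B,C,H,W) array, got shape {t.shape}")
    return t, False


class EncodingBlock(Module):
    """Asymmetric-convolution residual block.

    Main path: 3x3 conv -> 3x1 conv -> 1x3 conv (each conv+ReLU+BN);
    residual path: 1x1 conv+ReLU+BN; the two are summed.  Resolution is
    preserved ("same" padding throughout).
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        if out_channels <= 0:
            raise ValueError(f"out_channels must be positive, got {out_channels}")
        self.conv3 = ConvReLUBN(in_channels, out_channels, 3, rng)
        self.conv31 = ConvReLUBN(out_channels, out_channels, (3, 1), rng)
        self.conv13 = ConvReLUBN(out_channels, out_channels, (1, 3), rng)
        self.residual = ConvReLUBN(in_channels, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        main = self.conv13(self.conv31(self.conv3(x)))
        return main + self.residual(x)


class Encoder(Module):
    """Four encoding blocks with 2x2 max pooling between stages."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        widths = cfg.stage_widths
        chans = (cfg.input_channels,) + widths[:-1]
        self.blocks = [EncodingBlock(c_in, c_out, rng)
                       for c_in, c_out in zip(chans, widths)]

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        B, C, H, W = x.shape
        if H % 8 or W % 8:
            raise ValueError(
                f"input spatial size ({H}, {W}) must be divisible by 8: "
                "the encoder halves resolution three times between its four stages")
        feats: dict[str, Tensor] = {}
        h = x
        for i, (name, block) in enumerate(zip(STAGE_NAMES, self.blocks)):
            if i > 0:
                h = T.max_pool2d(h)
            h = block(h)
            feats[name] = h
        return feats


class EFEModule(Module):
    """Edge feature extraction: A = sum_s U^(k_s)[Conv3x3(E_s)].

    Each configured encoder stage is mapped to ``attention_maps``
    channels by a 3x3 conv (+ReLU+BN); stages deeper than E1 are
    bilinearly upsampled (x2 per level) back to E1 resolution, and the
    branches are summed elementwise into the attention stack.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.stages = tuple(sorted(cfg.efe_stages, key=STAGE_NAMES.index))
        self.branches = [ConvReLUBN(cfg.stage_widths[STAGE_NAMES.index(s)],
                                    cfg.attention_maps, 3, rng)
                         for s in self.stages]
        self.attention_maps = cfg.attention_maps

    def forward(self, feats: dict[str, Tensor]) -> Tensor:
        out = None
        for stage, branch in zip(self.stages, self.branches):
            h = branch(feats[stage])
            for _ in range(STAGE_NAMES.index(stage)):
                h = T.upsample_bilinear2x(h)
            out = h if out is None else out + h
        return out


def efe_forward(x1, x2, branch1: ConvReLUBN, branch2: ConvReLUBN) -> Tensor:
    """Two-stage EFE combination: Conv(X1) + upsample2x(Conv(X2)).

    ``x2`` must be at exactly half of ``x1``'s resolution in each
    dimension (the E1/E2 relationship).
    """
    t1, squeeze = _ensure_batched(x1)
    t2, _ = _ensure_batched(x2)
    if (t1.shape[2], t1.shape[3]) != (2 * t2.shape[2], 2 * t2.shape[3]):
        raise ValueError(
            f"X2 spatial size {t2.shape[2:]} must be exactly half of X1's {t1.shape[2:]}")
    out = branch1(t1) + T.upsample_bilinear2x(branch2(t2))
    return out.reshape(out.shape[1:]) if squeeze else out


def mag_aggregate(attention, x1) -> Tensor:
    """U_total = sum_m (A_m (x) X1): each single-channel attention map
    multiplies every channel of X1 elementwise and the N products are
    summed.  Because each term is A_m broadcast against X1, the sum
    factorises to (sum_m A_m) (x) X1, which is how it is evaluated.
    """
    a, squeeze = _ensure_batched(attention)
    x, _ = _ensure_batched(x1)
    if a.shape[2:] != x.shape[2:]:
        raise ValueError(
            f"attention stack spatial size {a.shape[2:]} != features' {x.shape[2:]}")
    out = a.sum(axis=1, keepdims=True) * x
    return out.reshape(out.shape[1:]) if squeeze else out


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pooling to z in R^C.  Excitation:
    s = sigmoid(W1 relu(W2 z)) with a C/reduction bottleneck (floored,
    minimum width 1); both fully connected layers are bias-free, so the
    gate is exactly the written gating function.  Scale: each channel
    u_k is rescaled by its gate s_k in [0, 1].
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.reduce = Linear(channels, hidden, rng, bias=False)   # W2
        self.expand = Linear(hidden, channels, rng, bias=False)   # W1
        self.channels = channels

    def gates(self, u: Tensor) -> Tensor:
        z = T.global_avg_pool(u)               # (B, C)
        return self.expand(self.reduce(z).relu()).sigmoid()

    def forward(self, u: Tensor) -> Tensor:
        s = self.gates(u)
        B, C = s.shape
        return s.reshape(B, C, 1, 1) * u


class EdgeHeads(Module):
    """The edge module's two 1x1-convolution output branches.

    Y1: edge features routed to the decoder (conv+ReLU+BN).
    Y2: edge prediction for early supervision (conv+ReLU+BN followed by
    a 1-channel logit head).
    """

    def __init__(self, in_channels: int, y1_channels: int, rng: np.random.Generator):
        super().__init__()
        self.y1_conv = ConvReLUBN(in_channels, y1_channels, 1, rng)
        self.y2_conv = ConvReLUBN(in_channels, in_channels, 1, rng)
        self.y2_head = Conv2d(in_channels, 1, 1, rng)

    def forward(self, u: Tensor) -> EdgeOutputs:
        return EdgeOutputs(y1=self.y1_conv(u),
                           y2_logits=self.y2_head(self.y2_conv(u)))


class MAGModule(Module):
    """Multilayer attention guidance: aggregate, SE-gate, two heads."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        channels = cfg.stage_widths[0]  # X1 is E1
        self.se = SEBlock(channels, cfg.se_reduction, rng)
        self.heads = EdgeHeads(channels, cfg.stage_widths[0], rng)

    def forward(self, attention: Tensor, x1: Tensor) -> EdgeOutputs:
        u_total = mag_aggregate(attention, x1)
        return self.heads(self.se(u_total))


class DecodingBlock(Module):
    """Fuse low-level (skip) and high-level (deeper) features.

    Branch 1: 1x1 conv of the low-level features.  Branch 2: 1x1 conv
    of the high-level features, bilinear x2 upsampling, then a channel
    gate (global max pooling -> 1x1 conv+ReLU -> 1x1 conv+sigmoid)
    whose [0, 1] weights rescale the upsampled features.  The branches
    are combined by elementwise addition (default) or concatenation
    plus a 1x1 projection.
    """

    def __init__(self, low_channels: int, high_channels: int,
                 rng: np.random.Generator, merge: str = "add"):
        super().__init__()
        out = low_channels
        self.low_proj = Conv2d(low_channels, out, 1, rng)
        self.high_proj = Conv2d(high_channels, out, 1, rng)
        self.gate_fc1 = Conv2d(out, out, 1, rng)
        self.gate_fc2 = Conv2d(out, out, 1, rng)
        self.merge = merge
        if merge == "concat":
            self.merge_proj = Conv2d(2 * out, out, 1, rng)
        self.out_channels = out

    def forward(self, low: Tensor, high: Tensor) -> Tensor:
        if (low.shape[2], low.shape[3]) != (2 * high.shape[2], 2 * high.shape[3]):
            raise ValueError(
                f"high-level spatial size {high.shape[2:]} must be half of "
                f"low-level's {low.shape[2:]}")
        b1 = self.low_proj(low)
        up = T.upsample_bilinear2x(self.high_proj(high))
        w = self.gate_fc2(self.gate_fc1(T.global_max_pool(up)).relu()).sigmoid()
        gated = up * w
        if self.merge == "concat":
            return self.merge_proj(T.concat([b1, gated], axis=1))
        return b1 + gated

    def gate_weights(self, high: Tensor) -> Tensor:
        """Channel gate values for given high-level features (testing aid)."""
        up = T.upsample_bilinear2x(self.high_proj(high))
        return self.gate_fc2(self.gate_fc1(T.global_max_pool(up)).relu()).sigmoid()


class MEANet(Module):
    """Full edge-attention encoder-decoder segmentation network."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.PCG64(seed))
        w = cfg.stage_widths
        self.encoder = Encoder(cfg, rng)
        # edge module (ablatable)
        if cfg.use_efe:
            self.efe = EFEModule(cfg, rng)
        elif cfg.use_mag:
            # attention stack from a plain 3x3 projection of E1
            self.att_proj = ConvReLUBN(w[0], cfg.attention_maps, 3, rng)
        if cfg.use_mag:
            self.mag = MAGModule(cfg, rng)
        elif cfg.use_efe:
            self.edge_heads = EdgeHeads(cfg.attention_maps, w[0], rng)
        # decoder: D3 fuses E3/E4, D2 fuses E2/D3, D1 fuses E1/D2
        self.decoders = [DecodingBlock(w[2], w[3], rng, cfg.decoder_merge),
                         DecodingBlock(w[1], w[2], rng, cfg.decoder_merge),
                         DecodingBlock(w[0], w[1], rng, cfg.decoder_merge)]
        fuse_in = w[0]
        if self.has_edge_module and cfg.y1_fusion == "concat":
            fuse_in = 2 * w[0]
        self.final_conv = Conv2d(fuse_in, 1, 3, rng)

    # ------------------------------------------------------------------
    @property
    def has_edge_module(self) -> bool:
        return self.cfg.use_efe or self.cfg.use_mag

    def edge_forward(self, feats: dict[str, Tensor]) -> EdgeOutputs | None:
        cfg = self.cfg
        if not self.has_edge_module:
            return None
        if cfg.use_efe:
            attention = self.efe(feats)
        else:
            attention = self.att_proj(feats["E1"])
        if cfg.use_mag:
            return self.mag(attention, feats["E1"])
        return self.edge_heads(attention)

    def forward(self, x) -> NetworkOutputs:
        t, squeeze = _ensure_batched(x)
        feats = self.encoder(t)
        edge = self.edge_forward(feats)
        d = self.decoders[0](feats["E3"], feats["E4"])
        d = self.decoders[1](feats["E2"], d)
        d = self.decoders[2](feats["E1"], d)
        if edge is not None:
            if self.cfg.y1_fusion == "concat":
                d = T.concat([d, edge.y1], axis=1)
            else:
                d = d + edge.y1
        seg = self.final_conv(d).sigmoid()
        edge_prob = edge.y2_logits.sigmoid() if edge is not None else None
        if squeeze:
            seg = seg.reshape(seg.shape[1:])
            if edge_prob is not None:
                edge_prob = edge_prob.reshape(edge_prob.shape[1:])
        return NetworkOutputs(seg_prob=seg, edge_prob=edge_prob)


# ----------------------------------------------------------------------
# Checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(model: MEANet, path) -> None:
    """Write weights + full configuration to a single .npz archive."""
    import json

    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, expected_cfg: NetworkConfig | None = None) -> MEANet:
    """Rebuild a model from a checkpoint; fail loudly on config mismatch."""
    import json

    with np.load(path) as archive:
        if "__config__" not in archive:
            raise ValueError(f"{path} is not a model checkpoint (no config entry)")
        cfg = NetworkConfig.from_dict(
            json.loads(archive["__config__"].tobytes().decode()))
        if expected_cfg is not None and cfg != expected_cfg:
            raise ValueError(
                "checkpoint configuration does not match the expected one:\n"
                f"  checkpoint: {cfg}\n  expected:   {expected_cfg}")
        state = {k.replace("/", "."): archive[k]
                 for k in archive.files if k != "__config__"}
    model = MEANet(cfg)
    model.load_state_dict(state)
    return model
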