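"""MFDA-UNet assembly.

Layout (default stem stride 4, widths W0..W3):

    stem:      two 3x3 stride-2 conv + ChannelLN + SiLU units  -> H/4, W0
    encoder:   4 stages of 2 MFDA blocks; a 3x3 stride-2 conv between
               stages doubles the reduction and switches width -> H/32, W3
    decoder:   3 levels; each = 2x2 transposed-conv upsample, GCSA fusion
               with the same-level encoder feature (added residually), then
               an inverted-residual block
    heads:     1x1 conv deep-supervision head per decoder level (logits
               bilinearly upsampled to full resolution); the final head
               restores full resolution with two more transposed convs

DropPath rates increase linearly over the 8 encoder blocks up to
``drop_path_max``.  The ablation switches reproduce the variant family:
``frequency_decoupling=False`` (attention over all channels — strictly more
parameters), ``positional_encoding=False`` (no CPE/LePE),
``gcsa_mode='off'`` (plain additive skips), ``conv_baseline=True`` (pure
convolutional blocks in place of MFDA), ``deep_supervision=False``.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import engine as eg
from .attention_core import map_to_tokens, mela_macs, tokens_to_map
from .engine import Tensor
from .frequency_blocks import BlockParams, MFDABlock
from .gcsa import GCSA, GCSA_MODES, SkipPair, gcsa_macs


@dataclass
class ModelConfig:
    """Architectural hyperparameters of MFDA-UNet."""

    in_channels: int = 3
    num_classes: int = 1
    stage_widths: tuple[int, ...] = (32, 64, 128, 256)
    depth_per_stage: int = 2
    stem_stride: int = 4
    mlp_ratio: int = 4
    drop_path_max: float = 0.1
    num_heads: int = 1
    gcsa_mode: str = "gate_on_output"
    positional_encoding: bool = True
    frequency_decoupling: bool = True
    deep_supervision: bool = True
    conv_baseline: bool = False
    seed: int = 0

    def __post_init__(self):
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        if len(self.stage_widths) != 4:
            raise ValueError("exactly four stage widths are required")
        if any(w % 2 for w in self.stage_widths):
            raise ValueError("stage widths must be even (channel splitting)")
        if any(a > b for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValueError("stage widths must be non-decreasing")
        if self.stem_stride != 4:
            raise ValueError("stem uses two stride-2 convolutions (stride 4)")
        if self.gcsa_mode not in GCSA_MODES:
            raise ValueError(f"gcsa_mode must be one of {GCSA_MODES}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def total_stride(self) -> int:
        return self.stem_stride * 2 ** 3

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        return d


class InvertedResidual(eg.Module):
    """1x1 expand -> DWConv3x3 -> 1x1 project, SiLU, channel LayerNorm,
    residual connection (MobileNet-style, batch-free normalization)."""

    def __init__(self, channels: int, expansion: int = 4):
        super().__init__()
        hidden = channels * expansion
        self.expansion = expansion
        self.expand = eg.Conv2d(channels, hidden, 1)
        self.norm1 = eg.ChannelLayerNorm(hidden)
        self.dwconv = eg.Conv2d(hidden, hidden, 3, padding=1, groups=hidden)
        self.norm2 = eg.ChannelLayerNorm(hidden)
        self.project = eg.Conv2d(hidden, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = eg.silu(self.norm1(self.expand(x)))
        y = eg.silu(self.norm2(self.dwconv(y)))
        return x + self.project(y)

    __call__ = forward


class ConvStem(eg.Module):
    """Patch embedding: two 3x3 stride-2 convolutions (x4 downsample)."""

    def __init__(self, in_channels: int, width: int):
        super().__init__()
        self.conv1 = eg.Conv2d(in_channels, width, 3, stride=2, padding=1)
        self.norm1 = eg.ChannelLayerNorm(width)
        self.conv2 = eg.Conv2d(width, width, 3, stride=2, padding=1)
        self.norm2 = eg.ChannelLayerNorm(width)

    def forward(self, x: Tensor) -> Tensor:
        x = eg.silu(self.norm1(self.conv1(x)))
        x = eg.silu(self.norm2(self.conv2(x)))
        return x

    __call__ = forward


class TokenStage(eg.Module):
    """A stack of MFDA (or baseline conv) blocks run in token layout."""

    def __init__(self, cfg: ModelConfig, width: int, drop_rates: list[float]):
        super().__init__()
        self.conv_blocks = cfg.conv_baseline
        if cfg.conv_baseline:
            self.blocks = eg.ModuleList(
                [InvertedResidual(width, expansion=2) for _ in drop_rates])
        else:
            self.blocks = eg.ModuleList([
                MFDABlock(BlockParams(
                    channels=width, mlp_ratio=cfg.mlp_ratio, drop_path=r,
                    num_heads=cfg.num_heads,
                    positional_encoding=cfg.positional_encoding,
                    frequency_decoupling=cfg.frequency_decoupling))
                for r in drop_rates])

    def forward(self, x: Tensor) -> Tensor:
        if self.conv_blocks:
            for blk in self.blocks:
                x = blk(x)
            return x
        tokens, spatial = map_to_tokens(x)
        for blk in self.blocks:
            tokens = blk(tokens, spatial)
        return tokens_to_map(tokens, spatial)

    __call__ = forward


@dataclass
class SegOutput:
    """Network output: full-resolution main logits plus (optionally) one
    pre-upsampled auxiliary logit map per decoder level."""

    main_logits: object
    aux_logits: list = field(default_factory=list)


class MFDAUNet(eg.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.stage_widths
        depth = cfg.depth_per_stage
        n_blocks = 4 * depth
        rates = [cfg.drop_path_max * i / max(n_blocks - 1, 1)
                 for i in range(n_blocks)]
        self.stem = ConvStem(cfg.in_channels, w[0])
        self.enc_stages = eg.ModuleList([
            TokenStage(cfg, w[i], rates[i * depth:(i + 1) * depth])
            for i in range(4)])
        self.downs = eg.ModuleList([
            eg.Conv2d(w[i], w[i + 1], 3, stride=2, padding=1) for i in range(3)])
        self.ups = eg.ModuleList([
            eg.ConvTranspose2x2(w[i + 1], w[i]) for i in reversed(range(3))])
        if cfg.gcsa_mode != "off":
            self.skips = eg.ModuleList([
                GCSA(w[i], cfg.gcsa_mode) for i in reversed(range(3))])
        self.dec_blocks = eg.ModuleList([
            InvertedResidual(w[i]) for i in reversed(range(3))])
        if cfg.deep_supervision:
            self.aux_heads = eg.ModuleList([
                eg.Conv2d(w[i], cfg.num_classes, 1) for i in reversed(range(3))])
        self.final_up1 = eg.ConvTranspose2x2(w[0], w[0])
        self.final_norm = eg.ChannelLayerNorm(w[0])
        self.final_up2 = eg.ConvTranspose2x2(w[0], w[0])
        self.head = eg.Conv2d(w[0], cfg.num_classes, 1)

    def forward(self, image) -> SegOutput:
        x = image if isinstance(image, Tensor) else Tensor(image)
        B, C, H, W = x.shape
        if C != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {C}")
        if H % self.cfg.total_stride or W % self.cfg.total_stride:
            raise ValueError(
                f"spatial size {H}x{W} not divisible by {self.cfg.total_stride}")
        x = self.stem(x)
        enc_feats = []
        for i in range(4):
            x = self.enc_stages[i](x)
            enc_feats.append(x)
            if i < 3:
                x = self.downs[i](x)
        # decoder: from deepest feature back up through three levels
        aux = []
        for lvl in range(3):
            x = self.ups[lvl](x)
            enc = enc_feats[2 - lvl]
            if self.cfg.gcsa_mode != "off":
                x = x + self.skips[lvl](SkipPair(enc=enc, dec=x))
            else:
                x = x + enc
            x = self.dec_blocks[lvl](x)
            if self.cfg.deep_supervision:
                logits = self.aux_heads[lvl](x)
                aux.append(eg.upsample_bilinear(logits, (H, W)))
        y = eg.silu(self.final_norm(self.final_up1(x)))
        y = self.final_up2(y)
        main = self.head(y)
        # nearest full resolution first
        return SegOutput(main_logits=main, aux_logits=list(reversed(aux)))

    __call__ = forward


def build_model(cfg: ModelConfig) -> MFDAUNet:
    """Construct an MFDA-UNet with reproducible (seeded) initialization."""
    eg.manual_seed(cfg.seed)
    return MFDAUNet(cfg)


def model_forward(model: MFDAUNet, image) -> SegOutput:
    return model(image)


def count_parameters(model: eg.Module) -> int:
    """Number of trainable scalars in the model."""
    return model.num_parameters()


def per_module_parameters(model: eg.Module) -> dict[str, int]:
    """Trainable-parameter count per top-level submodule."""
    out = {}
    for name, sub in model._modules.items():
        out[name] = sub.num_parameters()
    return out


# ---------------------------------------------------------------------------
# analytic cost model
# ---------------------------------------------------------------------------

def _conv_macs(cin, cout, k, hout, wout, groups=1):
    return (k * k * cin // groups) * cout * hout * wout


def _inverted_residual_macs(C, H, W, expansion):
    hidden = C * expansion
    return (_conv_macs(C, hidden, 1, H, W) + _conv_macs(hidden, hidden, 3, H, W, hidden)
            + _conv_macs(hidden, C, 1, H, W))


def _mfda_block_macs(cfg: ModelConfig, C, H, W):
    N = H * W
    macs = 0
    if cfg.frequency_decoupling:
        half = C // 2
        macs += 9 * half * N              # avg pool (counted as 3x3 window)
        if cfg.positional_encoding:
            macs += 9 * half * N          # low-path CPE
        macs += mela_macs(N, half, cfg.num_heads, cfg.positional_encoding)
        macs += 25 * half * N + half * half * N  # high branch DW5x5 + 1x1
        macs += C * C * N                 # fusion linear
    else:
        if cfg.positional_encoding:
            macs += 9 * C * N
        macs += mela_macs(N, C, cfg.num_heads, cfg.positional_encoding)
    if cfg.positional_encoding:
        macs += 9 * C * N                 # block-level CPE
    macs += 2 * cfg.mlp_ratio * C * C * N  # MLP
    return macs


def flop_estimate(model_or_cfg, input_shape: tuple[int, int]) -> int:
    """Analytic multiply-add count of one forward pass at ``input_shape``
    (H, W).  Attention is counted in the reassociated O(N C^2) order."""
    cfg = model_or_cfg.cfg if isinstance(model_or_cfg, MFDAUNet) else model_or_cfg
    H, W = input_shape
    if H % cfg.total_stride or W % cfg.total_stride:
        raise ValueError(f"input {H}x{W} not divisible by {cfg.total_stride}")
    w = cfg.stage_widths
    macs = 0
    macs += _conv_macs(cfg.in_channels, w[0], 3, H // 2, W // 2)
    macs += _conv_macs(w[0], w[0], 3, H // 4, W // 4)
    hs = [H // 4 // 2 ** i for i in range(4)]
    ws = [W // 4 // 2 ** i for i in range(4)]
    for i in range(4):
        for _ in range(cfg.depth_per_stage):
            if cfg.conv_baseline:
                macs += _inverted_residual_macs(w[i], hs[i], ws[i], 2)
            else:
                macs += _mfda_block_macs(cfg, w[i], hs[i], ws[i])
        if i < 3:
            macs += _conv_macs(w[i], w[i + 1], 3, hs[i + 1], ws[i + 1])
    for lvl, i in enumerate(reversed(range(3))):
        macs += 4 * w[i + 1] * w[i] * hs[i] * ws[i]  # transposed conv 2x2
        if cfg.gcsa_mode != "off":
            macs += gcsa_macs(hs[i] * ws[i], w[i])
        macs += _inverted_residual_macs(w[i], hs[i], ws[i], 4)
        if cfg.deep_supervision:
            macs += w[i] * cfg.num_classes * hs[i] * ws[i]
    macs += 4 * w[0] * w[0] * (H // 2) * (W // 2)
    macs += 4 * w[0] * w[0] * H * W
    macs += w[0] * cfg.num_classes * H * W
    return int(macs)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: MFDAUNet, extra: dict | None = None) -> None:
    """Single-file checkpoint: weight map keyed by hierarchical layer names
    plus the embedded config (so the model can be rebuilt)."""
    payload = dict(model.state_dict())
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> tuple[MFDAUNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode("utf-8"))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    model = build_model(cfg)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
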