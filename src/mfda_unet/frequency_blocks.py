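"""Frequency-decoupled feature mixing and the MFDA block.

Medical images mix smooth, large-scale anatomy (low spatial frequencies)
with fine edges and texture (high frequencies).  The mixer here splits the
block width in half along the channel axis and separates frequencies with
a 3x3 average pool:

    low  = AvgPool3x3(half1)
    high = half2 - AvgPool3x3(half2)

The pool averages only valid in-image pixels, so a spatially constant input
has exactly zero high-frequency content, borders included (DC rejection),
and ``high`` is by construction the float-exact difference between ``half2``
and its smoothed version.

The low path gets conditional positional encoding (CPE, x + DWConv3x3(x))
and global mixing by MELA linear attention; the high path gets a purely
convolutional pipeline (InstanceNorm -> 5x5 DWConv -> SiLU -> 1x1 conv).
The two halves are concatenated (low first) and fused by a linear layer.

The MFDA block wraps the mixer in a pre-norm transformer skeleton:

    X'   = X  + DropPath(FD-MELA(LN(X)))
    X''  = X' + DWConv3x3(X')                 (a second CPE, its own weights)
    Xout = X'' + DropPath(MLP(LN(X'')))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as eg
from .attention_core import MELA, TokenSequence, map_to_tokens, tokens_to_map
from .engine import Tensor


@dataclass
class FrequencyPair:
    """Half-width low/high frequency token sequences (each B, N, C/2)."""

    low: object
    high: object
    spatial: tuple[int, int]


@dataclass
class BlockParams:
    """Hyperparameters of one MFDA block."""

    channels: int
    mlp_ratio: int = 4
    drop_path: float = 0.0
    num_heads: int = 1
    positional_encoding: bool = True
    frequency_decoupling: bool = True

    def __post_init__(self):
        if self.channels % 2:
            raise ValueError("block width must be even for channel splitting")
        if self.mlp_ratio < 1:
            raise ValueError("mlp_ratio must be >= 1")
        if not 0.0 <= self.drop_path < 1.0:
            raise ValueError("drop_path must be in [0, 1)")


def freq_decouple(x, spatial: tuple[int, int]) -> FrequencyPair:
    """Split channels in half and separate low/high frequencies by average
    pooling (valid-pixel border handling).  Works on arrays or Tensors."""
    C = x.shape[-1]
    if C % 2:
        raise ValueError(f"channel count {C} must be even")
    is_tensor = isinstance(x, Tensor)
    half1 = x[:, :, : C // 2]
    half2 = x[:, :, C // 2:]
    m1 = tokens_to_map(half1, spatial)
    m2 = tokens_to_map(half2, spatial)
    low_m = eg.box_filter3(m1 if is_tensor else Tensor(m1))
    pool2 = eg.box_filter3(m2 if is_tensor else Tensor(m2))
    high_m = (m2 if is_tensor else Tensor(m2)) - pool2
    low, _ = map_to_tokens(low_m)
    high, _ = map_to_tokens(high_m)
    if not is_tensor:
        low, high = low.data, high.data
    return FrequencyPair(low=low, high=high, spatial=spatial)


class HighFreqBranch(eg.Module):
    """Convolutional path for high-frequency content.

    InstanceNorm removes per-sample contrast shifts, a 5x5 depth-wise
    convolution extracts local topology, SiLU adds non-linearity and a 1x1
    convolution projects channels (C/2 -> C/2).
    """

    def __init__(self, channels: int):
        super().__init__()
        self.norm = eg.InstanceNorm2d()
        self.dwconv = eg.Conv2d(channels, channels, 5, padding=2, groups=channels)
        self.proj = eg.Conv2d(channels, channels, 1)

    def forward(self, x: Tensor, spatial: tuple[int, int]) -> Tensor:
        m = tokens_to_map(x, spatial)
        m = self.norm(m)
        m = eg.silu(self.dwconv(m))
        m = self.proj(m)
        out, _ = map_to_tokens(m)
        return out

    __call__ = forward


class CPE(eg.Module):
    """Conditional positional encoding: x + DWConv3x3(x) in spatial layout."""

    def __init__(self, channels: int):
        super().__init__()
        self.dwconv = eg.Conv2d(channels, channels, 3, padding=1, groups=channels)

    def forward(self, x: Tensor, spatial: tuple[int, int]) -> Tensor:
        m = tokens_to_map(x, spatial)
        y, _ = map_to_tokens(self.dwconv(m))
        return x + y

    __call__ = forward


class FDMela(eg.Module):
    """The frequency-decoupled MELA feature mixer.

    Low path: CPE -> MELA (global mixing); high path: HighFreqBranch
    (local detail); halves concatenated (low first) and fused C -> C.
    With ``frequency_decoupling`` off, MELA runs over all C channels with
    no split or high branch — more parameters for the same width.
    """

    def __init__(self, p: BlockParams):
        super().__init__()
        self.params = p
        C = p.channels
        if p.frequency_decoupling:
            half = C // 2
            if p.positional_encoding:
                self.cpe_low = CPE(half)
            self.mela = MELA(half, p.num_heads, p.drop_path,
                             use_lepe=p.positional_encoding)
            self.high_branch = HighFreqBranch(half)
            self.fuse = eg.Linear(C, C)
        else:
            if p.positional_encoding:
                self.cpe_low = CPE(C)
            self.mela = MELA(C, p.num_heads, p.drop_path,
                             use_lepe=p.positional_encoding)

    def forward(self, x: Tensor, spatial: tuple[int, int]) -> Tensor:
        if not self.params.frequency_decoupling:
            z = self.cpe_low(x, spatial) if self.params.positional_encoding else x
            return self.mela(z, spatial)
        pair = freq_decouple(x, spatial)
        low = pair.low
        if self.params.positional_encoding:
            low = self.cpe_low(low, spatial)
        low_out = self.mela(low, spatial)
        high_out = self.high_branch(pair.high, spatial)
        return self.fuse(eg.concat([low_out, high_out], axis=-1))

    __call__ = forward


class MLP(eg.Module):
    def __init__(self, channels: int, ratio: int = 4):
        super().__init__()
        hidden = channels * ratio
        self.fc1 = eg.Linear(channels, hidden)
        self.fc2 = eg.Linear(hidden, channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(eg.gelu(self.fc1(x)))

    __call__ = forward


class MFDABlock(eg.Module):
    """Pre-norm residual block: LN -> FD-MELA -> DropPath residual, CPE,
    LN -> MLP -> DropPath residual.  With every learned weight zeroed it
    reduces to the identity map in eval mode."""

    def __init__(self, p: BlockParams):
        super().__init__()
        self.params = p
        self.norm1 = eg.LayerNorm(p.channels)
        self.mixer = FDMela(p)
        self.drop_path1 = eg.DropPath(p.drop_path)
        if p.positional_encoding:
            self.cpe = CPE(p.channels)
        self.norm2 = eg.LayerNorm(p.channels)
        self.mlp = MLP(p.channels, p.mlp_ratio)
        self.drop_path2 = eg.DropPath(p.drop_path)

    def forward(self, x: Tensor, spatial: tuple[int, int]) -> Tensor:
        x = x + self.drop_path1(self.mixer(self.norm1(x), spatial))
        if self.params.positional_encoding:
            x = self.cpe(x, spatial)
        x = x + self.drop_path2(self.mlp(self.norm2(x)))
        return x

    __call__ = forward


# convenience functional wrappers mirroring the module surface -------------

def high_freq_branch(branch: HighFreqBranch, high, spatial):
    t = high if isinstance(high, Tensor) else Tensor(high)
    out = branch(t, spatial)
    return out if isinstance(high, Tensor) else out.data


def cpe(mod: CPE, x, spatial):
    t = x if isinstance(x, Tensor) else Tensor(x)
    out = mod(t, spatial)
    return out if isinstance(x, Tensor) else out.data


def fd_mela_forward(mod: FDMela, x, spatial):
    t = x if isinstance(x, Tensor) else Tensor(x)
    out = mod(t, spatial)
    return out if isinstance(x, Tensor) else out.data


def mfda_block_forward(block: MFDABlock, x, spatial):
    t = x if isinstance(x, Tensor) else Tensor(x)
    out = block(t, spatial)
    return out if isinstance(x, Tensor) else out.data
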