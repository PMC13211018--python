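"""Gated cross-scale attention (GCSA) skip connections.

In a U-shaped network the encoder feature at a given level carries local
detail while the (upsampled) decoder feature carries semantics.  GCSA fuses
them with kernelized cross attention: decoder tokens form the queries,
encoder tokens the keys and values, computed in the same reassociated
O(N C^2) order as MELA.  A gate derived from the decoder tokens — a
two-layer MLP with GELU, squashed by a sigmoid — filters the fused feature
before the output projection.

Four wiring modes mirror the ablation variants of the gating design:
``off`` (no module; the network falls back to plain addition), ``ungated``
(no gate), ``gate_on_v`` (gate multiplies the value projection before
attention) and ``gate_on_output`` (default: gate multiplies the fused
feature before the output projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as eg
from .attention_core import (AttentionTriplet, kernel_map, lepe,
                             linear_attention, map_to_tokens, tokens_to_map)
from .engine import Tensor

GCSA_MODES = ("off", "ungated", "gate_on_v", "gate_on_output")


@dataclass
class SkipPair:
    """Same-shape encoder/decoder feature maps (B, C, H, W); the decoder
    feature is upsampled by the caller before entry."""

    enc: object
    dec: object

    def __post_init__(self):
        if self.enc.shape != self.dec.shape:
            raise ValueError(
                f"encoder/decoder shape mismatch: {self.enc.shape} vs {self.dec.shape}")


class GCSA(eg.Module):
    def __init__(self, channels: int, mode: str = "gate_on_output"):
        super().__init__()
        if mode not in GCSA_MODES or mode == "off":
            raise ValueError(f"gcsa mode must be one of {GCSA_MODES[1:]}, got {mode!r}")
        self.channels = channels
        self.mode = mode
        self.norm_enc = eg.LayerNorm(channels)
        self.norm_dec = eg.LayerNorm(channels)
        self.wq = eg.Linear(channels, channels)
        self.wk = eg.Linear(channels, channels)
        self.wv = eg.Linear(channels, channels)
        self.lepe_conv = eg.Conv2d(channels, channels, 3, padding=1,
                                   groups=channels)
        self.gate_fc1 = eg.Linear(channels, channels)
        self.gate_fc2 = eg.Linear(channels, channels)
        self.proj = eg.Linear(channels, channels)

    # -- pieces exposed for testing ---------------------------------------
    def cross_scale_projections(self, p: SkipPair):
        """LN + project both streams; Q from decoder, K/V from encoder.

        Q and K pass through the positive kernel map; V is a plain linear
        projection of the encoder stream."""
        enc = p.enc if isinstance(p.enc, Tensor) else Tensor(p.enc)
        dec = p.dec if isinstance(p.dec, Tensor) else Tensor(p.dec)
        enc_t, spatial = map_to_tokens(enc)
        dec_t, _ = map_to_tokens(dec)
        enc_t = self.norm_enc(enc_t)
        dec_t = self.norm_dec(dec_t)
        q = kernel_map(self.wq(dec_t))
        k = kernel_map(self.wk(enc_t))
        v = self.wv(enc_t)
        return AttentionTriplet(q, k, v), dec_t, spatial

    def gate_from_decoder(self, dec_tokens: Tensor) -> Tensor:
        """G = sigmoid(Linear(GELU(Linear(dec)))) in (0, 1), shape (B, N, C)."""
        return eg.sigmoid(self.gate_fc2(eg.gelu(self.gate_fc1(dec_tokens))))

    def forward(self, p: SkipPair):
        triplet, dec_t, spatial = self.cross_scale_projections(p)
        gated_v = self.mode in ("gate_on_v",)
        g = self.gate_from_decoder(dec_t) if self.mode != "ungated" else None
        v = triplet.V
        if gated_v:
            v = v * g
        y = linear_attention(AttentionTriplet(triplet.Q, triplet.K, v))
        y = y + lepe(v, spatial, self.lepe_conv.weight, self.lepe_conv.bias)
        if self.mode == "gate_on_output":
            y = y * g
        out = self.proj(y)
        out_map = tokens_to_map(out, spatial)
        return out_map if isinstance(p.enc, Tensor) else out_map.data

    __call__ = forward


def gcsa_forward(module: GCSA, enc, dec):
    """Fuse an encoder/decoder feature-map pair; returns (B, C, H, W)."""
    return module(SkipPair(enc=enc, dec=dec))


def gcsa_macs(N: int, C: int) -> int:
    """Analytic multiply-adds of one GCSA application at N tokens, width C."""
    from .attention_core import attention_macs
    macs = 3 * N * C * C                 # Q, K, V projections
    macs += attention_macs(N, C)
    macs += N * C * 9                    # LePE
    macs += 2 * N * C * C                # gate MLP
    macs += N * C * C                    # output projection
    return macs
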