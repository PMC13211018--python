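"""Mamba-enhanced linear attention (MELA).

Standard softmax attention forms an N x N weight matrix and therefore costs
O(N^2) in the token count N = H*W.  Linear attention replaces the softmax
with a strictly positive kernel feature map phi(x) = ELU(x) + 1 applied to
queries and keys, so the product can be reassociated as Q (K^T V) and the
cost drops to O(N C^2).  A per-query normalization factor rho — the inverse
inner product of the query with the mean key — makes the implied attention
weights sum to one, exactly as a softmax row would.

The MELA block wraps this attention in a gated dual-branch macro-structure
borrowed from state-space (Mamba-style) blocks: a SiLU-gated bypass, a
depth-wise convolution on the main branch, values taken verbatim from the
main branch (V = Z), locally-enhanced positional encoding (LePE, a 3x3
depth-wise convolution on V added residually to the attention output), a
Hadamard gate fusion, an output projection and DropPath.

All functional ops below accept either numpy arrays or engine Tensors and
return the matching kind, so they serve both as differentiable building
blocks inside the network and as plain numerical routines in analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as eg
from .engine import Tensor

EPS_RHO = 1e-6  # tiny constant guarding the rho denominator

#: analytic multiply-add guard for the quadratic-cost oracle
ORACLE_N_LIMIT = 512


# ---------------------------------------------------------------------------
# token containers
# ---------------------------------------------------------------------------

@dataclass
class TokenSequence:
    """A flattened feature map: data (B, N, C) plus its spatial shape.

    N must equal H*W so the sequence can be reshaped to (B, C, H, W) and
    back without loss.
    """

    data: object  # numpy array or engine Tensor, (B, N, C)
    spatial: tuple[int, int]

    def __post_init__(self):
        H, W = self.spatial
        n = self.data.shape[1]
        if n != H * W:
            raise ValueError(f"token count {n} != H*W = {H}*{W}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class AttentionTriplet:
    """Post-kernel-map queries/keys and values, all (B, N, C)."""

    Q: object
    K: object
    V: object
    epsilon: float = EPS_RHO

    def __post_init__(self):
        qs, ks, vs = self.Q.shape, self.K.shape, self.V.shape
        if not (qs == ks == vs):
            raise ValueError(f"Q/K/V shape mismatch: {qs}, {ks}, {vs}")


def tokens_to_map(x, spatial: tuple[int, int]):
    """(B, N, C) -> (B, C, H, W)."""
    H, W = spatial
    B, N, C = x.shape
    if N != H * W:
        raise ValueError(f"token count {N} incompatible with spatial {spatial}")
    if isinstance(x, Tensor):
        return eg.transpose(x, (0, 2, 1)).reshape(B, C, H, W)
    return np.ascontiguousarray(np.transpose(x, (0, 2, 1)).reshape(B, C, H, W))


def map_to_tokens(x):
    """(B, C, H, W) -> ((B, N, C), (H, W))."""
    B, C, H, W = x.shape
    if isinstance(x, Tensor):
        return eg.transpose(x.reshape(B, C, H * W), (0, 2, 1)), (H, W)
    return np.ascontiguousarray(
        np.transpose(x.reshape(B, C, H * W), (0, 2, 1))), (H, W)


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(x), False


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def kernel_map(x):
    """phi(x) = ELU(x) + 1: strictly positive feature map for Q/K."""
    t, was_tensor = _wrap(x)
    if not np.all(np.isfinite(t.data)):
        raise ValueError("kernel_map requires finite input")
    out = eg.elu_plus_one(t)
    return out if was_tensor else out.data


def linear_attention(t: AttentionTriplet):
    """Kernelized attention in the reassociated O(N C^2) order.

    Y = Q ((1/N) K^T V) * rho,  rho_i = 1 / (Q_i . mean_j K_j + eps).

    The N x N weight matrix is never materialized; with eps = 0 the implied
    weights (Q_i . K_j / N) * rho_i sum to exactly one per query.
    """
    q, q_t = _wrap(t.Q)
    k, k_t = _wrap(t.K)
    v, v_t = _wrap(t.V)
    eps = float(t.epsilon)
    if np.any(q.data <= 0) or np.any(k.data <= 0):
        if eps == 0.0:
            raise ValueError("non-positive Q/K with epsilon=0: division hazard")
    N = q.shape[1]
    kv = eg.matmul(eg.transpose(k, (0, 2, 1)), v) * (1.0 / N)  # (B, C, C)
    num = eg.matmul(q, kv)                                     # (B, N, C)
    k_mean = eg.tmean(k, axis=1, keepdims=True)                # (B, 1, C)
    denom = eg.tsum(q * k_mean, axis=-1, keepdims=True) + eps  # (B, N, 1)
    out = num / denom
    return out if (q_t or k_t or v_t) else out.data


def naive_attention_oracle(t: AttentionTriplet) -> np.ndarray:
    """Reference O(N^2) computation of the same attention (tests only).

    Forms the explicit weight matrix A_ij = (Q_i . K_j / N) * rho_i and
    returns A V.  Refuses N above ORACLE_N_LIMIT to keep memory bounded.
    """
    Q = np.asarray(t.Q.data if isinstance(t.Q, Tensor) else t.Q, dtype=float)
    K = np.asarray(t.K.data if isinstance(t.K, Tensor) else t.K, dtype=float)
    V = np.asarray(t.V.data if isinstance(t.V, Tensor) else t.V, dtype=float)
    N = Q.shape[1]
    if N > ORACLE_N_LIMIT:
        raise ValueError(f"oracle limited to N <= {ORACLE_N_LIMIT}, got {N}")
    scores = np.einsum("bic,bjc->bij", Q, K) / N          # (B, N, N)
    rho = 1.0 / (scores.sum(axis=2, keepdims=True) + t.epsilon)
    return np.einsum("bij,bjc->bic", scores * rho, V)


def implied_attention_weights(t: AttentionTriplet) -> np.ndarray:
    """The explicit (B, N, N) weight matrix A implied by linear attention."""
    Q = np.asarray(t.Q.data if isinstance(t.Q, Tensor) else t.Q, dtype=float)
    K = np.asarray(t.K.data if isinstance(t.K, Tensor) else t.K, dtype=float)
    N = Q.shape[1]
    if N > ORACLE_N_LIMIT:
        raise ValueError(f"oracle limited to N <= {ORACLE_N_LIMIT}, got {N}")
    scores = np.einsum("bic,bjc->bij", Q, K) / N
    rho = 1.0 / (scores.sum(axis=2, keepdims=True) + t.epsilon)
    return scores * rho


def lepe(v, spatial: tuple[int, int], weight, bias=None):
    """Locally-enhanced positional encoding: DWConv3x3 over V in spatial
    layout, flattened back.  Returns the convolution output alone; the
    caller adds it residually to the attention output."""
    t, was_tensor = _wrap(v)
    m = tokens_to_map(t, spatial)
    y = eg.conv2d(m, weight, bias, stride=1, padding=1, groups=m.shape[1])
    out, _ = map_to_tokens(y)
    return out if was_tensor else out.data


def _split_heads(x: Tensor, heads: int) -> Tensor:
    B, N, C = x.shape
    return eg.transpose(x.reshape(B, N, heads, C // heads), (0, 2, 1, 3)) \
             .reshape(B * heads, N, C // heads)


def _merge_heads(x: Tensor, heads: int, B: int) -> Tensor:
    Bh, N, Ch = x.shape
    return eg.transpose(x.reshape(B, heads, N, Ch), (0, 2, 1, 3)) \
             .reshape(B, N, heads * Ch)


# ---------------------------------------------------------------------------
# the MELA module
# ---------------------------------------------------------------------------

class MELA(eg.Module):
    """Gated dual-branch linear-attention block.

    Gate branch:  G = SiLU(Linear(x)).
    Main branch:  Z = SiLU(DWConv3x3(Linear(x))) computed through the
    spatial layout.  Q = phi(Z Wq), K = phi(Z Wk), V = Z; attention output
    plus LePE(V) is gated by G (Hadamard), projected and DropPath'ed.

    Parameters
    ----------
    channels : token width C (must be divisible by num_heads)
    num_heads : attention heads; 1 by default (single-head), heads are
        folded into the batch axis
    drop_path : stochastic-depth rate of the block's output
    use_lepe : disable to drop the positional-encoding term (ablation)
    """

    def __init__(self, channels: int, num_heads: int = 1,
                 drop_path: float = 0.0, use_lepe: bool = True):
        super().__init__()
        if channels % num_heads:
            raise ValueError("channels must be divisible by num_heads")
        self.channels = channels
        self.num_heads = num_heads
        self.use_lepe = use_lepe
        self.gate = eg.Linear(channels, channels)
        self.main = eg.Linear(channels, channels)
        self.dwconv = eg.Conv2d(channels, channels, 3, padding=1, groups=channels)
        self.wq = eg.Linear(channels, channels)
        self.wk = eg.Linear(channels, channels)
        if use_lepe:
            self.lepe_conv = eg.Conv2d(channels, channels, 3, padding=1,
                                       groups=channels)
        self.proj = eg.Linear(channels, channels)
        self.drop_path = eg.DropPath(drop_path)

    def forward(self, x: Tensor, spatial: tuple[int, int]) -> Tensor:
        B = x.shape[0]
        g = eg.silu(self.gate(x))
        z = self.main(x)
        z = tokens_to_map(z, spatial)
        z = eg.silu(self.dwconv(z))
        z, _ = map_to_tokens(z)
        q = kernel_map(self.wq(z))
        k = kernel_map(self.wk(z))
        v = z
        if self.num_heads > 1:
            qh, kh, vh = (_split_heads(t, self.num_heads) for t in (q, k, v))
            y = linear_attention(AttentionTriplet(qh, kh, vh))
            y = _merge_heads(y, self.num_heads, B)
        else:
            y = linear_attention(AttentionTriplet(q, k, v))
        if self.use_lepe:
            y = y + lepe(v, spatial, self.lepe_conv.weight, self.lepe_conv.bias)
        out = self.proj(y * g)
        return self.drop_path(out)

    __call__ = forward


# ---------------------------------------------------------------------------
# analytic cost model
# ---------------------------------------------------------------------------

def attention_macs(N: int, C: int, num_heads: int = 1) -> int:
    """Multiply-adds of the linear-attention core (reassociated order).

    Counts K^T V (N C^2 / heads), Q (K^T V) (N C^2 / heads), the mean key
    (N C) and the rho inner product (N C): linear in N, no N^2 term.
    """
    ch = C // num_heads
    per_head = 2 * N * ch * ch + 2 * N * ch
    return num_heads * per_head


def naive_attention_macs(N: int, C: int) -> int:
    """Multiply-adds of the explicit N x N formulation (oracle)."""
    return 2 * N * N * C + N * N  # QK^T, AV, row normalization


def mela_macs(N: int, C: int, num_heads: int = 1, use_lepe: bool = True) -> int:
    """Full MELA block multiply-adds at sequence length N, width C."""
    macs = 0
    macs += 2 * N * C * C          # gate + main linear
    macs += N * C * 9              # DWConv3x3 on main branch
    macs += 2 * N * C * C          # Wq, Wk
    macs += attention_macs(N, C, num_heads)
    if use_lepe:
        macs += N * C * 9
    macs += N * C * C              # output projection
    return macs
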