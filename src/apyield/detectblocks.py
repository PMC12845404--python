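"""Attention/state-space feature blocks for orchard fruit detection.

These are the architectural contributions of the YOLO-A detector as
standalone, composable image-feature operators on ``[B, C, H, W]`` tensors:

* ``SS2D`` — four-direction 2-D selective scan: the feature map is
  flattened row-major (left-to-right and right-to-left) and column-major
  (top-to-bottom and bottom-to-top); each direction runs a diagonal linear
  state-space recurrence ``h_t = A h_{t-1} + B x_t, y_t = C h_t + D x_t``
  and the four outputs are summed.  (Non-selective diagonal SSM: the
  contract is the four-direction scan + recurrence + sum.)
* ``GLICM`` — a convolutional local branch plus an SS2D global branch,
  summed and refined by sequential axial (H, then W) and channel attention.
* ``FMA`` — Fourier-modulated attention: 2-D DFT over space, multiplication
  by a learnable complex spectral filter, inverse DFT, sigmoid-gated
  residual combination with the input.
* ``FSPPF`` — SPPF (1x1 conv, three cascaded stride-1 5x5 max-pools,
  concatenation) with FMA inserted before the output projection.
* ``IAFM`` — interactive attention fusion of two same-resolution maps:
  ConvAttn on each input, shuffled-concat through single-head
  self-attention (x~), an explicit elementwise product (x*), concatenation
  of all four parts, and a conv/BN/GELU/depthwise/pointwise output stack.

Blocks preserve batch and spatial dimensions; channel transitions are
documented per block.  No block resizes its input implicitly.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat, dft_matrices, idft_matrices, max_pool2d, softmax


# ---------------------------------------------------------------------------
# SS2D

class SSMParams(nn.Module):
    """Diagonal linear SSM for one scan direction."""

    def __init__(self, channels: int, state_dim: int, rng):
        super().__init__()
        # |A| <= 1 at init keeps the recurrence stable
        self.A = Tensor(rng.uniform(0.0, 0.9, size=state_dim), requires_grad=True)
        self.B = Tensor(nn._kaiming(rng, channels, (channels, state_dim)),
                        requires_grad=True)
        self.C = Tensor(nn._kaiming(rng, state_dim, (state_dim, channels)),
                        requires_grad=True)
        self.D = Tensor(np.ones(channels), requires_grad=True)


class SS2D(nn.Module):
    """Four-direction 2-D scan with per-direction SSM recurrences, summed."""

    def __init__(self, channels: int, state_dim: int, rng):
        super().__init__()
        self.dirs = [SSMParams(channels, state_dim, rng) for _ in range(4)]

    @staticmethod
    def _scan(seq: Tensor, p: SSMParams) -> Tensor:
        """seq [B, L, C] -> [B, L, C] via h_t = A h_{t-1} + x_t B."""
        b, L, c = seq.shape
        h = Tensor(np.zeros((b, p.A.shape[0])))
        ys = []
        for t in range(L):
            h = h * p.A + seq[:, t, :] @ p.B
            ys.append(h @ p.C + seq[:, t, :] * p.D)
        out = concat([y.reshape(b, 1, c) for y in ys], axis=1)
        return out

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        row = x.transpose(0, 2, 3, 1).reshape(b, h * w, c)  # row-major
        col = x.transpose(0, 3, 2, 1).reshape(b, h * w, c)  # column-major
        outs = []
        for i, seq in enumerate([row, row, col, col]):
            if i % 2 == 1:  # reversed direction
                seq = seq[:, ::-1, :]
            y = self._scan(seq, self.dirs[i])
            if i % 2 == 1:
                y = y[:, ::-1, :]
            if i < 2:
                y = y.reshape(b, h, w, c).transpose(0, 3, 1, 2)
            else:
                y = y.reshape(b, w, h, c).transpose(0, 3, 2, 1)
            outs.append(y)
        return outs[0] + outs[1] + outs[2] + outs[3]


def ss2d_scan(x: np.ndarray, ss2d: SS2D) -> np.ndarray:
    """Functional wrapper: numpy [B, C, H, W] in / out."""
    return ss2d(Tensor(np.asarray(x, dtype=float))).data


# ---------------------------------------------------------------------------
# GLICM

class GLICM(nn.Module):
    """Global-local information capture: conv branch + SS2D branch, summed,
    then sequential axial (H, W) and channel attention.  Channel-preserving."""

    def __init__(self, channels: int, rng, state_dim: int = 8):
        super().__init__()
        self.local = nn.Conv2d(channels, channels, 3, rng)
        self.ss2d = SS2D(channels, state_dim, rng)
        # axial attentions: pooled profile -> sigmoid gate per position
        self.h_fc = nn.Linear(channels, channels, rng)
        self.w_fc = nn.Linear(channels, channels, rng)
        self.c_fc1 = nn.Linear(channels, max(channels // 4, 1), rng)
        self.c_fc2 = nn.Linear(max(channels // 4, 1), channels, rng)

    def forward(self, x: Tensor, attention_override: float | None = None
                ) -> Tensor:
        y = self.local(x) + self.ss2d(x)
        if attention_override is not None:
            return y * attention_override
        # H-axis: pool over W -> [B, H, C] -> gate per (h, c)
        hprof = y.mean(axis=3).transpose(0, 2, 1)  # [B, H, C]
        hgate = self.h_fc(hprof).sigmoid().transpose(0, 2, 1)  # [B, C, H]
        y = y * hgate.reshape(*hgate.shape, 1)
        # W-axis: pool over H
        wprof = y.mean(axis=2).transpose(0, 2, 1)  # [B, W, C]
        wgate = self.w_fc(wprof).sigmoid().transpose(0, 2, 1)  # [B, C, W]
        y = y * wgate.reshape(wgate.shape[0], wgate.shape[1], 1, wgate.shape[2])
        # channel attention (squeeze-excite)
        cprof = y.mean(axis=(2, 3))  # [B, C]
        cgate = self.c_fc2(self.c_fc1(cprof).relu()).sigmoid()
        return y * cgate.reshape(*cgate.shape, 1, 1)


def glicm_forward(x: np.ndarray, block: GLICM,
                  attention_override: float | None = None) -> np.ndarray:
    return block(Tensor(np.asarray(x, dtype=float)),
                 attention_override=attention_override).data


# ---------------------------------------------------------------------------
# FMA

class FMA(nn.Module):
    """Fourier-modulated attention over the spatial dimensions."""

    def __init__(self, channels: int, height: int, width: int):
        super().__init__()
        self.filter_re = Tensor(np.ones((channels, height, width)),
                                requires_grad=True)
        self.filter_im = Tensor(np.zeros((channels, height, width)),
                                requires_grad=True)
        self.gate_logit = Tensor(np.zeros(channels), requires_grad=True)
        Ch, Sh = dft_matrices(height)
        Cw, Sw = dft_matrices(width)
        Chi, Shi = idft_matrices(height)
        Cwi, Swi = idft_matrices(width)
        self._f = (Tensor(Ch), Tensor(Sh), Tensor(Cw), Tensor(Sw))
        self._i = (Tensor(Chi), Tensor(Shi), Tensor(Cwi), Tensor(Swi))

    def spectral(self, x: Tensor) -> Tensor:
        """inverse-DFT( filter * DFT2(x) ), real part."""
        Ch, Sh, Cw, Sw = self._f
        Chi, Shi, Cwi, Swi = self._i
        # DFT along W (last axis), x real
        xr = x @ Cw
        xi = x @ Sw
        # DFT along H: operate on axis 2 via transpose
        xr_t, xi_t = xr.transpose(0, 1, 3, 2), xi.transpose(0, 1, 3, 2)
        Xr = (xr_t @ Ch - xi_t @ Sh).transpose(0, 1, 3, 2)
        Xi = (xr_t @ Sh + xi_t @ Ch).transpose(0, 1, 3, 2)
        # learnable complex filter, per channel and spatial frequency
        Yr = Xr * self.filter_re - Xi * self.filter_im
        Yi = Xr * self.filter_im + Xi * self.filter_re
        # inverse along H
        yr_t, yi_t = Yr.transpose(0, 1, 3, 2), Yi.transpose(0, 1, 3, 2)
        Zr = (yr_t @ Chi - yi_t @ Shi).transpose(0, 1, 3, 2)
        Zi = (yr_t @ Shi + yi_t @ Chi).transpose(0, 1, 3, 2)
        # inverse along W, keep the real part
        return Zr @ Cwi - Zi @ Swi

    def forward(self, x: Tensor, gate_override: float | None = None) -> Tensor:
        filt = self.spectral(x)
        if gate_override is not None:
            g = gate_override
            return filt * g + x * (1.0 - g)
        g = self.gate_logit.sigmoid().reshape(1, -1, 1, 1)
        return filt * g + x * (1.0 - g)

    def identity_config(self):
        self.filter_re.data[:] = 1.0
        self.filter_im.data[:] = 0.0
        return self


def fma_modulate(x: np.ndarray, block: FMA,
                 gate_override: float | None = None) -> np.ndarray:
    return block(Tensor(np.asarray(x, dtype=float)),
                 gate_override=gate_override).data


# ---------------------------------------------------------------------------
# F-SPPF

class FSPPF(nn.Module):
    """SPPF with Fourier-modulated attention before the output projection.

    Channel path: C_in --1x1--> C_mid --3 max-pools + concat--> 4*C_mid
    --FMA--> 4*C_mid --1x1--> C_out.  Spatial dims preserved.
    """

    def __init__(self, c_in: int, c_out: int, height: int, width: int, rng,
                 c_mid: int | None = None, pool_kernel: int = 5):
        super().__init__()
        c_mid = c_mid or max(c_in // 2, 1)
        self.conv_in = nn.Conv2d(c_in, c_mid, 1, rng)
        self.pool_kernel = pool_kernel
        self.fma = FMA(4 * c_mid, height, width)
        self.conv_out = nn.Conv2d(4 * c_mid, c_out, 1, rng)

    def forward(self, x: Tensor, fma_identity: bool = False) -> Tensor:
        y = self.conv_in(x)
        p = (self.pool_kernel - 1) // 2
        p1 = max_pool2d(y, self.pool_kernel, p)
        p2 = max_pool2d(p1, self.pool_kernel, p)
        p3 = max_pool2d(p2, self.pool_kernel, p)
        cat = concat([y, p1, p2, p3], axis=1)
        if fma_identity:
            mod = self.fma(cat, gate_override=0.0)  # pass input through
        else:
            mod = self.fma(cat)
        return self.conv_out(mod)


def fsppf_forward(x: np.ndarray, block: FSPPF,
                  fma_identity: bool = False) -> np.ndarray:
    return block(Tensor(np.asarray(x, dtype=float)),
                 fma_identity=fma_identity).data


# ---------------------------------------------------------------------------
# IAFM sub-operators

class ConvAttn(nn.Module):
    """Convolutional attention: a depthwise large-kernel conv produces a
    modulation map multiplied onto a pointwise-projected input."""

    def __init__(self, channels: int, rng, kernel: int = 7):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(channels, kernel, rng)
        self.pw = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor, modulation_override: float | None = None
                ) -> Tensor:
        proj = self.pw(x)
        if modulation_override is not None:
            return proj * modulation_override
        return proj * self.dw(x)


class SHSA(nn.Module):
    """Single-head self-attention over spatial tokens with reduced
    query/key width (default half the channels)."""

    def __init__(self, channels: int, rng, reduction: int = 2):
        super().__init__()
        qk = max(channels // reduction, 1)
        self.q = nn.Linear(channels, qk, rng)
        self.k = nn.Linear(channels, qk, rng)
        self.v = nn.Linear(channels, channels, rng)
        self.scale = 1.0 / np.sqrt(qk)

    def forward(self, x: Tensor, uniform_attention: bool = False,
                identity_value: bool = False) -> Tensor:
        b, c, h, w = x.shape
        tok = x.transpose(0, 2, 3, 1).reshape(b, h * w, c)
        v = tok if identity_value else self.v(tok)
        if uniform_attention:
            out = v.mean(axis=1, keepdims=True) * Tensor(np.ones((1, h * w, 1)))
        else:
            q, k = self.q(tok), self.k(tok)
            att = softmax(q @ k.transpose(0, 2, 1) * self.scale, axis=-1)
            out = att @ v
        return out.reshape(b, h, w, c).transpose(0, 3, 1, 2)


def channel_shuffle(x, groups: int):
    """Group-transpose channel permutation (a bijection on channels)."""
    if isinstance(x, Tensor):
        b, c, h, w = x.shape
        if c % groups:
            raise ValueError("channels must divide evenly into groups")
        return (x.reshape(b, groups, c // groups, h, w)
                .transpose(0, 2, 1, 3, 4).reshape(b, c, h, w))
    x = np.asarray(x)
    b, c, h, w = x.shape
    if c % groups:
        raise ValueError("channels must divide evenly into groups")
    return (x.reshape(b, groups, c // groups, h, w)
            .transpose(0, 2, 1, 3, 4).reshape(b, c, h, w))


def convattn(x: np.ndarray, block: ConvAttn,
             modulation_override: float | None = None) -> np.ndarray:
    return block(Tensor(np.asarray(x, dtype=float)),
                 modulation_override=modulation_override).data


def shsa(x: np.ndarray, block: SHSA, **kw) -> np.ndarray:
    return block(Tensor(np.asarray(x, dtype=float)), **kw).data


# ---------------------------------------------------------------------------
# IAFM

class IAFM(nn.Module):
    """Interactive attention fusion of two same-resolution feature maps.

    With inputs of C channels each: x1', x2' (C each), x~ (C, from the
    shuffled concat through SHSA and a 2C->C conv), x* = x1' * x2' (C);
    their concat xc has 4C channels, and the output stack maps 4C -> C_out.
    """

    def __init__(self, channels: int, c_out: int, rng,
                 convattn_kernel: int = 7, tie_convattn: bool = False):
        super().__init__()
        self.attn1 = ConvAttn(channels, rng, kernel=convattn_kernel)
        self.attn2 = (self.attn1 if tie_convattn
                      else ConvAttn(channels, rng, kernel=convattn_kernel))
        self.shsa = SHSA(2 * channels, rng)
        self.conv_tilde = nn.Conv2d(2 * channels, channels, 1, rng)
        cc = 4 * channels
        self.conv_a = nn.Conv2d(cc, cc, 1, rng)
        self.bn_a = nn.BatchNorm2d(cc)
        self.dw = nn.DepthwiseConv2d(cc, 3, rng)
        self.pw = nn.Conv2d(cc, c_out, 1, rng)
        self.bn_b = nn.BatchNorm2d(c_out)
        self.conv_b = nn.Conv2d(c_out, c_out, 1, rng)

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape[0] != x2.shape[0] or x1.shape[2:] != x2.shape[2:]:
            raise ValueError("IAFM inputs must share batch and spatial dims "
                             "(no implicit resize)")
        x1p = self.attn1(x1)
        x2p = self.attn2(x2)
        mixed = channel_shuffle(concat([x1p, x2p], axis=1), groups=2)
        x_tilde = self.conv_tilde(self.shsa(mixed))
        x_star = x1p * x2p
        xc = concat([x1p, x2p, x_tilde, x_star], axis=1)
        # output stack, innermost first: GELU -> BN -> conv -> DW -> PW
        # -> GELU -> BN -> conv
        y = self.conv_a(self.bn_a(xc.gelu()))
        y = self.pw(self.dw(y))
        return self.conv_b(self.bn_b(y.gelu()))

    def parts(self, x1: Tensor, x2: Tensor):
        """Expose (x1', x2', x~, x*, xc) for contract checks."""
        x1p = self.attn1(x1)
        x2p = self.attn2(x2)
        mixed = channel_shuffle(concat([x1p, x2p], axis=1), groups=2)
        x_tilde = self.conv_tilde(self.shsa(mixed))
        x_star = x1p * x2p
        xc = concat([x1p, x2p, x_tilde, x_star], axis=1)
        return x1p, x2p, x_tilde, x_star, xc


def iafm_fuse(x1: np.ndarray, x2: np.ndarray, block: IAFM) -> np.ndarray:
    return block(Tensor(np.asarray(x1, dtype=float)),
                 Tensor(np.asarray(x2, dtype=float))).data


def zero_biases(module: nn.Module):
    """Zero every bias-like parameter (for zero-input trace checks)."""
    for m in module.modules():
        for name in ("bias", "beta"):
            p = getattr(m, name, None)
            if isinstance(p, Tensor):
                p.data[:] = 0.0
    return module
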