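"""APYieldNet: temporal regression network for county-scale apple yield.

Pipeline (per sample):

1. RevIN — reversible per-sample, per-channel instance normalization over the
   7-month axis, with a learnable affine, to absorb non-stationary level
   shifts between counties and years.
2. Per-group TCN — the 18 temporal channels are split into spectral (5),
   environmental (11) and vegetation-index (2) groups, each modeled by its
   own stack of causal dilated 1-D convolutions with residual connections.
3. ASB — adaptive spectral block: DFT along time, learnable complex
   per-frequency weights, a learned boost on the dominant high-frequency
   bins, inverse DFT, plus a learnable residual mix with the input.
4. GIFM — grouped interaction fusion: per-group gated convolution (GLU) and
   single-head self-attention over time, channel-attention pooling of each
   group to a single token, cross-group token exchange by addition, and
   sigmoid-gated fusion of the three groups.
5. Multi-scale 1-D CNN — parallel convolutions (kernels 3/5/7), global
   average pooling, softmax-weighted branch combination.
6. Regression head — pooled vector concatenated with learned county/year
   embeddings and the z-scored planting area, through an MLP to one scalar
   (kg/mu after label de-scaling).

Eval mode is exactly deterministic on CPU; all initialization randomness is
routed through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concat, dft_matrices, idft_matrices, softmax
from .features import GROUP_SLICES, N_CHANNELS, N_MONTHS, FeatureSequenceRecord
from .nn import EPS

GROUP_NAMES = ("spectral", "environmental", "vegetation")


@dataclass
class APYieldNetConfig:
    seq_len: int = N_MONTHS
    tcn_hidden: int = 32
    tcn_kernel: int = 3
    tcn_dilations: tuple = (1, 2)  # receptive field 1+2*(1+2)=7 = seq_len
    asb_top_k: int = 2
    attention_heads: int = 1  # single-head attention throughout
    multiscale_kernels: tuple = (3, 5, 7)
    embed_dim: int = 8
    head_hidden: tuple = (64,)
    dropout: float = 0.0  # training sets here are tens of samples
    n_counties: int = 64  # embedding-table capacities
    n_years: int = 100  # year code = calendar year mod 100
    seed: int = 0

    def validate(self):
        if any(k % 2 == 0 for k in self.multiscale_kernels):
            raise ValueError("multi-scale kernels must be odd")
        if self.seq_len < 2:
            raise ValueError("seq_len must be >= 2")


# ---------------------------------------------------------------------------
# RevIN: functional form (numpy) + learnable layer

@dataclass
class RevInState:
    mean: np.ndarray  # per-channel mean over time
    std: np.ndarray  # per-channel std over time, epsilon-floored


def revin_normalize(x: np.ndarray) -> tuple[np.ndarray, RevInState]:
    """Per-channel standardization of a [T x C] block over the time axis."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a [T x C] block with T >= 2")
    mean = x.mean(axis=0)
    std = np.maximum(x.std(axis=0), EPS)
    return (x - mean) / std, RevInState(mean=mean, std=std)


def revin_denormalize(xn: np.ndarray, state: RevInState) -> np.ndarray:
    return xn * state.std + state.mean


class RevIN(nn.Module):
    """Instance normalization over time with learnable per-channel affine.

    The output of the network is a scalar, not a series, so there is no
    series to denormalize; instead the removed statistics (per-channel mean
    and std) are returned so the regression head can condition on the level
    and scale information that normalization strips away — the scalar-head
    analogue of RevIN's reversibility.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.gain = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:  # [B, T, C]
        mu = x.mean(axis=1, keepdims=True)
        sd = (((x - mu) ** 2).mean(axis=1, keepdims=True)).sqrt().clip_min(EPS)
        return (x - mu) / sd * self.gain + self.bias, mu, sd


# ---------------------------------------------------------------------------
# per-group temporal convolutional network

class TCNBlock(nn.Module):
    """Causal dilated residual block: conv-relu-conv-relu + skip."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng):
        super().__init__()
        self.conv1 = nn.Conv1d(c_in, c_out, kernel, rng, dilation=dilation,
                               causal=True)
        self.conv2 = nn.Conv1d(c_out, c_out, kernel, rng, dilation=dilation,
                               causal=True)
        self.skip = (nn.Conv1d(c_in, c_out, 1, rng, causal=True)
                     if c_in != c_out else None)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).relu()).relu()
        res = self.skip(x) if self.skip is not None else x
        return y + res


class TCN(nn.Module):
    def __init__(self, c_in: int, hidden: int, kernel: int, dilations, rng):
        super().__init__()
        blocks, c = [], c_in
        for d in dilations:
            blocks.append(TCNBlock(c, hidden, kernel, d, rng))
            c = hidden
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


# ---------------------------------------------------------------------------
# adaptive spectral block

class ASB(nn.Module):
    """DFT-domain reweighting of [B, T, H] with high-frequency boosting.

    With unit weights, k = 0 and zero residual coefficient the block is the
    identity (DFT round trip).  The k largest-amplitude bins of the upper
    half of the spectrum receive a learned multiplicative boost (1 + s);
    their selection follows the data and is treated as a constant mask in
    the backward pass.
    """

    def __init__(self, seq_len: int, channels: int, top_k: int = 2):
        super().__init__()
        self.seq_len = seq_len
        self.top_k = top_k
        self.w_re = Tensor(np.ones((seq_len, channels)), requires_grad=True)
        self.w_im = Tensor(np.zeros((seq_len, channels)), requires_grad=True)
        self.boost = Tensor(np.zeros(()), requires_grad=True)
        self.res_coeff = Tensor(np.zeros(()), requires_grad=True)
        C, S = dft_matrices(seq_len)
        Ci, Si = idft_matrices(seq_len)
        self._C, self._S, self._Ci, self._Si = (Tensor(C), Tensor(S),
                                                Tensor(Ci), Tensor(Si))

    def forward(self, x: Tensor) -> Tensor:  # [B, T, H]
        xt = x.transpose(0, 2, 1)  # [B, H, T]
        Xr = xt @ self._C
        Xi = xt @ self._S
        # learnable complex weights per bin per channel
        wr, wi = self.w_re.transpose(1, 0), self.w_im.transpose(1, 0)  # [H, T]
        Yr = Xr * wr - Xi * wi
        Yi = Xr * wi + Xi * wr
        if self.top_k > 0:
            amp = np.sqrt(Yr.data ** 2 + Yi.data ** 2)  # constant for grads
            T = self.seq_len
            upper = np.arange(T) >= (T + 1) // 2  # upper half of the spectrum
            masked = np.where(upper, amp, -np.inf)
            k = min(self.top_k, int(upper.sum()))
            thresh = np.sort(masked, axis=-1)[..., -k][..., None]
            sel = Tensor((masked >= thresh) & upper)
            gain = sel * self.boost + 1.0
            Yr, Yi = Yr * gain, Yi * gain
        yt = Yr @ self._Ci - Yi @ self._Si  # real part of inverse DFT
        return yt.transpose(0, 2, 1) + x * self.res_coeff

    def identity_config(self):
        """Force the exact-identity configuration (for contract checks)."""
        self.w_re.data[:] = 1.0
        self.w_im.data[:] = 0.0
        self.boost.data = np.zeros(())
        self.res_coeff.data = np.zeros(())
        self.top_k = 0
        return self


# ---------------------------------------------------------------------------
# grouped interaction fusion module

class GateConv(nn.Module):
    """GLU-style gated convolution: conv(x) * sigmoid(conv_gate(x))."""

    def __init__(self, channels: int, kernel: int, rng):
        super().__init__()
        self.conv = nn.Conv1d(channels, channels, kernel, rng)
        self.gate = nn.Conv1d(channels, channels, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x) * self.gate(x).sigmoid()


class AttBlock(nn.Module):
    """Single-head scaled dot-product self-attention over time tokens."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.q = nn.Linear(channels, channels, rng)
        self.k = nn.Linear(channels, channels, rng)
        self.v = nn.Linear(channels, channels, rng)
        self.scale = 1.0 / np.sqrt(channels)

    def forward(self, x: Tensor) -> Tensor:  # [B, T, H]
        q, k, v = self.q(x), self.k(x), self.v(x)
        att = softmax(q @ k.transpose(0, 2, 1) * self.scale, axis=-1)
        return att @ v + x


class ChannelAttnPool(nn.Module):
    """Compress [B, T, H] to one scalar token per sample: a learned query
    attends over the H channels of the time-pooled representation."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.query = Tensor(nn._kaiming(rng, channels, (channels,)),
                            requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:  # -> [B, 1]
        key = x.mean(axis=1)  # [B, H]
        attn = softmax(key * self.query, axis=-1)
        return (attn * key).sum(axis=-1, keepdims=True)


class GIFM(nn.Module):
    """Grouped interaction fusion of the three channel-group encodings."""

    def __init__(self, channels: int, kernel: int, rng):
        super().__init__()
        self.gateconvs = [GateConv(channels, kernel, rng) for _ in range(3)]
        self.attblocks = [AttBlock(channels, rng) for _ in range(3)]
        self.pools = [ChannelAttnPool(channels, rng) for _ in range(3)]
        self.gate_fc = nn.Linear(3, 3, rng)

    def forward(self, f_spec: Tensor, f_env: Tensor, f_veg: Tensor,
                gate_override=None) -> Tensor:
        groups = [f_spec, f_env, f_veg]
        if not (f_spec.shape[1] == f_env.shape[1] == f_veg.shape[1]):
            raise ValueError("groups must share the time dimension")
        enh = [att(gc(g)) for g, gc, att in
               zip(groups, self.gateconvs, self.attblocks)]
        tokens = [pool(e) for pool, e in zip(self.pools, enh)]  # [B,1] each
        # each group's pooled token is added back to its own features
        enh = [e + t.reshape(-1, 1, 1) for e, t in zip(enh, tokens)]
        if gate_override is not None:
            gates = Tensor(np.asarray(gate_override, dtype=float))
            gated = [e * gates[i] for i, e in enumerate(enh)]
        else:
            summary = concat([t for t in tokens], axis=-1)  # [B, 3]
            gates = self.gate_fc(summary).sigmoid()  # [B, 3]
            gated = [e * gates[:, i:i + 1].reshape(-1, 1, 1)
                     for i, e in enumerate(enh)]
        return gated[0] + gated[1] + gated[2]


# ---------------------------------------------------------------------------
# multi-scale 1-D CNN

class MultiScaleCNN(nn.Module):
    """Parallel same-padded convolutions + GAP, softmax-weighted over
    learnable branch logits (equal logits = arithmetic branch mean)."""

    def __init__(self, channels: int, kernels, rng):
        super().__init__()
        # edge padding keeps the response to a constant series constant
        self.branches = [nn.Conv1d(channels, channels, k, rng, pad_mode="edge")
                         for k in kernels]
        self.logits = Tensor(np.zeros(len(kernels)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:  # [B, T, H] -> [B, H]
        pooled = [b(x).mean(axis=1) for b in self.branches]  # [B, H] each
        weights = softmax(self.logits, axis=-1)
        out = None
        for i, p in enumerate(pooled):
            term = p * weights[i]
            out = term if out is None else out + term
        return out


# ---------------------------------------------------------------------------
# full model

@dataclass
class DataScaler:
    """Training-set statistics used to z-score labels, planting area and
    the RevIN per-channel statistics fed to the regression head."""

    y_mean: float = 0.0
    y_std: float = 1.0
    area_mean: float = 0.0
    area_std: float = 1.0
    stat_mean: np.ndarray = field(
        default_factory=lambda: np.zeros(2 * N_CHANNELS))
    stat_std: np.ndarray = field(
        default_factory=lambda: np.ones(2 * N_CHANNELS))

    @staticmethod
    def channel_stats(temporal: np.ndarray) -> np.ndarray:
        """Per-channel [mean, std] over time for a [B, T, C] batch."""
        mu = temporal.mean(axis=1)
        sd = temporal.std(axis=1)
        return np.concatenate([mu, sd], axis=-1)  # [B, 2C]

    @classmethod
    def fit(cls, records) -> "DataScaler":
        ys = np.array([r.yield_label for r in records], dtype=float)
        areas = np.array([r.planting_area for r in records], dtype=float)
        stats = cls.channel_stats(np.stack([r.temporal for r in records]))
        return cls(y_mean=float(ys.mean()), y_std=float(max(ys.std(), EPS)),
                   area_mean=float(areas.mean()),
                   area_std=float(max(areas.std(), EPS)),
                   stat_mean=stats.mean(axis=0),
                   stat_std=np.maximum(stats.std(axis=0), EPS))


class APYieldNet(nn.Module):
    def __init__(self, cfg: APYieldNetConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or APYieldNetConfig()
        cfg.validate()
        rng = nn.seeded_rng(cfg.seed)
        H = cfg.tcn_hidden
        self.revin = RevIN(N_CHANNELS)
        self.tcns = {name: TCN(GROUP_SLICES[name].stop - GROUP_SLICES[name].start,
                               H, cfg.tcn_kernel, cfg.tcn_dilations, rng)
                     for name in GROUP_NAMES}
        self.asbs = {name: ASB(cfg.seq_len, H, cfg.asb_top_k)
                     for name in GROUP_NAMES}
        self.gifm = GIFM(H, 3, rng)
        self.mscnn = MultiScaleCNN(H, cfg.multiscale_kernels, rng)
        self.county_emb = nn.Embedding(cfg.n_counties, cfg.embed_dim)
        self.year_emb = nn.Embedding(cfg.n_years, cfg.embed_dim)
        self.dropout = nn.Dropout(cfg.dropout, rng)
        dims = [H + 2 * N_CHANNELS + 2 * cfg.embed_dim + 1, *cfg.head_hidden, 1]
        self.head = [nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        # linear bypass: a purely linear yield response stays easy to reach
        self.head_linear = nn.Linear(dims[0], 1, rng)
        self.scaler = DataScaler()

    # -- forward ---------------------------------------------------------
    def forward(self, temporal: np.ndarray, county_code: np.ndarray,
                year_code: np.ndarray, area: np.ndarray) -> Tensor:
        """temporal [B, T, C]; returns z-scored yield predictions [B]."""
        temporal = np.asarray(temporal, dtype=float)
        x, _, _ = self.revin(Tensor(temporal))
        feats = []
        for name in GROUP_NAMES:
            sl = GROUP_SLICES[name]
            g = x[:, :, sl]
            g = self.tcns[name](g)
            g = self.asbs[name](g)
            feats.append(g)
        fused = self.gifm(*feats)
        pooled = self.mscnn(fused)  # [B, H]
        pooled = self.dropout(pooled)
        sc = self.scaler
        area_z = (np.asarray(area, dtype=float) - sc.area_mean) / sc.area_std
        stats = DataScaler.channel_stats(temporal)
        stats_z = (stats - sc.stat_mean) / sc.stat_std
        h = concat([pooled,
                    Tensor(stats_z),  # RevIN statistics, re-injected
                    self.county_emb(county_code),
                    self.year_emb(year_code),
                    Tensor(area_z.reshape(-1, 1))], axis=-1)
        z = h
        for layer in self.head[:-1]:
            z = layer(z).relu()
        return (self.head[-1](z) + self.head_linear(h)).reshape(-1)

    # -- record-level API -------------------------------------------------
    @staticmethod
    def batch_from_records(records):
        temporal = np.stack([r.temporal for r in records])
        county = np.array([r.county for r in records], dtype=np.int64)
        year = np.array([r.year for r in records], dtype=np.int64)
        area = np.array([r.planting_area for r in records], dtype=float)
        labels = np.array([np.nan if r.yield_label is None else r.yield_label
                           for r in records], dtype=float)
        return temporal, county, year % 100, area, labels

    def predict_records(self, records) -> np.ndarray:
        """Deterministic kg/mu predictions (eval mode)."""
        was_training = self.training
        self.eval()
        t, c, y, a, _ = self.batch_from_records(records)
        out = self.forward(t, c, y, a).data
        if was_training:
            self.train()
        return out * self.scaler.y_std + self.scaler.y_mean


# ---------------------------------------------------------------------------
# operation-level wrappers (single [T x C] blocks, numpy in / numpy out)

def tcn_encode(group_block: np.ndarray, tcn: TCN) -> np.ndarray:
    out = tcn(Tensor(np.asarray(group_block, dtype=float)[None]))
    return out.data[0]


def asb_transform(block: np.ndarray, asb: ASB) -> np.ndarray:
    return asb(Tensor(np.asarray(block, dtype=float)[None])).data[0]


def gifm_fuse(f_spec: np.ndarray, f_env: np.ndarray, f_veg: np.ndarray,
              gifm: GIFM, gate_override=None) -> np.ndarray:
    out = gifm(Tensor(f_spec[None]), Tensor(f_env[None]), Tensor(f_veg[None]),
               gate_override=gate_override)
    return out.data[0]


def multiscale_cnn(fused: np.ndarray, ms: MultiScaleCNN) -> np.ndarray:
    return ms(Tensor(np.asarray(fused, dtype=float)[None])).data[0]


def apyieldnet_forward(record: FeatureSequenceRecord,
                       model: APYieldNet) -> float:
    """Predicted yield in kg/mu for one record (deterministic)."""
    return float(model.predict_records([record])[0])
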