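"""The residual large-kernel U-Net with attention-filtered skip connections.

Architecture overview
---------------------
Encoder: four stages of residual large-kernel (RLK) blocks — a 13×13
"same"-padded convolution followed by group normalization, GELU and a 1×1
projection, wrapped in a residual connection with stochastic depth
(droppath).  Downsampling between stages uses stride-2 3×3 convolutions, so
input H and W must be divisible by 8.

Skip connections: each of the three encoder skips is refined by CBAM
(sequential channel and spatial attention) and then by an additive attention
gate conditioned on the coarser decoder feature before being concatenated
into the decoder.  CBAM can be switched off per skip for ablations.

Decoder: bilinear ×2 upsampling + 3×3 convolution, fusion with the gated
skip, and a refinement block.  Deep supervision: 1×1 heads produce a
full-resolution logit map plus three auxiliary maps at 1/2, 1/4 and 1/8
resolution (the last from the bottleneck), ordered final → deepest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn.layers import Conv2d, GroupNorm, Module, Param, gelu_with_deriv, sigmoid
from .nn.ops import upsample2, upsample2_backward


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the segmentation network.

    ``stage_channels`` are the widths of the four encoder stages;
    ``rlk_kernel`` is the (odd) large-kernel size, 13 by default so the
    receptive field covers a microbleed and its surrounding context;
    ``cbam_enabled_skips`` selects which of the three skip connections carry
    CBAM (1 = highest resolution), enabling the ablation configurations.
    """

    in_channels: int = 3
    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    rlk_kernel: int = 13
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    groupnorm_groups: Optional[int] = None  # None -> min(8, channels)
    droppath_rates: tuple[float, float, float, float] = (0.0, 0.0333, 0.0667, 0.1)
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    cbam_enabled_skips: frozenset[int] = frozenset({1, 2, 3})
    attention_gates: bool = True
    n_outputs: int = 4

    def __post_init__(self) -> None:
        if self.rlk_kernel % 2 == 0 or self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if len(self.stage_channels) != 4 or len(self.blocks_per_stage) != 4:
            raise ValueError("exactly four encoder stages are required")
        if list(self.droppath_rates) != sorted(self.droppath_rates):
            raise ValueError("droppath_rates must be non-decreasing")
        if not set(self.cbam_enabled_skips) <= {1, 2, 3}:
            raise ValueError("cbam_enabled_skips must be a subset of {1, 2, 3}")

    def gn_groups(self, channels: int) -> int:
        g = self.groupnorm_groups if self.groupnorm_groups is not None else min(8, channels)
        while channels % g != 0:
            g -= 1
        return g


# Desk-scale preset: stochastic depth is regularization for long trainings
# and only adds gradient noise in short desk-scale runs, so it is off here.
TINY = NetworkConfig(
    stage_channels=(8, 16, 32, 32),
    blocks_per_stage=(1, 1, 1, 1),
    droppath_rates=(0.0, 0.0, 0.0, 0.0),
)


class RLKBlock(Module):
    """x + droppath(conv_k → GN → GELU → conv_1x1)."""

    def __init__(self, ch: int, cfg: NetworkConfig, rate: float, rng: np.random.Generator, name: str):
        self.conv = Conv2d(ch, ch, cfg.rlk_kernel, rng, name=f"{name}.lk")
        self.norm = GroupNorm(ch, cfg.gn_groups(ch), name=f"{name}.gn")
        self.pw = Conv2d(ch, ch, 1, rng, name=f"{name}.pw")
        self.rate = rate
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if train and self.rate >= 1.0:
            self._cache = ("dropped", None, None)
            return x
        a = self.conv.forward(x)
        n = self.norm.forward(a)
        g, dgelu = gelu_with_deriv(n)
        br = self.pw.forward(g)
        if train and self.rate > 0.0:
            keep = (rng.random(size=(x.shape[0], 1, 1, 1)) >= self.rate).astype(np.float32)
            scale = keep / (1.0 - self.rate)
            self._cache = ("train", dgelu, scale)
            return x + br * scale
        self._cache = ("eval", dgelu, None)
        return x + br

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mode, dgelu, scale = self._cache
        if mode == "dropped":
            return dy
        dbr = dy * scale if scale is not None else dy
        dg = self.pw.backward(dbr)
        dn = dg * dgelu
        da = self.norm.backward(dn)
        dx = self.conv.backward(da)
        return dy + dx


class ConvNormAct(Module):
    """conv → GN → GELU, the standard stem/downsample/decoder unit."""

    def __init__(self, cin: int, cout: int, k: int, cfg: NetworkConfig,
                 rng: np.random.Generator, stride: int = 1, name: str = "cna"):
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, name=name)
        self.norm = GroupNorm(cout, cfg.gn_groups(cout), name=f"{name}.gn")
        self._dgelu = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = self.norm.forward(self.conv.forward(x))
        out, self._dgelu = gelu_with_deriv(n)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.norm.backward(dy * self._dgelu))


class ChannelAttention(Module):
    """CBAM channel attention: sigmoid(MLP(avgpool) + MLP(maxpool)), applied
    multiplicatively per channel.  The two-layer bottleneck perceptron is
    shared between the average- and max-pooled descriptors, so both branches
    accumulate into the same weights on the backward pass."""

    def __init__(self, ch: int, reduction: int, rng: np.random.Generator, name: str):
        hidden = max(1, ch // reduction)
        self.w1 = Param((rng.standard_normal((ch, hidden)) * np.sqrt(2.0 / ch)).astype(np.float32), f"{name}.w1")
        self.b1 = Param(np.zeros(hidden, dtype=np.float32), f"{name}.b1")
        self.w2 = Param((rng.standard_normal((hidden, ch)) * np.sqrt(2.0 / hidden)).astype(np.float32), f"{name}.w2")
        self.b2 = Param(np.zeros(ch, dtype=np.float32), f"{name}.b2")
        self._cache = None

    def _mlp(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = v @ self.w1.value + self.b1.value
        return np.maximum(h, 0.0) @ self.w2.value + self.b2.value, h

    def attention(self, x: np.ndarray) -> np.ndarray:
        """The channel map Mc(F) alone, shape (B, C); values in (0, 1)."""
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        avg = flat.mean(axis=2)
        amax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]
        ya, ha = self._mlp(avg)
        ym, hm = self._mlp(mx)
        mc = sigmoid(ya + ym)
        self._cache = (x, avg, mx, ha, hm, amax, mc)
        return mc

    def forward(self, x: np.ndarray) -> np.ndarray:
        mc = self.attention(x)
        return x * mc[:, :, None, None]

    def _mlp_backward(self, v: np.ndarray, h: np.ndarray, dout: np.ndarray) -> np.ndarray:
        hr = np.maximum(h, 0.0)
        self.w2.grad += hr.T @ dout
        self.b2.grad += dout.sum(axis=0)
        dh = (dout @ self.w2.value.T) * (h > 0)
        self.w1.grad += v.T @ dh
        self.b1.grad += dh.sum(axis=0)
        return dh @ self.w1.value.T

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, avg, mx, ha, hm, amax, mc = self._cache
        B, C, H, W = x.shape
        dmc = (dy * x).sum(axis=(2, 3))
        dx = dy * mc[:, :, None, None]
        ds = dmc * mc * (1.0 - mc)  # through the sigmoid
        davg = self._mlp_backward(avg, ha, ds)
        dx += davg[:, :, None, None].astype(np.float32) / (H * W)
        dmx = self._mlp_backward(mx, hm, ds)
        dflat = np.zeros((B, C, H * W), dtype=np.float32)
        np.put_along_axis(dflat, amax[:, :, None], dmx[:, :, None].astype(np.float32), axis=2)
        dx += dflat.reshape(B, C, H, W)
        return dx


class SpatialAttention(Module):
    """CBAM spatial attention: sigmoid(conv_kxk([avg_c ; max_c])), applied
    multiplicatively per spatial location."""

    def __init__(self, k: int, rng: np.random.Generator, name: str):
        self.conv = Conv2d(2, 1, k, rng, name=f"{name}.conv")
        self._cache = None

    def attention(self, x: np.ndarray) -> np.ndarray:
        """The spatial map Ms(F'), shape (B, 1, H, W); values in (0, 1)."""
        B, C, H, W = x.shape
        avg = x.mean(axis=1, keepdims=True)
        amax = x.argmax(axis=1)
        mx = np.take_along_axis(x, amax[:, None], axis=1)
        cat = np.concatenate([avg, mx], axis=1).astype(np.float32)
        ms = sigmoid(self.conv.forward(cat))
        self._cache = (x, amax, ms)
        return ms

    def forward(self, x: np.ndarray) -> np.ndarray:
        ms = self.attention(x)
        return x * ms

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, amax, ms = self._cache
        B, C, H, W = x.shape
        dms = (dy * x).sum(axis=1, keepdims=True)
        dx = dy * ms
        dcat = self.conv.backward(dms * ms * (1.0 - ms))
        dx += dcat[:, 0:1] / C  # avg branch
        dmx = dcat[:, 1:2]
        scat = np.zeros_like(x)
        np.put_along_axis(scat, amax[:, None], dmx, axis=1)
        dx += scat
        return dx


class CBAM(Module):
    def __init__(self, ch: int, cfg: NetworkConfig, rng: np.random.Generator, name: str):
        self.channel = ChannelAttention(ch, cfg.cbam_reduction, rng, name=f"{name}.ca")
        self.spatial = SpatialAttention(cfg.cbam_spatial_kernel, rng, name=f"{name}.sa")

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.spatial.forward(self.channel.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.channel.backward(self.spatial.backward(dy))


class AttentionGate(Module):
    """Additive attention gate: the skip feature is re-weighted by a spatial
    coefficient computed from 1×1 projections of the skip and the (upsampled)
    coarser gating feature."""

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator, name: str):
        inter = max(1, skip_ch // 2)
        self.theta = Conv2d(skip_ch, inter, 1, rng, bias=False, name=f"{name}.theta")
        self.phi = Conv2d(gate_ch, inter, 1, rng, name=f"{name}.phi")
        self.psi = Conv2d(inter, 1, 1, rng, name=f"{name}.psi")
        self._cache = None

    def forward(self, skip: np.ndarray, gating: np.ndarray) -> np.ndarray:
        if gating.shape[2] * 2 != skip.shape[2] or gating.shape[3] * 2 != skip.shape[3]:
            raise ValueError(
                f"gating spatial dims {gating.shape[2:]} must be half of skip {skip.shape[2:]}"
            )
        gup = upsample2(gating)
        s = self.theta.forward(skip) + self.phi.forward(gup)
        q = np.maximum(s, 0.0)
        alpha = sigmoid(self.psi.forward(q))
        self._cache = (skip, s, q, alpha)
        return skip * alpha

    def coefficients(self) -> np.ndarray:
        """The last computed gate map alpha, shape (B, 1, H, W)."""
        return self._cache[3]

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        skip, s, q, alpha = self._cache
        dalpha = (dy * skip).sum(axis=1, keepdims=True)
        dskip = dy * alpha
        dq = self.psi.backward(dalpha * alpha * (1.0 - alpha))
        ds = dq * (s > 0)
        dskip += self.theta.backward(ds)
        dgup = self.phi.backward(ds)
        return dskip, upsample2_backward(dgup)


class DecoderStage(Module):
    """Upsample the deeper feature, refine the (CBAM + gated) skip, fuse."""

    def __init__(self, deep_ch: int, skip_ch: int, cfg: NetworkConfig,
                 use_cbam: bool, rng: np.random.Generator, name: str):
        self.up = ConvNormAct(deep_ch, skip_ch, 3, cfg, rng, name=f"{name}.up")
        self.cbam = CBAM(skip_ch, cfg, rng, name=f"{name}.cbam") if use_cbam else None
        self.gate = AttentionGate(skip_ch, deep_ch, rng, name=f"{name}.gate") if cfg.attention_gates else None
        self.fuse = ConvNormAct(2 * skip_ch, skip_ch, 3, cfg, rng, name=f"{name}.fuse")
        self._skip_ch = skip_ch
        self.last_activation: np.ndarray | None = None
        self.last_grad: np.ndarray | None = None

    def forward(self, deep: np.ndarray, skip: np.ndarray) -> np.ndarray:
        u = self.up.forward(upsample2(deep))
        s = self.cbam.forward(skip) if self.cbam is not None else skip
        s = self.gate.forward(s, deep) if self.gate is not None else s
        out = self.fuse.forward(np.concatenate([s, u], axis=1))
        self.last_activation = out
        return out

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        self.last_grad = dy
        dcat = self.fuse.backward(dy)
        ds, du = dcat[:, : self._skip_ch], dcat[:, self._skip_ch :]
        ddeep = upsample2_backward(self.up.backward(du))
        if self.gate is not None:
            ds, dg = self.gate.backward(ds)
            ddeep = ddeep + dg
        dskip = self.cbam.backward(ds) if self.cbam is not None else ds
        return ddeep, dskip


class RLKUNet(Module):
    """Four-stage large-kernel encoder/decoder with deep supervision.

    ``forward`` returns four logit maps ordered final → deepest, with spatial
    sizes H, H/2, H/4, H/8 (likewise for W).
    """

    def __init__(self, cfg: NetworkConfig = NetworkConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.stage_channels
        self.stem = ConvNormAct(cfg.in_channels, c[0], 3, cfg, rng, name="stem")
        self.stages: list[list[RLKBlock]] = []
        for i in range(4):
            self.stages.append(
                [RLKBlock(c[i], cfg, cfg.droppath_rates[i], rng, name=f"enc{i+1}.b{j}")
                 for j in range(cfg.blocks_per_stage[i])]
            )
        self.downs = [
            ConvNormAct(c[i], c[i + 1], 3, cfg, rng, stride=2, name=f"down{i+1}")
            for i in range(3)
        ]
        skips = cfg.cbam_enabled_skips
        # decoder stages from deepest (fusing skip 3) to shallowest (skip 1)
        self.dec3 = DecoderStage(c[3], c[2], cfg, 3 in skips, rng, "dec3")
        self.dec2 = DecoderStage(c[2], c[1], cfg, 2 in skips, rng, "dec2")
        self.dec1 = DecoderStage(c[1], c[0], cfg, 1 in skips, rng, "dec1")
        self.head = Conv2d(c[0], 1, 1, rng, name="head")
        self.aux2 = Conv2d(c[1], 1, 1, rng, name="aux2")
        self.aux3 = Conv2d(c[2], 1, 1, rng, name="aux3")
        self.aux4 = Conv2d(c[3], 1, 1, rng, name="aux4")
        # background-prior initialization: lesions occupy a vanishing pixel
        # fraction, so output heads start strongly biased toward background
        for h in (self.head, self.aux2, self.aux3, self.aux4):
            h.b.value[...] = -4.0

    # -- forward / backward ------------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> list[np.ndarray]:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError(f"spatial dims {x.shape[2:]} must be divisible by 8")
        if train and rng is None:
            rng = np.random.default_rng(0)
        h = self.stem.forward(x)
        feats = []
        for i in range(4):
            for blk in self.stages[i]:
                h = blk.forward(h, train, rng)
            feats.append(h)
            if i < 3:
                h = self.downs[i].forward(h)
        e1, e2, e3, e4 = feats
        d3 = self.dec3.forward(e4, e3)
        d2 = self.dec2.forward(d3, e2)
        d1 = self.dec1.forward(d2, e1)
        return [
            self.head.forward(d1),
            self.aux2.forward(d2),
            self.aux3.forward(d3),
            self.aux4.forward(e4),
        ]

    def backward(self, dlogits: Sequence[np.ndarray]) -> None:
        d_final, d_a2, d_a3, d_a4 = dlogits
        dd1 = self.head.backward(d_final)
        dd2, de1 = self.dec1.backward(dd1)
        dd2 = dd2 + self.aux2.backward(d_a2)
        dd3, de2 = self.dec2.backward(dd2)
        dd3 = dd3 + self.aux3.backward(d_a3)
        de4, de3 = self.dec3.backward(dd3)
        de4 = de4 + self.aux4.backward(d_a4)
        # encoder, deepest stage first
        grads = [de1, de2, de3, de4]
        g = None
        for i in range(3, -1, -1):
            g = grads[i] if g is None else grads[i] + self.downs[i].backward(g)
            for blk in reversed(self.stages[i]):
                g = blk.backward(g)
        self.stem.backward(g)

    # -- utilities ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid of the final full-resolution logits, (B, H, W)."""
        logits = self.forward(x, train=False)[0]
        return sigmoid(logits)[:, 0]

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]

    def summary(self) -> str:
        lines = [f"RLKUNet: {self.n_params():,} parameters"]
        for p in self.params():
            lines.append(f"  {p.name:24s} {str(p.value.shape):18s} {p.size:>8,}")
        return "\n".join(lines)
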