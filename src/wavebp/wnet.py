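"""W-Net / U-Net 1D architectures and the composite training loss.

The W-Net is two concatenated 1D U-Net blocks — the first acting as an
encoder, the second as a decoder — followed by a single-channel convolution
with a tanh activation.  Each U-block descends ``levels`` times (Conv1D →
BatchNorm → LeakyReLU pairs, then average pooling by 2), passes a bottleneck,
and ascends with nearest-neighbour upsampling and skip concatenations across
matching levels.  The U-Net variant is a single U-block with the same output
head (the left half of the W).

The training loss combines, per window of scaled ([0, 1]) ABP:
``0.05 * mal + mse + (1 - |r|)`` where ``mal`` is the maximal absolute
pointwise error, ``mse`` the mean squared error, and ``r`` the Pearson
correlation between reference and reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor


class Arch(str, Enum):
    WNET = "WNET"
    UNET = "UNET"


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``window_len`` must be divisible by ``2**levels`` so pooling and
    upsampling return to the original length.  Defaults follow common 1D
    U-Net practice: 4 levels, 32 filters at the top doubling per level,
    kernel size 9, two Conv-BN-LeakyReLU pairs per level; all are
    configurable.  The output activation is tanh and the LeakyReLU negative
    slope is 0.1.
    """

    arch: Arch | str = Arch.WNET
    in_channels: int = 1
    window_len: int = 1024
    levels: int = 4
    base_filters: int = 32
    kernel_size: int = 9
    convs_per_level: int = 2
    leaky_slope: float = 0.1
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.arch = Arch(self.arch)
        if self.window_len % (2 ** self.levels) != 0:
            raise ValueError(
                f"window_len {self.window_len} not divisible by 2^levels = {2**self.levels}"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 (PPG) or 3 (PPG+VPG+APG)")


@dataclass
class LossWeights:
    """Weights of the composite loss terms: maximal absolute error, MSE,
    and the Pearson penalty (1 - |r|)."""

    mal_weight: float = 0.05
    mse_weight: float = 1.0
    corr_weight: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mal_weight, self.mse_weight, self.corr_weight) < 0:
            raise ValueError("loss weights must be non-negative")


class _ConvUnit:
    """Conv1D -> (BatchNorm) -> LeakyReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, slope: float,
                 use_bn: bool, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * k))
        self.w = Tensor(rng.normal(0.0, std, (k, c_in, c_out)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.bn = nn.BatchNorm1d(c_out) if use_bn else None
        self.slope = slope

    def parameters(self) -> list[Tensor]:
        ps = [self.w, self.b]
        if self.bn is not None:
            ps += self.bn.parameters()
        return ps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        x = nn.conv1d(x, self.w, self.b)
        if self.bn is not None:
            x = self.bn(x, training)
        return x.leaky_relu(self.slope)


class _Stage:
    """A stack of conv units at one resolution level."""

    def __init__(self, c_in: int, c_out: int, n: int, k: int, slope: float,
                 use_bn: bool, rng: np.random.Generator):
        self.units = [_ConvUnit(c_in if i == 0 else c_out, c_out, k, slope, use_bn, rng)
                      for i in range(n)]

    def parameters(self) -> list[Tensor]:
        return [p for u in self.units for p in u.parameters()]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        for u in self.units:
            x = u(x, training)
        return x


class _UBlock:
    """One 1D U-Net block: encoder, bottleneck, decoder with skip concatenation."""

    def __init__(self, c_in: int, cfg: ModelConfig, rng: np.random.Generator):
        L, B = cfg.levels, cfg.base_filters
        mk = lambda ci, co: _Stage(ci, co, cfg.convs_per_level, cfg.kernel_size,
                                   cfg.leaky_slope, cfg.batch_norm, rng)
        self.enc = []
        c = c_in
        for lvl in range(L):
            co = B * (2 ** lvl)
            self.enc.append(mk(c, co))
            c = co
        self.bottleneck = mk(c, B * (2 ** L))
        self.dec = []
        c = B * (2 ** L)
        for lvl in reversed(range(L)):
            co = B * (2 ** lvl)
            self.dec.append(mk(c + co, co))  # upsampled + skip channels
            c = co
        self.out_channels = B

    def parameters(self) -> list[Tensor]:
        stages = self.enc + [self.bottleneck] + self.dec
        return [p for s in stages for p in s.parameters()]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        skips = []
        for stage in self.enc:
            x = stage(x, training)
            skips.append(x)
            x = nn.avgpool2(x)
        x = self.bottleneck(x, training)
        for stage, skip in zip(self.dec, reversed(skips)):
            x = nn.upsample2(x)
            x = nn.concat([x, skip], axis=2)
            x = stage(x, training)
        return x


class Model:
    """A W-Net (two U-blocks) or U-Net (one U-block) with a 1-channel tanh head.

    Input: (n_segments, window_len, in_channels) arrays; output:
    (n_segments, window_len, 1) scaled ABP in (-1, 1).
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = [_UBlock(config.in_channels, config, rng)]
        if config.arch is Arch.WNET:
            self.blocks.append(_UBlock(self.blocks[0].out_channels, config, rng))
        k = config.kernel_size
        std = np.sqrt(1.0 / (self.blocks[-1].out_channels * k))
        self.head_w = Tensor(
            rng.normal(0.0, std, (k, self.blocks[-1].out_channels, 1)).astype(np.float32),
            requires_grad=True)
        self.head_b = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        ps = [p for blk in self.blocks for p in blk.parameters()]
        return ps + [self.head_w, self.head_b]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        """x: (n_segments, window_len, in_channels) -> Tensor (n, window_len, 1)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != self.config.in_channels \
                or x.shape[1] != self.config.window_len:
            raise ValueError(
                f"expected (n, {self.config.window_len}, {self.config.in_channels}), "
                f"got {x.shape}")
        t = Tensor(np.ascontiguousarray(x))
        for blk in self.blocks:
            t = blk(t, training)
        t = nn.conv1d(t, self.head_w, self.head_b)
        return t.tanh()

    def predict_array(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Inference (normalization in running-stats mode): (n, window, 1) output."""
        outs = []
        for lo in range(0, len(x), batch_size):
            out = self.forward(x[lo:lo + batch_size], training=False)
            outs.append(out.data)
        return np.concatenate(outs, axis=0) if outs else np.empty((0, self.config.window_len, 1))

    # -- checkpointing -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        i = 0
        for blk in self.blocks:
            for stage in blk.enc + [blk.bottleneck] + blk.dec:
                for u in stage.units:
                    if u.bn is not None:
                        state[f"bn_mean_{i}"] = u.bn.running_mean
                        state[f"bn_var_{i}"] = u.bn.running_var
                        i += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float32)
        i = 0
        for blk in self.blocks:
            for stage in blk.enc + [blk.bottleneck] + blk.dec:
                for u in stage.units:
                    if u.bn is not None:
                        u.bn.running_mean = np.asarray(state[f"bn_mean_{i}"], dtype=np.float32)
                        u.bn.running_var = np.asarray(state[f"bn_var_{i}"], dtype=np.float32)
                        i += 1


def build_model(config: ModelConfig) -> Model:
    """Construct a W-Net or U-Net; identical seed gives identical initial weights."""
    return Model(config)


# ---- loss components (numpy, float64) --------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation in [-1, 1]; 0 when either input has zero
    variance (a constant prediction earns the maximal correlation penalty)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("pearson_r requires equal-length sequences")
    if len(x) < 2:
        raise ValueError("pearson_r requires length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(xc @ yc) / np.sqrt(sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def mal(ref: Sequence[float], rec: Sequence[float]) -> float:
    """Maximal absolute pointwise error."""
    ref = np.asarray(ref, dtype=np.float64)
    rec = np.asarray(rec, dtype=np.float64)
    if ref.shape != rec.shape or ref.size == 0:
        raise ValueError("mal requires equal-length non-empty sequences")
    return float(np.max(np.abs(ref - rec)))


def loss(ref_scaled: Sequence[float], rec_scaled: Sequence[float],
         weights: LossWeights = LossWeights()) -> float:
    """Composite loss on scaled signals:
    ``mal_weight*mal + mse_weight*mse + corr_weight*(1 - |r|)``."""
    ref = np.asarray(ref_scaled, dtype=np.float64).ravel()
    rec = np.asarray(rec_scaled, dtype=np.float64).ravel()
    if ref.shape != rec.shape:
        raise ValueError("loss requires equal-length sequences")
    if len(ref) < 2:
        raise ValueError("loss requires length >= 2")
    m = float(np.mean((ref - rec) ** 2))
    return (weights.mal_weight * mal(ref, rec)
            + weights.mse_weight * m
            + weights.corr_weight * (1.0 - abs(pearson_r(ref, rec))))


def loss_graph(pred: Tensor, target: np.ndarray, weights: LossWeights,
               eps: float = 1e-8) -> Tensor:
    """Differentiable batch loss: per-segment composite loss averaged over the
    batch.  ``pred`` is (n, window, 1); ``target`` likewise.  The correlation
    denominator carries an ``eps`` guard so constant windows are penalized
    (r -> 0) instead of dividing by zero."""
    tgt = Tensor(np.asarray(target, dtype=np.float32))
    diff = pred - tgt
    mse_seg = (diff * diff).mean(axes=(1, 2))
    mal_seg = diff.abs().max(axes=(1, 2))
    pc = pred - pred.mean(axes=(1, 2), keepdims=True)
    tc = tgt.data - tgt.data.mean(axis=(1, 2), keepdims=True)
    tc_t = Tensor(tc)
    num = (pc * tc_t).sum(axes=(1, 2))
    den = ((pc * pc).sum(axes=(1, 2)) * Tensor((tc * tc).sum(axis=(1, 2))) + eps).sqrt()
    r_abs = (num / den).abs()
    per_seg = (mal_seg * weights.mal_weight
               + mse_seg * weights.mse_weight
               + (1.0 - r_abs) * weights.corr_weight)
    return per_seg.mean()
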