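"""Classifier scaffolding for the weakly supervised localization layer.

The head is a small, fully deterministic numpy conv net: conv blocks
(convolution, batch normalization, ReLU, 2x2 max pooling) feeding a
region-pooling layer (global average pool plus the four spatial quadrants)
and a linear class layer whose weights double as the localization weights.
The optimizer is SGD with momentum and weight decay under the piecewise
learning-rate schedule; all of these are exposed as standalone operations so
they can be tested against closed forms.

The backbone is pluggable: anything exposing ``forward``/``backward``/
``parameters`` with the :class:`SmallCNNBackbone` signatures can be swapped
in (an EfficientNet-style network would slot into the same interface; only
the bundled small CNN ships here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import (
    InvalidDatasetError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "FeatureMaps",
    "PooledUnits",
    "ClassWeights",
    "BatchStats",
    "TrainState",
    "TrainConfig",
    "conv_unit",
    "batch_stats",
    "normalize_batch",
    "local_response_norm",
    "global_avg_pool",
    "region_pool",
    "quadrant_slices",
    "momentum_update",
    "lr_schedule",
    "softmax_prob",
    "SmallCNNBackbone",
    "TrainedModel",
    "train_classifier",
]

N_REGIONS = 5  # region 0 = whole map, regions 1..4 = spatial quadrants


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureMaps:
    """Final-layer activations ``f_n(x, y)``: an ``(n, H', W')`` stack."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ShapeError("feature maps must be (n, H, W)")
        if not np.isfinite(self.maps).all():
            raise InvalidParameterError("feature maps must be finite")

    @property
    def n(self) -> int:
        return self.maps.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class PooledUnits:
    """Region-pooled activations: the global unit plus the four quadrants."""

    global_unit: np.ndarray  # (n,)
    region_units: np.ndarray  # (n, 4)
    region_size: int  # N_1, pixels in the global region

    def as_matrix(self) -> np.ndarray:
        """All five units as an ``(n, 5)`` matrix, region 0 = global."""
        return np.concatenate([self.global_unit[:, None], self.region_units], axis=1)


@dataclass
class ClassWeights:
    """Per-class, per-map, per-region linear weights ``w_{n j}^c``.

    ``weights`` has shape ``(n_classes, n_maps, 5)``; region index 0 is the
    whole-map (global average pooling) unit, 1..4 the quadrants in
    (top-left, top-right, bottom-left, bottom-right) order.
    """

    weights: np.ndarray
    classes: tuple = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3 or self.weights.shape[2] != N_REGIONS:
            raise ShapeError("class weights must be (classes, maps, 5)")
        if not np.isfinite(self.weights).all():
            raise InvalidParameterError("class weights must be finite")
        if not self.classes:
            self.classes = tuple(range(self.weights.shape[0]))

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_maps(self) -> int:
        return self.weights.shape[1]

    def class_index(self, c) -> int:
        if c in self.classes:
            return self.classes.index(c)
        if isinstance(c, (int, np.integer)) and 0 <= int(c) < self.n_classes:
            return int(c)
        raise InvalidParameterError(f"unknown class {c!r}; known classes: {self.classes}")


@dataclass
class BatchStats:
    """Mini-batch mean and (biased) variance."""

    mean: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise InvalidParameterError("variance must be non-negative")


@dataclass
class TrainState:
    """SGD-with-momentum state for one parameter tensor."""

    weights: np.ndarray
    velocity: np.ndarray
    learning_rate: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epoch: int = 1
    n: int = 1  # the divisor of the weight-decay term

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.velocity.shape != self.weights.shape:
            raise ShapeError("velocity shape must equal weights shape")
        if not 0 <= self.momentum < 1:
            raise InvalidParameterError("momentum must lie in [0, 1)")
        if not 0 <= self.weight_decay < 1:
            raise InvalidParameterError("weight_decay must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# elementary operations


def conv_unit(window: np.ndarray, filt: np.ndarray, bias: float = 0.0,
              activation: Callable[[float], float] | None = None) -> float:
    """One convolution unit: ``c_i = phi(u . x_{i:i+m-1} + b)``.

    ``window`` is the flattened input slice (the concatenation of ``m``
    d-dimensional steps) and ``filt`` the matching filter vector.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    u = np.asarray(filt, dtype=np.float64).ravel()
    if x.shape != u.shape:
        raise ShapeError(f"window length {x.size} != filter length {u.size}")
    pre = float(u @ x + bias)
    return pre if activation is None else float(activation(pre))


def relu(x):
    return np.maximum(x, 0.0)


def batch_stats(batch) -> BatchStats:
    """Mini-batch mean ``mu = (1/n) sum x_i`` and biased variance."""
    x = np.asarray(batch, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidParameterError("batch must be non-empty")
    mu = float(x.mean())
    var = float(((x - mu) ** 2).mean())
    return BatchStats(mean=mu, variance=var, n=x.size)


def normalize_batch(batch, eps: float = 1e-5) -> np.ndarray:
    """Standardize a batch with its own statistics: ``(x - mu)/sqrt(var + eps)``."""
    x = np.asarray(batch, dtype=np.float64)
    s = batch_stats(x)
    return (x - s.mean) / np.sqrt(s.variance + eps)


def local_response_norm(
    features: FeatureMaps | np.ndarray,
    offset: float = 2.0,
    scale: float = 1e-4,
    exponent: float = 0.75,
    neighborhood: int = 5,
) -> FeatureMaps:
    """Cross-channel response normalization.

    ``Q(x,y,i) = P(x,y,i) * (offset + scale * sum_j P(x,y,j)^2)^(-exponent)``
    with the sum over the ``neighborhood`` channels centered on ``i``
    (clamped at the ends; a neighborhood >= the channel count sums all
    channels).
    """
    fm = features if isinstance(features, FeatureMaps) else FeatureMaps(np.asarray(features))
    p = fm.maps
    n = p.shape[0]
    half = neighborhood // 2
    sq = p**2
    out = np.empty_like(p)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        energy = sq[lo:hi].sum(axis=0)
        out[i] = p[i] * (offset + scale * energy) ** (-exponent)
    return FeatureMaps(out)


def global_avg_pool(features: FeatureMaps | np.ndarray) -> np.ndarray:
    """Spatial mean of each feature map: an ``(n,)`` vector."""
    fm = features if isinstance(features, FeatureMaps) else FeatureMaps(np.asarray(features))
    return fm.maps.mean(axis=(1, 2))


def quadrant_slices(h: int, w: int) -> list[tuple[slice, slice]]:
    """The four quadrant windows (TL, TR, BL, BR), splitting at ``H//2, W//2``."""
    rm, cm = h // 2, w // 2
    return [
        (slice(0, rm), slice(0, cm)),
        (slice(0, rm), slice(cm, w)),
        (slice(rm, h), slice(0, cm)),
        (slice(rm, h), slice(cm, w)),
    ]


def region_pool(features: FeatureMaps | np.ndarray) -> PooledUnits:
    """Pool each map into five units: the global mean plus four quadrant means.

    The quadrants partition the map exactly once (split at ``H//2``,
    ``W//2``), so for even dimensions the mean of the four quadrant units
    recovers the global unit.
    """
    fm = features if isinstance(features, FeatureMaps) else FeatureMaps(np.asarray(features))
    h, w = fm.spatial_shape
    if h < 2 or w < 2:
        raise ShapeError(f"region_pool needs maps of at least 2x2, got {h}x{w}")
    quads = quadrant_slices(h, w)
    region_units = np.stack(
        [fm.maps[:, rs, cs].mean(axis=(1, 2)) for rs, cs in quads], axis=1
    )
    return PooledUnits(
        global_unit=fm.maps.mean(axis=(1, 2)),
        region_units=region_units,
        region_size=h * w,
    )


def momentum_update(
    state: TrainState, gradient: np.ndarray, strict_printed: bool = False
) -> TrainState:
    """One SGD step with momentum and weight decay.

    Standard mode folds the weight-decay penalty's gradient into the update:
    ``v' = gamma v + eta (dC/dw + (lambda/n) w)``, ``w' = w - v'``.  With
    ``strict_printed=True`` the scalar penalty value ``(lambda/2n) sum w_i^2``
    itself is added to the velocity instead — the literal printed form, kept
    for reference.
    """
    grad = np.asarray(gradient, dtype=np.float64)
    if grad.shape != state.weights.shape:
        raise ShapeError(f"gradient shape {grad.shape} != weights shape {state.weights.shape}")
    lam, n = state.weight_decay, state.n
    if strict_printed:
        penalty = (lam / (2 * n)) * np.sum(state.weights**2)
        v = state.momentum * state.velocity + state.learning_rate * grad + penalty
    else:
        v = state.momentum * state.velocity + state.learning_rate * (
            grad + (lam / n) * state.weights
        )
    return TrainState(
        weights=state.weights - v,
        velocity=v,
        learning_rate=state.learning_rate,
        momentum=state.momentum,
        weight_decay=state.weight_decay,
        epoch=state.epoch,
        n=state.n,
    )


def lr_schedule(epoch: int, total_epochs: int = 60) -> float:
    """Piecewise-constant learning rate: 0.1 / 0.01 / 0.001 / 0.0001.

    Plateaus end at epochs 25, 37 and 45; each change takes effect the epoch
    after the milestone, and the final rate holds through ``total_epochs``.
    """
    if not 1 <= epoch <= total_epochs:
        raise InvalidParameterError(f"epoch must lie in [1, {total_epochs}], got {epoch}")
    if epoch <= 25:
        return 0.1
    if epoch <= 37:
        return 0.01
    if epoch <= 45:
        return 0.001
    return 0.0001


def softmax_prob(scores) -> np.ndarray:
    """Softmax ``P_c = e^{S_c} / sum_c e^{S_c}`` with max-shift stabilization.

    Works on a vector or on a batch ``(N, C)`` along the last axis.
    """
    s = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(s).all():
        raise InvalidParameterError("scores must be finite")
    shifted = s - s.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# numpy conv-net layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix with edge padding (same conv)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (N, C, k, k, H, W) -> (N, C*k*k, H*W)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, h * w)


class _Conv2D:
    """Same-padded 3x3 convolution with He-initialized weights."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch * k * k))
        self.b = np.zeros(out_ch)
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = np.einsum("oc,ncp->nop", self.w, cols) + self.b[None, :, None]
        self._cache = (cols, (n, c, h, w))
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        d = dout.reshape(n, self.out_ch, h * w)
        self.dw = np.einsum("nop,ncp->oc", d, cols)
        self.db = d.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.w, d)  # (N, C*k*k, H*W)
        k, p = self.k, self.k // 2
        dcols = dcols.reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, di, dj]
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm2D:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]  # elements per channel
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        sum_d = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dx = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g * inv_std[None, :, None, None] / n) * (n * dout - sum_d - xhat * sum_dx)


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    """2x2 max pooling with stride 2; deterministic first-argmax tie-break."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        blocks = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = blocks.argmax(axis=-1)
        self._in_shape = (n, c, h, w)
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dblocks, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dblocks.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class SmallCNNBackbone:
    """The bundled small backbone: three conv/BN/ReLU blocks with pooling.

    The last block keeps full resolution by default (``pool_last=False``),
    so a 64x64 input yields ``channels[-1]`` final maps of 16x16 — the
    resolution the heat maps are computed at; coarser maps quantize the
    saliency peak and cost localization precision.
    """

    def __init__(self, in_channels: int = 3, channels: tuple[int, ...] = (8, 16, 32),
                 seed: int = 0, pool_last: bool = False):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.pool_last = pool_last
        self.convs, self.bns, self.relus, self.pools = [], [], [], []
        prev = in_channels
        for i, ch in enumerate(channels):
            self.convs.append(_Conv2D(prev, ch, 3, rng))
            self.bns.append(_BatchNorm2D(ch))
            self.relus.append(_ReLU())
            is_last = i == len(channels) - 1
            self.pools.append(_MaxPool2() if (pool_last or not is_last) else None)
            prev = ch

    @property
    def n_maps(self) -> int:
        return self.channels[-1]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for conv, bn, act, pool in zip(self.convs, self.bns, self.relus, self.pools):
            x = conv.forward(x)
            x = bn.forward(x, train=train)
            x = act.forward(x)
            if pool is not None:
                x = pool.forward(x)
        return x

    def backward(self, dfeat: np.ndarray) -> None:
        d = dfeat
        for conv, bn, act, pool in zip(
            reversed(self.convs), reversed(self.bns), reversed(self.relus), reversed(self.pools)
        ):
            if pool is not None:
                d = pool.backward(d)
            d = act.backward(d)
            d = bn.backward(d)
            d = conv.backward(d)

    def parameters(self) -> list[tuple[str, object, str]]:
        out = []
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            out.append((f"conv{i}.w", conv, "w"))
            out.append((f"conv{i}.b", conv, "b"))
            out.append((f"bn{i}.gamma", bn, "gamma"))
            out.append((f"bn{i}.beta", bn, "beta"))
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        g = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            g[f"conv{i}.w"] = conv.dw
            g[f"conv{i}.b"] = conv.db
            g[f"bn{i}.gamma"] = bn.dgamma
            g[f"bn{i}.beta"] = bn.dbeta
        return g

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            d[f"conv{i}.w"] = conv.w
            d[f"conv{i}.b"] = conv.b
            d[f"bn{i}.gamma"] = bn.gamma
            d[f"bn{i}.beta"] = bn.beta
            d[f"bn{i}.running_mean"] = bn.running_mean
            d[f"bn{i}.running_var"] = bn.running_var
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            conv.w = np.asarray(d[f"conv{i}.w"], dtype=np.float64)
            conv.b = np.asarray(d[f"conv{i}.b"], dtype=np.float64)
            bn.gamma = np.asarray(d[f"bn{i}.gamma"], dtype=np.float64)
            bn.beta = np.asarray(d[f"bn{i}.beta"], dtype=np.float64)
            bn.running_mean = np.asarray(d[f"bn{i}.running_mean"], dtype=np.float64)
            bn.running_var = np.asarray(d[f"bn{i}.running_var"], dtype=np.float64)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Training protocol: momentum SGD under the plateau LR schedule."""

    epochs: int = 60
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0001
    lr_scale: float = 1.0  # multiplies the schedule; 1.0 is the printed protocol
    seed: int = 0
    channels: tuple[int, ...] = (8, 16, 32)
    freeze_backbone: bool = False
    use_lrn: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise InvalidParameterError("batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A trained backbone plus its region-pooled class layer."""

    backbone: SmallCNNBackbone
    class_weights: ClassWeights
    config: TrainConfig
    classes: tuple
    loss_history: list[float] = field(default_factory=list)
    input_stats: tuple[float, float] = (0.0, 255.0)  # (shift, scale) applied to inputs

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] in (1, 3):  # HWC -> CHW
            x = x.transpose(0, 3, 1, 2)
        shift, scale = self.input_stats
        return (x - shift) / scale

    def feature_maps(self, images: np.ndarray) -> np.ndarray:
        """Final-layer activations, ``(N, n_maps, H', W')``, in inference mode."""
        x = self._prepare(images)
        feats = self.backbone.forward(x, train=False)
        if self.config.use_lrn:
            feats = np.stack([local_response_norm(f).maps for f in feats])
        return feats

    def scores(self, images: np.ndarray) -> np.ndarray:
        feats = self.feature_maps(images)
        pooled = np.stack([region_pool(f).as_matrix() for f in feats])  # (N, maps, 5)
        return np.einsum("cmr,nmr->nc", self.class_weights.weights, pooled)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax_prob(self.scores(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(images).argmax(axis=1)
        return np.asarray([self.classes[i] for i in idx])

    def save(self, path) -> None:
        state = self.backbone.state_dict()
        state["class_weights"] = self.class_weights.weights
        state["classes"] = np.asarray(self.classes)
        state["loss_history"] = np.asarray(self.loss_history)
        state["input_stats"] = np.asarray(self.input_stats)
        state["channels"] = np.asarray(self.config.channels)
        state["use_lrn"] = np.asarray(self.config.use_lrn)
        state["in_channels"] = np.asarray(self.backbone.convs[0].in_ch)
        state["pool_last"] = np.asarray(self.backbone.pool_last)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            channels = tuple(int(c) for c in data["channels"])
            config = TrainConfig(channels=channels, use_lrn=bool(data["use_lrn"]))
            backbone = SmallCNNBackbone(
                in_channels=int(data["in_channels"]), channels=channels,
                pool_last=bool(data["pool_last"]),
            )
            backbone.load_state_dict({k: data[k] for k in data.files})
            classes = tuple(data["classes"].tolist())
            return cls(
                backbone=backbone,
                class_weights=ClassWeights(data["class_weights"], classes=classes),
                config=config,
                classes=classes,
                loss_history=[float(v) for v in data["loss_history"]],
                input_stats=tuple(float(v) for v in data["input_stats"]),
            )


def _pooled_grad_to_maps(dpooled: np.ndarray, h: int, w: int) -> np.ndarray:
    """Spread gradients of the 5 pooled units back over an (n_maps, h, w) grid."""
    n_maps = dpooled.shape[0]
    d = np.zeros((n_maps, h, w))
    d += dpooled[:, 0, None, None] / (h * w)
    for q, (rs, cs) in enumerate(quadrant_slices(h, w), start=1):
        area = (rs.stop - rs.start) * (cs.stop - cs.start)
        d[:, rs, cs] += dpooled[:, q, None, None] / area
    return d


def train_classifier(
    images: np.ndarray,
    labels,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train the region-pool-head classifier on labeled images.

    ``images`` is ``(N, H, W, C)`` (or ``(N, C, H, W)``) in 0..255;
    ``labels`` any hashable class labels with at least two distinct values.
    The loss is cross-entropy over the softmax of the region-pooled scores;
    updates use momentum SGD with weight decay under the plateau schedule.
    Everything is driven by ``config.seed``, so a repeated run is
    bit-identical.
    """
    cfg = config or TrainConfig()
    x = np.asarray(images, dtype=np.float64)
    if x.ndim != 4:
        raise InvalidDatasetError("images must be a 4-D array")
    if x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
        x = x.transpose(0, 3, 1, 2)
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) < 2:
        raise InvalidDatasetError("training needs at least two classes")
    y = np.asarray([classes.index(v) for v in labels])
    n_classes = len(classes)

    rng = np.random.default_rng(cfg.seed)
    backbone = SmallCNNBackbone(
        in_channels=x.shape[1], channels=cfg.channels, seed=int(rng.integers(2**31))
    )
    n_maps = backbone.n_maps
    head_w = rng.normal(0.0, 0.01, size=(n_classes, n_maps, N_REGIONS))

    shift, scale = 0.0, 255.0
    xn = (x - shift) / scale

    velocities: dict[str, np.ndarray] = {
        name: np.zeros_like(getattr(obj, attr)) for name, obj, attr in backbone.parameters()
    }
    velocities["head.w"] = np.zeros_like(head_w)

    loss_history: list[float] = []
    n = x.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_schedule(epoch, total_epochs=max(cfg.epochs, 60)) * cfg.lr_scale
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = xn[idx], y[idx]
            feats = backbone.forward(xb, train=True)  # (B, maps, h, w)
            b, _, fh, fw = feats.shape
            pooled = np.stack([region_pool(f).as_matrix() for f in feats])
            s = np.einsum("cmr,bmr->bc", head_w, pooled)
            p = softmax_prob(s)
            loss = -np.log(np.clip(p[np.arange(b), yb], 1e-12, None)).mean()
            epoch_loss += loss * b
            seen += b

            ds = p.copy()
            ds[np.arange(b), yb] -= 1.0
            ds /= b
            dhead = np.einsum("bc,bmr->cmr", ds, pooled)
            if not cfg.freeze_backbone:
                dpooled = np.einsum("cmr,bc->bmr", head_w, ds)
                dfeats = np.stack([_pooled_grad_to_maps(dp, fh, fw) for dp in dpooled])
                backbone.backward(dfeats)
                grads = backbone.gradients()
                for name, obj, attr in backbone.parameters():
                    w = getattr(obj, attr)
                    v = cfg.momentum * velocities[name] + lr * (
                        grads[name] + cfg.weight_decay * w
                    )
                    velocities[name] = v
                    setattr(obj, attr, w - v)
            v = cfg.momentum * velocities["head.w"] + lr * (dhead + cfg.weight_decay * head_w)
            velocities["head.w"] = v
            head_w = head_w - v
        loss_history.append(epoch_loss / seen)

    return TrainedModel(
        backbone=backbone,
        class_weights=ClassWeights(head_w, classes=classes),
        config=cfg,
        classes=classes,
        loss_history=loss_history,
        input_stats=(shift, scale),
    )
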