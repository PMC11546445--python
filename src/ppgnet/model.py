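"""PPG-NET: an Xception-style depthwise-separable CNN, implemented in numpy.

The network classifies scalogram images into the four blood-pressure
stages.  Its graph has three flows:

* **entry** — a two-conv stem, then downsampling residual blocks of
  depthwise-separable convolutions with max pooling and a strided 1x1
  convolution shortcut;
* **middle** — identity-shortcut residual blocks of three separable
  convolutions each;
* **exit** — separable convolutions, global average pooling, and a dense
  softmax head.

A depthwise-separable convolution factors a standard Dk x Dk x M x N
convolution into a per-channel Dk x Dk depthwise step (Dk^2 M parameters)
and a 1x1 pointwise step (M N parameters), so it costs Dk^2 M + M N
parameters instead of Dk^2 M N.  Closed-form parameter arithmetic for every
layer lives in :func:`count_parameters` and is checked against the built
model's arrays.

Everything here — forward pass, backpropagation, SGD with momentum, early
stopping — is plain numpy (float32), so training is deterministic for a
fixed seed.  Convolutions use patch extraction (im2col) plus einsum;
backward input gradients use a 9-term col2im scatter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

_DT = np.float32


# ---------------------------------------------------------------------------
# configs and parameter arithmetic
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SeparableConvSpec:
    """One separable convolution: kernel Dk, M input and N output channels."""

    kernel: int = 3
    in_channels: int = 1
    out_channels: int = 1
    stride: int = 1

    def param_count(self) -> int:
        """Dk^2 M (depthwise) + M N (pointwise)."""
        return self.kernel**2 * self.in_channels + self.in_channels * self.out_channels

    def standard_param_count(self) -> int:
        """Dk^2 M N of the equivalent standard convolution."""
        return self.kernel**2 * self.in_channels * self.out_channels


def separable_conv_params(kernel: int, m: int, n: int) -> int:
    return SeparableConvSpec(kernel, m, n).param_count()


def standard_conv_params(kernel: int, m: int, n: int) -> int:
    return SeparableConvSpec(kernel, m, n).standard_param_count()


@dataclasses.dataclass
class PPGNetConfig:
    """Architectural description of the network.

    ``entry_widths`` are the output channels of the downsampling entry
    blocks (each halves the spatial size); ``middle_width`` defaults to the
    last entry width (identity residual blocks need matching channels).
    """

    input_size: tuple[int, int, int] = (224, 224, 3)
    stem_widths: tuple[int, int] = (32, 64)
    entry_widths: tuple[int, ...] = (128, 256, 728)
    middle_blocks: int = 4
    middle_width: int | None = None
    exit_widths: tuple[int, ...] = (1024,)
    n_classes: int = 4
    use_batch_normalization: bool = True
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ValidationError("the stage classifier is 4-way")
        widths = (*self.stem_widths, *self.entry_widths, *self.exit_widths)
        if any(w < 1 for w in widths) or len(self.stem_widths) != 2:
            raise ValidationError("all widths must be >= 1; stem has 2 convs")
        if self.middle_width is not None and self.middle_width != self.entry_widths[-1]:
            raise ValidationError(
                "middle_width must equal the last entry width (identity shortcuts)"
            )
        if self.middle_blocks < 0:
            raise ValidationError("middle_blocks must be >= 0")
        h, w, c = self.input_size
        factor = self.total_downsampling()
        if h % factor or w % factor or h < factor or w < factor:
            raise ValidationError(
                f"input {h}x{w} must be a positive multiple of the total "
                f"downsampling factor {factor}"
            )

    def total_downsampling(self) -> int:
        return 2 ** (1 + len(self.entry_widths))  # stem stride 2 + one pool per block

    def resolved_middle_width(self) -> int:
        return self.middle_width if self.middle_width is not None else self.entry_widths[-1]

    @classmethod
    def desk_scale(cls) -> "PPGNetConfig":
        """Reduced network for CPU-scale experiments on 64x64 inputs."""
        return cls(
            input_size=(64, 64, 3),
            stem_widths=(8, 16),
            entry_widths=(32, 64),
            middle_blocks=1,
            exit_widths=(128,),
        )


@dataclasses.dataclass
class ParameterCount:
    """Convolution/dense ("core") and normalization parameter totals."""

    core: int
    norm: int

    @property
    def total(self) -> int:
        return self.core + self.norm


def count_parameters(cfg: PPGNetConfig) -> ParameterCount:
    """Closed-form parameter count of the graph built by :func:`build_ppgnet`.

    Core counts: standard convs Dk^2*M*N (no bias; normalization absorbs
    offsets), separable convs Dk^2*M + M*N, pointwise shortcuts M*N, dense
    head M*N + N (bias).  Normalization: 2 trainable parameters (scale,
    shift) per normalized channel.
    """
    k = cfg.kernel
    core = 0
    norm_channels = 0
    c = cfg.input_size[2]
    # stem: two standard convs
    for w in cfg.stem_widths:
        core += k * k * c * w
        norm_channels += w
        c = w
    # entry blocks: two separable convs + 1x1 shortcut
    for w in cfg.entry_widths:
        core += separable_conv_params(k, c, w) + separable_conv_params(k, w, w)
        core += c * w  # shortcut pointwise conv, stride 2
        norm_channels += 3 * w
        c = w
    # middle blocks: three separable convs each, identity shortcut
    mw = cfg.resolved_middle_width()
    core += cfg.middle_blocks * 3 * separable_conv_params(k, mw, mw)
    norm_channels += cfg.middle_blocks * 3 * mw
    c = mw
    # exit separable convs
    for w in cfg.exit_widths:
        core += separable_conv_params(k, c, w)
        norm_channels += w
        c = w
    # dense head (with bias)
    core += c * cfg.n_classes + cfg.n_classes
    norm = 2 * norm_channels if cfg.use_batch_normalization else 0
    return ParameterCount(core=core, norm=norm)


@dataclasses.dataclass
class TrainConfig:
    """Optimization protocol: SGD, learning rate 0.01, batch size 12,
    up to 100 epochs, 5 folds; early stopping on validation accuracy."""

    learning_rate: float = 0.01
    batch_size: int = 12
    epochs: int = 100
    folds: int = 5
    early_stop_patience: int = 10
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("invalid optimization parameters")
        if self.early_stop_patience < 1 or self.folds < 1:
            raise ValidationError("patience and folds must be >= 1")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad", "is_norm")

    def __init__(self, value: np.ndarray, is_norm: bool = False):
        self.value = value.astype(_DT)
        self.grad = np.zeros_like(self.value)
        self.is_norm = is_norm


def _patches(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Same-padded sliding windows: (N, Ho, Wo, C, k, k)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    return win[:, ::stride, ::stride]


def _col2im(dcol: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_patches`: scatter patch grads back to the input."""
    n, h, w, c = x_shape
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=_DT)
    ho, wo = dcol.shape[1:3]
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcol[..., i, j]
    return dxp[:, p:p + h, p:p + w]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Standard same-padded convolution, no bias."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = Param(rng.normal(0.0, scale, (k, k, cin, cout)))
        self.k, self.stride = k, stride

    def params(self):
        return [self.w]

    def forward(self, x, training):
        self._x_shape = x.shape
        self._cols = _patches(x, self.k, self.stride)
        return np.einsum("nhwcij,ijcm->nhwm", self._cols, self.w.value, optimize=True)

    def backward(self, dy):
        self.w.grad += np.einsum("nhwcij,nhwm->ijcm", self._cols, dy, optimize=True)
        dcol = np.einsum("nhwm,ijcm->nhwcij", dy, self.w.value, optimize=True)
        return _col2im(dcol, self._x_shape, self.k, self.stride)


class PointwiseConv(Layer):
    """1x1 convolution (optionally strided), no bias."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)))
        self.stride = stride

    def params(self):
        return [self.w]

    def forward(self, x, training):
        self._x_shape = x.shape
        self._x = x[:, ::self.stride, ::self.stride]
        return np.einsum("nhwc,cm->nhwm", self._x, self.w.value, optimize=True)

    def backward(self, dy):
        self.w.grad += np.einsum("nhwc,nhwm->cm", self._x, dy, optimize=True)
        dxs = np.einsum("nhwm,cm->nhwc", dy, self.w.value, optimize=True)
        if self.stride == 1:
            return dxs
        dx = np.zeros(self._x_shape, dtype=_DT)
        dx[:, ::self.stride, ::self.stride] = dxs
        return dx


class DepthwiseConv2d(Layer):
    """Per-channel same-padded spatial convolution."""

    def __init__(self, c: int, k: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / (k * k)), (k, k, c)))
        self.k = k

    def params(self):
        return [self.w]

    def forward(self, x, training):
        self._x_shape = x.shape
        self._cols = _patches(x, self.k, 1)
        return np.einsum("nhwcij,ijc->nhwc", self._cols, self.w.value, optimize=True)

    def backward(self, dy):
        self.w.grad += np.einsum("nhwcij,nhwc->ijc", self._cols, dy, optimize=True)
        dcol = np.einsum("nhwc,ijc->nhwcij", dy, self.w.value, optimize=True)
        return _col2im(dcol, self._x_shape, self.k, 1)


class SeparableConv2d(Layer):
    """Depthwise Dk x Dk followed by pointwise 1x1 (Dk^2 M + M N params)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.depthwise = DepthwiseConv2d(cin, k, rng)
        self.pointwise = PointwiseConv(cin, cout, 1, rng)

    def params(self):
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x, training):
        return self.pointwise.forward(self.depthwise.forward(x, training), training)

    def backward(self, dy):
        return self.depthwise.backward(self.pointwise.backward(dy))


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), is_norm=True)
        self.beta = Param(np.zeros(c), is_norm=True)
        self.rmean = np.zeros(c, dtype=_DT)
        self.rvar = np.ones(c, dtype=_DT)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.rmean = self.momentum * self.rmean + (1 - self.momentum) * mean
            self.rvar = self.momentum * self.rvar + (1 - self.momentum) * var
        else:
            mean, var = self.rmean, self.rvar
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(_DT)
        self._xhat = ((x - mean) * self._istd).astype(_DT)
        self._m = x.shape[0] * x.shape[1] * x.shape[2]
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        self.gamma.grad += np.einsum("nhwc,nhwc->c", dy, self._xhat, optimize=True)
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        g = self.gamma.value * self._istd
        if not self._training:
            return (dy * g).astype(_DT)
        m = self._m
        dxhat = dy * self.gamma.value
        term = dxhat - dxhat.mean(axis=(0, 1, 2)) - self._xhat * np.einsum(
            "nhwc,nhwc->c", dxhat, self._xhat, optimize=True
        ) / m
        return (term * self._istd).astype(_DT)


class Identity(Layer):
    def forward(self, x, training):
        return x

    def backward(self, dy):
        return dy


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(n, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._x_shape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=_DT)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._x_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._x_shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._x_shape).astype(_DT)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class _Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class _ResidualBlock(Layer):
    """main(x) + shortcut(x); shortcut may be Identity."""

    def __init__(self, main: _Sequential, shortcut: Layer):
        self.main, self.shortcut = main, shortcut

    def params(self):
        return self.main.params() + self.shortcut.params()

    def forward(self, x, training):
        return self.main.forward(x, training) + self.shortcut.forward(x, training)

    def backward(self, dy):
        return self.main.backward(dy) + self.shortcut.backward(dy)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class PPGNet:
    """The assembled network: entry, middle, and exit flows plus the head."""

    def __init__(self, cfg: PPGNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k = cfg.kernel
        bn = (lambda c: BatchNorm2d(c)) if cfg.use_batch_normalization else (lambda c: Identity())
        layers: list[Layer] = []
        c = cfg.input_size[2]
        s0, s1 = cfg.stem_widths
        layers += [Conv2d(c, s0, k, 2, rng), bn(s0), ReLU()]
        layers += [Conv2d(s0, s1, k, 1, rng), bn(s1), ReLU()]
        c = s1
        for w in cfg.entry_widths:
            main = _Sequential([
                ReLU(),
                SeparableConv2d(c, w, k, rng), bn(w), ReLU(),
                SeparableConv2d(w, w, k, rng), bn(w),
                MaxPool2(),
            ])
            shortcut = _Sequential([PointwiseConv(c, w, 2, rng), bn(w)])
            layers.append(_ResidualBlock(main, shortcut))
            c = w
        mw = cfg.resolved_middle_width()
        for _ in range(cfg.middle_blocks):
            main = _Sequential(
                sum(([ReLU(), SeparableConv2d(mw, mw, k, rng), bn(mw)] for _ in range(3)), [])
            )
            layers.append(_ResidualBlock(main, Identity()))
        c = mw
        for w in cfg.exit_widths:
            layers += [ReLU(), SeparableConv2d(c, w, k, rng), bn(w)]
            c = w
        layers += [ReLU(), GlobalAvgPool()]
        self.body = _Sequential(layers)
        self.head = Dense(c, cfg.n_classes, rng)

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Param]:
        return self.body.params() + self.head.params()

    def parameter_count(self) -> ParameterCount:
        core = sum(p.value.size for p in self.params() if not p.is_norm)
        norm = sum(p.value.size for p in self.params() if p.is_norm)
        return ParameterCount(core=core, norm=norm)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of NHWC images in [0, 1]."""
        x = np.asarray(x, dtype=_DT)
        if x.ndim != 4 or x.shape[1:] != tuple(self.cfg.input_size):
            raise ValidationError(
                f"expected batch of {self.cfg.input_size} images, got {x.shape}"
            )
        return self.head.forward(self.body.forward(x, training), training)

    def backward(self, dlogits: np.ndarray) -> None:
        self.body.backward(self.head.backward(dlogits))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for l in _iter_layers(self.body):
            if isinstance(l, BatchNorm2d):
                state += [l.rmean.copy(), l.rvar.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = iter(state[len(ps):])
        for l in _iter_layers(self.body):
            if isinstance(l, BatchNorm2d):
                l.rmean[...] = next(rest)
                l.rvar[...] = next(rest)


def _iter_layers(layer: Layer):
    yield layer
    for attr in ("layers",):
        for sub in getattr(layer, attr, []):
            yield from _iter_layers(sub)
    for attr in ("main", "shortcut", "depthwise", "pointwise"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, Layer):
            yield from _iter_layers(sub)


def build_ppgnet(cfg: PPGNetConfig, seed: int = 0) -> PPGNet:
    """Instantiate the network with He-style random initial weights."""
    return PPGNet(cfg, seed)


# ---------------------------------------------------------------------------
# loss, optimizer, training
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    d = p
    d[np.arange(n), y] -= 1.0
    return float(loss), (d / n).astype(_DT)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


def predict(model: PPGNet, images: np.ndarray, batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Labels (argmax; ties break to the lowest class index) + probabilities."""
    images = np.asarray(images, dtype=_DT)
    probs = []
    for i in range(0, len(images), batch_size):
        probs.append(softmax(model.forward(images[i:i + batch_size], training=False)))
    p = np.vstack(probs) if probs else np.zeros((0, model.cfg.n_classes))
    return p.argmax(axis=1), p


@dataclasses.dataclass
class FitResult:
    history: dict  # per-epoch lists: train_loss, train_acc, val_acc
    best_epoch: int
    best_val_acc: float
    stopped_early: bool


def fit(
    model: PPGNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> FitResult:
    """SGD training with early stopping on validation accuracy.

    Training data is reshuffled each epoch (validation order is never
    touched).  When validation accuracy fails to improve for
    ``early_stop_patience`` epochs, training halts and the weights from the
    best validation epoch are restored — never a later epoch's.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValidationError("empty training or validation set")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.params(), cfg.learning_rate, cfg.momentum)
    history = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_acc, best_epoch, best_state, wait = -1.0, -1, None, 0
    stopped = False
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        losses, hits = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise ValidationError(f"non-finite loss at epoch {epoch}; aborting")
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
        val_pred, _ = predict(model, x_val, max(cfg.batch_size, 32))
        val_acc = float((val_pred == y_val).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / len(x_train))
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch, wait = val_acc, epoch, 0
            best_state = model.get_state()
        else:
            # Ties refresh the snapshot (the latest best-validation epoch
            # has had the most training) but still count toward patience,
            # so a flat plateau stops early.
            if val_acc == best_acc:
                best_epoch = epoch
                best_state = model.get_state()
            wait += 1
            if wait >= cfg.early_stop_patience:
                stopped = True
                break
    if best_state is not None:
        model.set_state(best_state)
    return FitResult(history, best_epoch, best_acc, stopped)


@dataclasses.dataclass
class FoldResult:
    fold: int
    fit: FitResult
    val_accuracy: float


def train_cv(
    model_cfg: PPGNetConfig,
    images: np.ndarray,
    labels: np.ndarray,
    source_subjects: list[str],
    folds: list[list[str]],
    train_cfg: TrainConfig,
) -> tuple[list[FoldResult], list[PPGNet]]:
    """Subject-aware k-fold training: each fold validates on its own
    subjects and trains on everyone else's.  Returns per-fold results and
    the trained (best-epoch) models."""
    labels = np.asarray(labels)
    sources = np.asarray(source_subjects)
    results, models = [], []
    for i, fold in enumerate(folds):
        val_mask = np.isin(sources, list(fold))
        if not val_mask.any() or val_mask.all():
            raise ValidationError(f"fold {i} leaves an empty train or validation set")
        model = build_ppgnet(model_cfg, seed=train_cfg.seed + i)
        fcfg = dataclasses.replace(train_cfg, seed=train_cfg.seed + i)
        res = fit(
            model,
            images[~val_mask], labels[~val_mask],
            images[val_mask], labels[val_mask],
            fcfg,
        )
        results.append(FoldResult(i, res, res.best_val_acc))
        models.append(model)
    return results, models


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: PPGNet, path: str | Path, seed: int | None = None) -> None:
    """Weights as .npz plus a JSON sidecar recording config (and seed)."""
    path = Path(path)
    state = model.get_state()
    np.savez(path, **{f"arr_{i}": a for i, a in enumerate(state)})
    sidecar = {
        "config": dataclasses.asdict(model.cfg),
        "seed": seed,
        "n_arrays": len(state),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> PPGNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["config"])
    for key in ("input_size", "stem_widths", "entry_widths", "exit_widths"):
        cfg_d[key] = tuple(cfg_d[key])
    model = PPGNet(PPGNetConfig(**cfg_d), seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        state = [z[f"arr_{i}"] for i in range(sidecar["n_arrays"])]
    model.set_state(state)
    return model
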