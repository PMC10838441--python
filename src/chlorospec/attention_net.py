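"""1-D spectral-attention CNN for SPAD regression, with its training loop.

Architecture (input: a min-max scaled mean spectrum of length ``n_bands``):

1. **Spectral attention (squeeze-and-excitation)** — the spectrum is a
   single-channel sequence, so each band is treated as a channel: the
   per-band descriptor is the band value itself, two fully connected layers
   (bottleneck ``n_bands / se_reduction``, ReLU between) map it through a
   sigmoid to a per-band weight vector in (0, 1), which multiplicatively
   recalibrates the input bands.
2. **Stem** — one convolution (stride 2) followed by average pooling
   (stride 3), shrinking the sequence to exactly 1/6 of the input length
   (180 bands -> 30 positions).
3. **1-D Inception module** — four parallel branches (kernel sizes 1, 3, 5
   and an average-pooling branch with a 1x1 convolution), concatenated on
   the channel axis.
4. **Head** — two fully connected layers with a ReLU between; the single
   output is the SPAD estimate.

Training uses Adam on MSE plus L2 weight decay, batch size 6, base learning
rate 1e-4 under cosine annealing with periodic restarts, and optional
offset/slope augmentation of the training spectra.  Everything runs on
plain numpy; gradients are hand-derived per layer (and checked against
finite differences in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import AugmentationConfig

__all__ = [
    "ModelConfig",
    "AttentionWeights",
    "TrainingHistory",
    "ChlorophyllCNN",
    "build_model",
    "se_recalibrate",
    "forward",
    "cosine_annealing_lr",
    "train",
    "get_attention_weights",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Strides are fixed by the design (conv stride 2, pool stride 3 -> 1/6
    downsampling) and the Inception kernel sizes are exactly {1, 3, 5} plus
    the pooling branch; attempting other values is rejected.  Setting
    ``use_attention=False`` ablates the SE block to an identity gate,
    giving the plain 1-D Inception comparator.
    """

    n_bands: int = 180
    use_attention: bool = True
    se_reduction: int = 4
    stem_channels: int = 16
    stem_kernel_size: int = 7
    stem_conv_stride: int = 2
    stem_pool_stride: int = 3
    inception_kernel_sizes: tuple[int, ...] = (1, 3, 5)
    inception_branch_channels: int = 16
    fc_hidden_size: int = 64
    learning_rate: float = 1e-4
    batch_size: int = 6
    epochs: int = 500
    lr_restart_period: int = 200
    lr_min: float = 0.0
    l2_coefficient: float = 1e-4
    center_output_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands % 6 != 0 or self.n_bands <= 0:
            raise ValueError(f"n_bands must be a positive multiple of 6; got {self.n_bands}")
        if self.stem_conv_stride != 2 or self.stem_pool_stride != 3:
            raise ValueError("stem strides are fixed: conv stride 2, pool stride 3")
        if tuple(self.inception_kernel_sizes) != (1, 3, 5):
            raise ValueError("inception kernel sizes are fixed to (1, 3, 5)")
        if self.se_reduction < 1 or self.n_bands // self.se_reduction < 1:
            raise ValueError("invalid se_reduction")
        if self.epochs < 1 or self.lr_restart_period < 1:
            raise ValueError("epochs and lr_restart_period must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class AttentionWeights:
    """Per-band sigmoid gate values, each strictly in (0, 1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("attention weights must be a 1-D vector")
        if np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("attention weights must lie strictly in (0, 1)")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class TrainingHistory:
    """Per-epoch training loss, validation loss and learning rate."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


# --------------------------------------------------------------------------
# layers (forward caches what backward needs; params/grads are dicts)
# --------------------------------------------------------------------------

class _Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_out, n_in)), "b": np.zeros(n_out)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads = {"W": dy.T @ self._x, "b": dy.sum(axis=0)}
        return dy @ self.params["W"]


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(left, right, out_length) padding so out = ceil(length / stride)."""
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2, out


class Conv1d(_Layer):
    """1-D convolution over (batch, channels, length) with 'same'-style padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride
        scale = math.sqrt(2.0 / (in_ch * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_ch, in_ch, kernel)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        left, right, out = _same_pad(x.shape[2], self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride]  # (n, c, out, k)
        self._win, self._pad, self._in_len = win, (left, right), x.shape[2]
        return np.einsum("nclk,ock->nol", win, self.params["W"], optimize=True) + \
            self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads = {
            "W": np.einsum("nol,nclk->ock", dy, self._win, optimize=True),
            "b": dy.sum(axis=(0, 2)),
        }
        left, right = self._pad
        n, c = self._win.shape[0], self._win.shape[1]
        dxp = np.zeros((n, c, left + self._in_len + right))
        starts = np.arange(dy.shape[2]) * self.stride
        for j in range(self.kernel):
            dxp[:, :, starts + j] += np.einsum("nol,oc->ncl", dy, W[:, :, j], optimize=True)
        return dxp[:, :, left:left + self._in_len]


class AvgPool1d(_Layer):
    """Average pooling over (batch, channels, length); counts include padding."""

    def __init__(self, kernel: int, stride: int, same: bool = False) -> None:
        super().__init__()
        self.kernel, self.stride, self.same = kernel, stride, same

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.same:
            left, right, _ = _same_pad(x.shape[2], self.kernel, self.stride)
        else:
            left = right = 0
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride]
        self._pad, self._in_len, self._n_out = (left, right), x.shape[2], win.shape[2]
        self._shape = x.shape
        return win.mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        left, right = self._pad
        n, c, _ = self._shape
        dxp = np.zeros((n, c, left + self._in_len + right))
        starts = np.arange(self._n_out) * self.stride
        for j in range(self.kernel):
            dxp[:, :, starts + j] += dy / self.kernel
        return dxp[:, :, left:left + self._in_len]


class SEBlock(_Layer):
    """Squeeze-and-excitation gate over spectral bands.

    Input (batch, n_bands): the band-wise descriptor is the band value
    itself (its singleton spatial extent makes global average pooling the
    identity); two Dense layers with a ReLU bottleneck and a sigmoid
    produce per-band weights that rescale the input.
    """

    def __init__(self, n_bands: int, reduction: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fc1 = Dense(n_bands, n_bands // reduction, rng)
        self.fc2 = Dense(n_bands // reduction, n_bands, rng)
        self.relu = ReLU()

    @property
    def sublayers(self) -> list[_Layer]:
        return [self.fc1, self.fc2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu.forward(self.fc1.forward(x))
        z = self.fc2.forward(h)
        w = 1.0 / (1.0 + np.exp(-z))
        self._x, self._w = x, w
        return w * x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, x = self._w, self._x
        dz = (dy * x) * w * (1.0 - w)
        dx_gate = self.fc1.backward(self.relu.backward(self.fc2.backward(dz)))
        return dy * w + dx_gate

    def gate(self, x: np.ndarray) -> np.ndarray:
        """Per-band weights for input spectra (no caching side effects kept)."""
        h = np.maximum(self.fc1.forward(x), 0.0)
        z = self.fc2.forward(h)
        return 1.0 / (1.0 + np.exp(-z))


class Inception1d(_Layer):
    """Four parallel branches (1x1, 1x3, 1x5 convs + avgpool->1x1), concatenated."""

    def __init__(self, in_ch: int, branch_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv1d(in_ch, branch_ch, 1, 1, rng)
        self.conv3 = Conv1d(in_ch, branch_ch, 3, 1, rng)
        self.conv5 = Conv1d(in_ch, branch_ch, 5, 1, rng)
        self.pool = AvgPool1d(3, 1, same=True)
        self.pool_conv = Conv1d(in_ch, branch_ch, 1, 1, rng)
        self.relus = [ReLU() for _ in range(4)]
        self.branch_ch = branch_ch

    @property
    def sublayers(self) -> list[_Layer]:
        return [self.conv1, self.conv3, self.conv5, self.pool_conv]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [
            self.relus[0].forward(self.conv1.forward(x)),
            self.relus[1].forward(self.conv3.forward(x)),
            self.relus[2].forward(self.conv5.forward(x)),
            self.relus[3].forward(self.pool_conv.forward(self.pool.forward(x))),
        ]
        return np.concatenate(outs, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = self.branch_ch
        parts = [dy[:, i * c:(i + 1) * c] for i in range(4)]
        dx = self.conv1.backward(self.relus[0].backward(parts[0]))
        dx += self.conv3.backward(self.relus[1].backward(parts[1]))
        dx += self.conv5.backward(self.relus[2].backward(parts[2]))
        dx += self.pool.backward(self.pool_conv.backward(self.relus[3].backward(parts[3])))
        return dx


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class ChlorophyllCNN:
    """The full network; see the module docstring for the layer order."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.attention = SEBlock(cfg.n_bands, cfg.se_reduction, rng) if cfg.use_attention else None
        self.stem_conv = Conv1d(1, cfg.stem_channels, cfg.stem_kernel_size,
                                cfg.stem_conv_stride, rng)
        self.stem_relu = ReLU()
        self.stem_pool = AvgPool1d(cfg.stem_pool_stride, cfg.stem_pool_stride)
        self.inception = Inception1d(cfg.stem_channels, cfg.inception_branch_channels, rng)
        self.stem_out_len = cfg.n_bands // 6
        flat = 4 * cfg.inception_branch_channels * self.stem_out_len
        self.fc1 = Dense(flat, cfg.fc_hidden_size, rng)
        self.fc_relu = ReLU()
        self.fc2 = Dense(cfg.fc_hidden_size, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _param_layers(self) -> list[_Layer]:
        layers: list[_Layer] = []
        if self.attention is not None:
            layers += self.attention.sublayers
        layers.append(self.stem_conv)
        layers += self.inception.sublayers
        layers += [self.fc1, self.fc2]
        return layers

    def parameters(self) -> list[tuple[_Layer, str, np.ndarray]]:
        return [(layer, name, arr) for layer in self._param_layers()
                for name, arr in layer.params.items()]

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray) -> np.ndarray:
        h = self.attention.forward(X) if self.attention is not None else X
        h = h[:, None, :]  # add the channel axis
        h = self.stem_pool.forward(self.stem_relu.forward(self.stem_conv.forward(h)))
        h = self.inception.forward(h)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.fc2.forward(self.fc_relu.forward(self.fc1.forward(h)))
        return h[:, 0]

    def _backward(self, dpred: np.ndarray) -> None:
        dy = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(dpred[:, None])))
        dy = dy.reshape(self._flat_shape)
        dy = self.inception.backward(dy)
        dy = self.stem_conv.backward(self.stem_relu.backward(self.stem_pool.backward(dy)))
        dy = dy[:, 0, :]
        if self.attention is not None:
            self.attention.backward(dy)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.cfg.n_bands:
            raise ValueError(f"expected spectra of length {self.cfg.n_bands}; got {X.shape[1]}")
        if np.any(np.isnan(X)):
            raise ValueError("input spectra contain NaN")
        return self._forward(X)


def build_model(cfg: ModelConfig) -> ChlorophyllCNN:
    """Construct the network with deterministic initialization from ``cfg.seed``."""
    return ChlorophyllCNN(cfg)


def se_recalibrate(spectrum: np.ndarray, attention: SEBlock) -> tuple[np.ndarray, AttentionWeights]:
    """Apply the SE gate to one spectrum; returns (reweighted, weights)."""
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != attention.fc1.params["W"].shape[1]:
        raise ValueError(
            f"spectrum length {X.shape[1]} does not match attention input size "
            f"{attention.fc1.params['W'].shape[1]}"
        )
    w = attention.gate(X)
    out = w * X
    weights = AttentionWeights(w.mean(axis=0))
    return (out[0] if squeeze else out), weights


def forward(model: ChlorophyllCNN, spectrum: np.ndarray):
    """Predict SPAD for one spectrum (scalar) or a batch (vector)."""
    x = np.asarray(spectrum, dtype=float)
    pred = model.predict(x)
    return float(pred[0]) if x.ndim == 1 else pred


def cosine_annealing_lr(epoch: int, cfg: ModelConfig) -> float:
    """Cosine-annealed learning rate with restarts every ``lr_restart_period``."""
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    T = cfg.lr_restart_period
    phase = (epoch % T) / T
    return cfg.lr_min + 0.5 * (cfg.learning_rate - cfg.lr_min) * (1.0 + math.cos(math.pi * phase))


def get_attention_weights(model: ChlorophyllCNN, spectra: np.ndarray) -> AttentionWeights:
    """Mean SE gate vector over the given spectra."""
    if model.attention is None:
        raise ValueError("model was built without an attention block")
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("need at least one spectrum")
    return AttentionWeights(model.attention.gate(X).mean(axis=0))


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, model: ChlorophyllCNN, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {
            id(arr): (np.zeros_like(arr), np.zeros_like(arr))
            for _, _, arr in model.parameters()
        }

    def step(self, model: ChlorophyllCNN, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, arr in model.parameters():
            g = layer.grads[name]
            m, v = self.state[id(arr)]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            arr -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "X") and hasattr(dataset, "y"):
        return np.asarray(dataset.X, dtype=float), np.asarray(dataset.y, dtype=float)
    X, y = dataset
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def _loss_and_grad(model: ChlorophyllCNN, X: np.ndarray, y: np.ndarray,
                   l2: float) -> tuple[float, np.ndarray]:
    pred = model._forward(X)
    resid = pred - y
    mse = float(np.mean(resid ** 2))
    loss = mse
    if l2 > 0:
        loss += l2 * sum(float(np.sum(arr ** 2)) for layer, name, arr in model.parameters()
                         if name == "W")
    dpred = 2.0 * resid / y.size
    return loss, dpred


def train(
    model: ChlorophyllCNN,
    train_set,
    val_set=None,
    cfg: ModelConfig | None = None,
    augment: AugmentationConfig | None = None,
    augment_mode: str = "global",
) -> tuple[ChlorophyllCNN, TrainingHistory]:
    """Adam on MSE + L2 weight decay, with cosine-annealed learning rate.

    Augmentation (offset/slope jitter, fresh draw per sample per epoch) is
    applied to training batches only; the validation set is used solely for
    the loss history.  Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    X, y = _as_xy(train_set)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if X.shape[1] != cfg.n_bands:
        raise ValueError(f"spectra length {X.shape[1]} != n_bands {cfg.n_bands}")
    Xv = yv = None
    if val_set is not None:
        Xv, yv = _as_xy(val_set)

    if cfg.center_output_init:
        # start the output at the training-label mean so Adam fits residuals
        model.fc2.params["b"][:] = y.mean()

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A41]))
    adam = _Adam(model)
    history = TrainingHistory()
    n = X.shape[0]
    sds = X.std(axis=1)

    for epoch in range(cfg.epochs):
        lr = cosine_annealing_lr(epoch, cfg)
        order = rng.permutation(n)
        if augment is not None:
            a = rng.uniform(augment.slope_low, augment.slope_high, size=n)
            b = rng.uniform(-1.0, 1.0, size=n) * augment.offset_factor * sds
            if augment_mode == "global":
                Xe = a[:, None] * X + b[:, None]
            elif augment_mode == "tilt":
                ramp = np.linspace(0.0, 1.0, cfg.n_bands)[None, :]
                Xe = (1.0 + (a[:, None] - 1.0) * ramp) * X + b[:, None]
            else:
                raise ValueError(f"unknown augmentation mode {augment_mode!r}")
        else:
            Xe = X
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, dpred = _loss_and_grad(model, Xe[idx], y[idx], cfg.l2_coefficient)
            model._backward(dpred)
            if cfg.l2_coefficient > 0:
                for layer, name, arr in model.parameters():
                    if name == "W":
                        layer.grads[name] += 2.0 * cfg.l2_coefficient * arr
            adam.step(model, lr)
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)
        history.learning_rate.append(lr)
        if Xv is not None:
            pred_v = model._forward(Xv)
            history.val_loss.append(float(np.mean((pred_v - yv) ** 2)))
        else:
            history.val_loss.append(float("nan"))
    return model, history
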