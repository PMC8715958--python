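"""Compact 3-D convolutional classifier for impaired/healthy FDG-PET.

The network is a short stack of [3x3x3 conv (stride 1, same padding) ->
batch norm -> ReLU] blocks, each followed by 2x2x2 max pooling, with the
filter count doubling from ``base_filters`` up to ``max_filters``.  Instead
of stacked fully connected layers, a 1x1x1 convolution summarises the
channel features before a single-unit sigmoid output — the design that
keeps the trainable parameter count in the hundreds of thousands rather
than hundreds of millions for whole-volume input.

Training uses Adam on binary cross-entropy with mini-batches of 4 and an
early-stopping rule on the *training* loss (stop when it has not improved
by at least ``min_delta`` for ``patience`` consecutive epochs).

The engine is written directly on numpy: convolutions run as im2col + BLAS
matrix products, and the input gradient of a convolution is computed as a
transposed-kernel convolution of the output gradient, which keeps every
matrix product fat enough for BLAS.  All randomness (weight init, batch
shuffling) derives from the training seed, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .petprep import BrainVolume


class NetworkError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    Filters at block ``b`` are ``min(base_filters * 2**b, max_filters)``.
    ``head_channels = 0`` ablates the 1x1x1 head (flatten feeds the dense
    output directly).
    """

    input_edge: int = 96
    n_blocks: int = 4
    base_filters: int = 16
    max_filters: int = 128
    convs_per_block: int = 1
    head_channels: int = 64

    def __post_init__(self) -> None:
        if self.input_edge % (2**self.n_blocks) != 0:
            raise NetworkError(
                f"input edge {self.input_edge} not divisible by 2^{self.n_blocks}"
            )
        if min(self.base_filters, self.max_filters, self.convs_per_block) < 1:
            raise NetworkError("filters and convs per block must be >= 1")

    @property
    def block_filters(self) -> tuple[int, ...]:
        return tuple(
            min(self.base_filters * 2**b, self.max_filters)
            for b in range(self.n_blocks)
        )

    @property
    def final_edge(self) -> int:
        return self.input_edge // 2**self.n_blocks

    @property
    def feature_length(self) -> int:
        channels = self.head_channels or self.block_filters[-1]
        return self.final_edge**3 * channels


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, binary cross-entropy)."""

    learning_rate: float = 0.001
    batch_size: int = 4
    early_stop_min_delta: float = 0.01
    early_stop_patience: int = 10
    max_epochs: int = 100
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(
            self.learning_rate, self.batch_size, self.early_stop_min_delta,
            self.early_stop_patience, self.max_epochs,
        ) <= 0:
            raise NetworkError("all training parameters must be positive")
        if not (0.0 < self.decision_threshold < 1.0):
            raise NetworkError("decision threshold must lie in (0, 1)")


class EarlyStopping:
    """Stop when the monitored loss has not improved by ``min_delta``
    for ``patience`` consecutive epochs."""

    def __init__(self, min_delta: float, patience: int) -> None:
        self.min_delta = min_delta
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def update(self, loss: float) -> bool:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.wait = 0
        else:
            self.wait += 1
        return self.wait >= self.patience


# --------------------------------------------------------------------------
# layers


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = None
        self.m = None
        self.v = None


def _im2col(xp: np.ndarray, k: int, out: np.ndarray) -> None:
    """Fill ``out`` (N, C*k^3, P) from the padded grid ``xp``."""
    N, C, Dp, Hp, Wp = xp.shape
    D, H, W = Dp - k + 1, Hp - k + 1, Wp - k + 1
    view = out.reshape(N, C, k**3, D, H, W)
    i = 0
    for a in range(k):
        for b in range(k):
            for c in range(k):
                view[:, :, i] = xp[:, :, a : a + D, b : b + H, c : c + W]
                i += 1


class _Conv3D:
    """Same-padding 3-D convolution, kernel k x k x k, stride 1.

    Weights are stored as (c_out, c_in * k^3) with the kernel offset as the
    fastest index.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, compute_dx: bool = True):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.compute_dx = compute_dx
        self.w = _Param(np.zeros((c_out, c_in * kernel**3)))
        self.b = _Param(np.zeros(c_out))

    def initialize(self, rng: np.random.Generator, dtype) -> None:
        fan_in = self.c_in * self.k**3
        self.w.value = (
            rng.standard_normal((self.c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        ).astype(dtype)
        self.b.value = np.zeros(self.c_out, dtype=dtype)

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, D, H, W = x.shape
        P = D * H * W
        if self.k == 1:
            cols = x.reshape(N, C, P)
        else:
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
            cols = np.empty((N, C * self.k**3, P), dtype=x.dtype)
            _im2col(xp, self.k, cols)
        out = np.matmul(self.w.value, cols)
        out += self.b.value[:, None]
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(N, self.c_out, D, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        N, C, D, H, W = self._xshape
        P = D * H * W
        do = dout.reshape(N, self.c_out, P)
        self.w.grad = np.matmul(do, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad = do.sum(axis=(0, 2))
        self._cols = None
        if not self.compute_dx:
            return None
        if self.k == 1:
            return np.matmul(self.w.value.T, do).reshape(N, C, D, H, W)
        # input gradient as a transposed-kernel convolution of dout
        p = self.k // 2
        dop = np.pad(do.reshape(N, self.c_out, D, H, W),
                     ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((N, self.c_out * self.k**3, P), dtype=dout.dtype)
        _im2col(dop, self.k, cols)
        wt = (
            self.w.value.reshape(self.c_out, self.c_in, self.k**3)[:, :, ::-1]
            .transpose(1, 0, 2)
            .reshape(self.c_in, self.c_out * self.k**3)
        )
        return np.matmul(np.ascontiguousarray(wt), cols).reshape(N, C, D, H, W)

    def n_trainable(self) -> int:
        return self.w.value.size + self.b.value.size


class _BatchNorm3D:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = _Param(np.ones(channels))
        self.beta = _Param(np.zeros(channels))
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)

    def initialize(self, rng, dtype) -> None:
        self.gamma.value = np.ones(self.channels, dtype=dtype)
        self.beta.value = np.zeros(self.channels, dtype=dtype)
        self.run_mean = np.zeros(self.channels, dtype=dtype)
        self.run_var = np.ones(self.channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean = ((1 - m) * self.run_mean + m * mean).astype(x.dtype)
            self.run_var = ((1 - m) * self.run_var + m * var).astype(x.dtype)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
            self._xhat, self._inv = xhat, inv
            return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        inv = 1.0 / np.sqrt(self.run_var + self.eps)
        scale = (self.gamma.value * inv).reshape(shape)
        shift = (self.beta.value - self.gamma.value * self.run_mean * inv).reshape(shape)
        return x * scale + shift

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        xhat, inv = self._xhat, self._inv
        self._xhat = None
        m = dout.size / dout.shape[1]
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.gamma.grad, self.beta.grad = dgamma, dbeta
        coeff = (self.gamma.value * inv / m).reshape(shape)
        return coeff * (
            m * dout - dbeta.reshape(shape) - xhat * dgamma.reshape(shape)
        )

    def n_trainable(self) -> int:
        return 2 * self.channels


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * (self._out > 0)
        self._out = None
        return dx

    def n_trainable(self) -> int:
        return 0


_POOL_OFFSETS = [(i, j, k) for i in range(2) for j in range(2) for k in range(2)]


class _MaxPool3D:
    """2x2x2 max pooling via strided views.

    The backward pass routes the gradient to positions equal to the pooled
    maximum.  Exact ties only occur at ReLU zeros, whose gradient the
    upstream ReLU mask removes, so the duplication is inconsequential.
    """

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x[:, :, ::2, ::2, ::2].copy()
        for (i, j, k) in _POOL_OFFSETS[1:]:
            np.maximum(out, x[:, :, i::2, j::2, k::2], out=out)
        if train:
            self._x, self._out = x, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._x, self._out
        self._x = self._out = None
        dx = np.zeros_like(x)
        for (i, j, k) in _POOL_OFFSETS:
            sl = x[:, :, i::2, j::2, k::2]
            dx[:, :, i::2, j::2, k::2] = dout * (sl == out)
        return dx

    def n_trainable(self) -> int:
        return 0


class _Dense1:
    """Single-unit dense layer producing the classification logit."""

    def __init__(self, n_in: int):
        self.n_in = n_in
        self.w = _Param(np.zeros(n_in))
        self.b = _Param(np.zeros(1))

    def initialize(self, rng, dtype) -> None:
        self.w.value = (
            rng.standard_normal(self.n_in) / np.sqrt(self.n_in)
        ).astype(dtype)
        self.b.value = np.zeros(1, dtype=dtype)

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value[0]

    def backward(self, dz: np.ndarray) -> np.ndarray:
        self.w.grad = self._x.T @ dz
        self.b.grad = np.array([dz.sum()], dtype=dz.dtype)
        self._x = None
        return np.outer(dz, self.w.value)

    def n_trainable(self) -> int:
        return self.n_in + 1


# --------------------------------------------------------------------------
# network


class Net3D:
    """Model handle: ordered layers plus a flatten point before the dense
    output.  ``forward`` returns logits; probabilities are ``sigmoid``."""

    def __init__(self, spec: NetworkSpec, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.trained = False
        self.input_mean: np.ndarray | None = None
        self.input_scale: float = 1.0
        self.blocks: list = []
        c_in = 1
        for b, c_out in enumerate(spec.block_filters):
            for j in range(spec.convs_per_block):
                first = b == 0 and j == 0
                self.blocks.append(
                    _Conv3D(c_in, c_out, 3, compute_dx=not first)
                )
                self.blocks.append(_BatchNorm3D(c_out))
                self.blocks.append(_ReLU())
                c_in = c_out
            self.blocks.append(_MaxPool3D())
        if spec.head_channels:
            self.blocks.append(_Conv3D(c_in, spec.head_channels, 1))
            self.blocks.append(_ReLU())
        self.dense = _Dense1(spec.feature_length)
        self.initialize(np.random.default_rng(0))

    # -- lifecycle ---------------------------------------------------------

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.blocks:
            if hasattr(layer, "initialize"):
                layer.initialize(rng, self.dtype)
        self.dense.initialize(rng, self.dtype)
        self.trained = False

    def parameters(self):
        out = []
        for layer in self.blocks:
            out.extend(layer.params())
        out.extend(self.dense.params())
        return out

    def n_trainable(self) -> int:
        return sum(l.n_trainable() for l in self.blocks if hasattr(l, "n_trainable")) + self.dense.n_trainable()

    # -- passes ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        e = self.spec.input_edge
        if x.shape[1:] != (e, e, e):
            raise NetworkError(
                f"input shape {x.shape[1:]} does not match input edge {e}"
            )
        # per-volume intensity standardisation: cancels the global-scale
        # jitter a reference-region normalisation leaves behind
        flat = x.reshape(len(x), -1)
        mean = flat.mean(axis=1)[:, None, None, None]
        sd = flat.std(axis=1)[:, None, None, None]
        x = (x - mean) / np.maximum(sd, np.asarray(1e-7, dtype=self.dtype))
        # mean-image centring (classical mean subtraction, fitted on the
        # training set): volumes of one template share almost all of their
        # structure, and without removing it the between-sample signal is
        # far below the optimiser's gradient noise
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_scale
        return x[:, None]  # add channel axis

    def fit_input_scaling(self, volumes: np.ndarray) -> None:
        """Fit the mean-image centring on (training) volumes."""
        x = np.asarray(volumes, dtype=self.dtype)
        flat = x.reshape(len(x), -1)
        mean = flat.mean(axis=1)[:, None, None, None]
        sd = np.maximum(
            flat.std(axis=1)[:, None, None, None],
            np.asarray(1e-7, dtype=self.dtype),
        )
        z = (x - mean) / sd
        self.input_mean = z.mean(axis=0)
        self.input_scale = float(max(float((z - self.input_mean).std()), 1e-7))

    def forward(self, x: np.ndarray, train: bool = False,
                return_features: bool = False) -> np.ndarray:
        h = self._check_input(x)
        for layer in self.blocks:
            h = layer.forward(h, train)
        feats = h.reshape(h.shape[0], -1)
        if return_features:
            return feats
        return self.dense.forward(feats, train)

    def backward(self, dlogit: np.ndarray) -> None:
        dh = self.dense.backward(dlogit)
        n = dh.shape[0]
        # restore the pre-flatten spatial shape
        e = self.spec.final_edge
        c = self.spec.head_channels or self.spec.block_filters[-1]
        dh = dh.reshape(n, c, e, e, e)
        for layer in reversed(self.blocks):
            dh = layer.backward(dh)


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> Net3D:
    """Construct and He-initialise the classifier for a given spec."""
    model = Net3D(spec, dtype=dtype)
    model.initialize(np.random.default_rng(seed))
    return model


def parameter_breakdown(spec: NetworkSpec) -> dict:
    """Closed-form trainable-parameter counts per component.

    Each 3x3x3 conv holds ``f_out * (27 f_in + 1)`` weights, each batch
    norm ``2 f_out``; the 1x1x1 head ``head * (f_last + 1)``; the dense
    output ``final_edge^3 * channels + 1``.
    """
    conv_bn = 0
    c_in = 1
    for c_out in spec.block_filters:
        for _ in range(spec.convs_per_block):
            conv_bn += c_out * (27 * c_in + 1) + 2 * c_out
            c_in = c_out
    head = spec.head_channels * (c_in + 1) if spec.head_channels else 0
    dense = spec.feature_length + 1
    return {"conv_bn": conv_bn, "head": head, "dense": dense,
            "total": conv_bn + head + dense}


def count_parameters(spec: NetworkSpec) -> int:
    return parameter_breakdown(spec)["total"]


# --------------------------------------------------------------------------
# training


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        for p in params:
            p.m = np.zeros_like(p.value)
            p.v = np.zeros_like(p.value)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            g = p.grad
            p.m += (1 - self.b1) * (g - p.m)
            p.v += (1 - self.b2) * (g * g - p.v)
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def _as_array(volumes) -> np.ndarray:
    if isinstance(volumes, np.ndarray):
        return volumes
    return np.stack([
        v.data if isinstance(v, BrainVolume) else np.asarray(v) for v in volumes
    ])


def train(
    model: Net3D,
    volumes,
    labels,
    config: TrainConfig,
    val_volumes=None,
    val_labels=None,
) -> dict:
    """Fit the classifier; returns the loss history.

    Labels are 1 = impaired, 0 = healthy.  Weight initialisation and batch
    shuffling both derive from ``config.seed``.  An optional validation set
    is evaluated per epoch for monitoring only; early stopping watches the
    training loss.
    """
    x = _as_array(volumes).astype(model.dtype, copy=False)
    y = np.asarray(labels, dtype=model.dtype)
    if np.unique(y).size < 2:
        raise TrainingError("training requires both classes present")

    rng = np.random.default_rng(config.seed)
    model.initialize(rng)
    model.fit_input_scaling(x)
    optim = _Adam(model.parameters(), config.learning_rate)
    stopper = EarlyStopping(config.early_stop_min_delta, config.early_stop_patience)
    history = {"train_loss": [], "val_loss": []}

    n = len(y)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = model.forward(x[idx], train=True)
            yb = y[idx]
            losses.append(_bce_with_logits(z, yb))
            dz = ((_sigmoid(z) - yb) / len(idx)).astype(model.dtype)
            model.backward(dz)
            optim.step()
        epoch_loss = float(np.mean(losses))
        history["train_loss"].append(epoch_loss)
        if val_volumes is not None:
            zv = predict(model, val_volumes, _trained_ok=True, logits=True)
            history["val_loss"].append(
                _bce_with_logits(zv, np.asarray(val_labels, dtype=model.dtype))
            )
        if stopper.update(epoch_loss):
            break
    model.trained = True
    return history


def predict(
    model: Net3D, volumes, batch_size: int = 8,
    _trained_ok: bool = False, logits: bool = False,
) -> np.ndarray:
    """Per-volume impairment probability, order-preserving and
    batch-size independent (batch norm runs in eval mode)."""
    x = _as_array(volumes)
    out = np.empty(len(x), dtype=np.float64)
    for start in range(0, len(x), batch_size):
        z = model.forward(x[start : start + batch_size], train=False)
        out[start : start + len(z)] = z
    return out if logits else _sigmoid(out)


def extract_features(model: Net3D, volumes, batch_size: int = 8) -> np.ndarray:
    """Flatten-layer feature vectors (the penultimate representation)."""
    if not model.trained:
        raise TrainingError("extract_features requires a trained model")
    x = _as_array(volumes)
    out = np.empty((len(x), model.spec.feature_length), dtype=np.float64)
    for start in range(0, len(x), batch_size):
        f = model.forward(x[start : start + batch_size], train=False,
                          return_features=True)
        out[start : start + len(f)] = f
    return out


def diagnose_uncertain(
    model: Net3D, volumes, threshold: float = 0.5
) -> "pd.DataFrame":
    """Diagnose uncertain samples: impaired iff probability >= threshold."""
    import pandas as pd

    if not model.trained:
        raise TrainingError("diagnose_uncertain requires a trained model")
    probs = predict(model, volumes)
    return pd.DataFrame({
        "diagnosis": np.where(probs >= threshold, "impaired", "healthy"),
        "diagnosis_prob": probs,
    })


# --------------------------------------------------------------------------
# serialization


def save_model(model: Net3D, path) -> None:
    """Checkpoint weights plus the architecture spec (JSON header)."""
    import json as _json
    from dataclasses import asdict as _asdict

    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"p{i}"] = p.value
    for i, layer in enumerate(model.blocks):
        if isinstance(layer, _BatchNorm3D):
            arrays[f"rm{i}"] = layer.run_mean
            arrays[f"rv{i}"] = layer.run_var
    if model.input_mean is not None:
        arrays["input_mean"] = model.input_mean
        arrays["input_scale"] = np.array(model.input_scale)
    np.savez(
        path,
        spec=_json.dumps(_asdict(model.spec)),
        trained=np.array(model.trained),
        **arrays,
    )


def load_model(path) -> Net3D:
    import json as _json

    with np.load(path, allow_pickle=False) as data:
        spec = NetworkSpec(**_json.loads(str(data["spec"])))
        model = Net3D(spec)
        for i, p in enumerate(model.parameters()):
            p.value = data[f"p{i}"]
        for i, layer in enumerate(model.blocks):
            if isinstance(layer, _BatchNorm3D):
                layer.run_mean = data[f"rm{i}"]
                layer.run_var = data[f"rv{i}"]
        model.trained = bool(data["trained"])
        if "input_mean" in data:
            model.input_mean = data["input_mean"]
            model.input_scale = float(data["input_scale"])
    return model


# --------------------------------------------------------------------------
# baseline comparators

BASELINE_KINDS = (
    "mlp3", "c_svm_linear", "c_svm_rbf", "nu_svm_linear", "nu_svm_rbf",
    "linear_reg", "logistic_reg",
)


class BaselineScorer:
    """Classical comparator fitted on masked-voxel feature vectors.

    ``scores`` returns a real decision value per sample (higher = more
    likely impaired); ``predict`` thresholds it (linear regression at its
    fitted value 0.5, margin classifiers at 0).
    """

    def __init__(self, kind: str, estimator, threshold: float):
        self.kind = kind
        self.estimator = estimator
        self.threshold = threshold

    def scores(self, features) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(features), dtype=float)
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(features)[:, 1], dtype=float)
        return np.asarray(est.predict(features), dtype=float)

    def predict(self, features) -> np.ndarray:
        return (self.scores(features) >= self.threshold).astype(int)


def fit_baseline(kind: str, features, labels, seed: int = 0) -> BaselineScorer:
    from sklearn.linear_model import LinearRegression, LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC, NuSVC

    features = np.asarray(features)
    labels = np.asarray(labels)
    threshold = 0.0
    if kind == "mlp3":
        est = MLPClassifier(
            hidden_layer_sizes=(64, 32, 16), random_state=seed, max_iter=500,
        )
    elif kind == "c_svm_linear":
        est = SVC(kernel="linear", random_state=seed)
    elif kind == "c_svm_rbf":
        est = SVC(kernel="rbf", random_state=seed)
    elif kind == "nu_svm_linear":
        est = NuSVC(kernel="linear", random_state=seed)
    elif kind == "nu_svm_rbf":
        est = NuSVC(kernel="rbf", random_state=seed)
    elif kind == "linear_reg":
        est = LinearRegression()
        threshold = 0.5
    elif kind == "logistic_reg":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    else:
        raise NetworkError(f"unknown baseline kind {kind!r}; one of {BASELINE_KINDS}")
    est.fit(features, labels)
    if kind == "mlp3":
        threshold = 0.5  # probability of the impaired class
    return BaselineScorer(kind, est, threshold)
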