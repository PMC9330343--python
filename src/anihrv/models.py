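"""Compact MLP and LSTM regressors predicting pain scores from (100 - ANI).

The input feature is the per-second opposite of the ANI.  It is standardized
with training-set statistics (z = (x - mu) / sigma), cut into non-overlapping
10-s windows, and each window's consensus pain score at its final second is
the regression target.  Both networks end in a sigmoid, so labels are
trained on the 0-1 scale (divided by 100) and predictions are scaled back;
losses are mean absolute error, reported on the 0-100 scale.

Architectures:

* MLP: 10 -> 32 -> 32 -> 1; each hidden layer is affine -> batch
  normalization -> sigmoid; Adam, lr 0.001, batch 32, 30 epochs.
* LSTM: the 10-step univariate sequence through two stacked 32-unit LSTM
  layers (standard forget/input/output gates), batch normalization of each
  layer's output sequence, sigmoid head on the last step; Adamax, lr 0.001,
  batch 32, 15 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from anihrv._autograd import Adam, Adamax, Tensor, concat, sigmoid, tanh

__all__ = [
    "StandardizationParams",
    "FeatureWindowSet",
    "ModelSpec",
    "TrainedModel",
    "fit_standardizer",
    "apply_standardizer",
    "make_feature_windows",
    "concat_window_sets",
    "train_mlp",
    "train_lstm",
    "predict",
]

WINDOW_LEN = 10
LABEL_SCALE = 100.0


@dataclass(frozen=True)
class StandardizationParams:
    """Training-set mean and SD used to standardize every split."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class FeatureWindowSet:
    """Non-overlapping 10-s feature windows paired with their labels.

    ``windows`` has shape (n, 10): the (100 - ANI) values from t-9 to t.
    ``labels`` holds the consensus pain score at t.  ``patient_ids`` tags
    each window for patient-wise error aggregation.
    """

    windows: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        y = np.asarray(self.labels, dtype=float)
        pid = np.asarray(self.patient_ids)
        if w.ndim != 2 or w.shape[1] != WINDOW_LEN:
            raise ValueError(f"windows must be (n, {WINDOW_LEN})")
        if y.shape != (w.shape[0],) or pid.shape != (w.shape[0],):
            raise ValueError("labels/patient_ids must align with windows")
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "patient_ids", pid)

    def __len__(self) -> int:
        return int(self.windows.shape[0])


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training recipe for one regressor."""

    kind: str = "mlp"  # "mlp" | "lstm"
    hidden_width: int = 32
    depth: int = 2
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int | None = None  # 30 for MLP, 15 for LSTM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "lstm"):
            raise ValueError("kind must be 'mlp' or 'lstm'")
        if self.hidden_width < 1 or self.depth < 1:
            raise ValueError("width/depth must be positive")
        if self.epochs is None:
            object.__setattr__(self, "epochs", 30 if self.kind == "mlp" else 15)
        if self.epochs < 1:
            raise ValueError("epochs must be positive")

    @property
    def optimizer(self) -> str:
        return "adam" if self.kind == "mlp" else "adamax"


@dataclass
class TrainedModel:
    """A fitted network with its recipe and per-epoch loss history (x100)."""

    spec: ModelSpec
    net: "_MLPNet | _LSTMNet"
    history: list  # list of dicts: {"epoch", "train_loss", "val_loss"}


def fit_standardizer(train_features: np.ndarray) -> StandardizationParams:
    """Mean/SD of the training-set feature values (and only the training set)."""
    x = np.asarray(train_features, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty training features")
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    if sigma == 0.0:
        raise ValueError("training features have zero variance")
    return StandardizationParams(mu=mu, sigma=sigma)


def apply_standardizer(p: StandardizationParams, x: np.ndarray) -> np.ndarray:
    """z = (x - mu) / sigma, elementwise."""
    return (np.asarray(x, dtype=float) - p.mu) / p.sigma


def make_feature_windows(opposite_ani: np.ndarray, labels, patient_id: str = "") -> FeatureWindowSet:
    """Cut aligned 1-Hz series into non-overlapping 10-s windows.

    Window k holds feature seconds 10k .. 10k+9 and is labeled by the pain
    score at second 10k+9; the trailing remainder (< 10 s) is dropped.
    """
    x = np.asarray(opposite_ani, dtype=float)
    y = np.asarray(getattr(labels, "eaps", labels), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and label series must be aligned 1-d arrays")
    n_win = x.size // WINDOW_LEN
    if n_win == 0:
        raise ValueError(f"series shorter than {WINDOW_LEN} s")
    w = x[: n_win * WINDOW_LEN].reshape(n_win, WINDOW_LEN)
    lab = y[WINDOW_LEN - 1 : n_win * WINDOW_LEN : WINDOW_LEN]
    return FeatureWindowSet(windows=w, labels=lab, patient_ids=np.full(n_win, patient_id, dtype=object))


def concat_window_sets(sets: list) -> FeatureWindowSet:
    sets = [s for s in sets if len(s) > 0]
    if not sets:
        raise ValueError("no windows")
    return FeatureWindowSet(
        windows=np.vstack([s.windows for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        patient_ids=np.concatenate([s.patient_ids for s in sets]),
    )


# --------------------------------------------------------------------------
# layers


class _Linear:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(1, fan_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class _BatchNorm:
    """Per-feature batch normalization: batch statistics while training,
    exponential running statistics at inference."""

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, width)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, width)), requires_grad=True)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbias = n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbias * var.data.ravel()
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean[None, :]) * ((self.running_var[None, :] + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class _MLPNet:
    """10 -> (affine -> BN -> sigmoid) x depth -> affine -> sigmoid."""

    def __init__(self, spec: ModelSpec, n_inputs: int = WINDOW_LEN):
        rng = np.random.default_rng(spec.seed)
        widths = [n_inputs] + [spec.hidden_width] * spec.depth
        self.linears = [_Linear(widths[i], widths[i + 1], rng) for i in range(spec.depth)]
        self.norms = [_BatchNorm(spec.hidden_width) for _ in range(spec.depth)]
        self.head = _Linear(widths[-1], 1, rng)

    def forward(self, x: np.ndarray, training: bool) -> Tensor:
        h = Tensor(x)
        for lin, bn in zip(self.linears, self.norms):
            h = sigmoid(bn(lin(h), training))
        return sigmoid(self.head(h))

    @property
    def params(self):
        out = []
        for lin, bn in zip(self.linears, self.norms):
            out += lin.params + bn.params
        return out + self.head.params


class _LSTMLayer:
    """Standard LSTM: gates i, f, o with sigmoid; candidate and cell output tanh."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_hidden)
        self.n_hidden = n_hidden
        self.Wx = Tensor(rng.uniform(-bound, bound, size=(n_in, 4 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.uniform(-bound, bound, size=(n_hidden, 4 * n_hidden)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(1, 4 * n_hidden)), requires_grad=True)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple:
        z = x_t @ self.Wx + h @ self.Wh + self.b
        H = self.n_hidden
        i = sigmoid(z[:, 0 * H : 1 * H])
        f = sigmoid(z[:, 1 * H : 2 * H])
        g = tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H : 4 * H])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new

    def forward_seq(self, xs: list) -> list:
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.n_hidden)))
        c = Tensor(np.zeros((batch, self.n_hidden)))
        out = []
        for x_t in xs:
            h, c = self.step(x_t, h, c)
            out.append(h)
        return out

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]


class _LSTMNet:
    """Two stacked LSTM layers, BN of each layer's output sequence, sigmoid head."""

    def __init__(self, spec: ModelSpec, n_steps: int = WINDOW_LEN):
        rng = np.random.default_rng(spec.seed)
        self.n_steps = n_steps
        widths = [1] + [spec.hidden_width] * spec.depth
        self.layers = [_LSTMLayer(widths[i], widths[i + 1], rng) for i in range(spec.depth)]
        self.norms = [_BatchNorm(spec.hidden_width) for _ in range(spec.depth)]
        self.head = _Linear(spec.hidden_width, 1, rng)

    def forward(self, x: np.ndarray, training: bool) -> Tensor:
        batch, T = x.shape
        xs = [Tensor(x[:, t : t + 1]) for t in range(T)]
        for layer, bn in zip(self.layers, self.norms):
            hs = layer.forward_seq(xs)
            # normalize the layer's output sequence jointly over batch and time
            flat = bn(concat(hs, axis=0), training)
            xs = [flat[t * batch : (t + 1) * batch, :] for t in range(T)]
        return sigmoid(self.head(xs[-1]))

    @property
    def params(self):
        out = []
        for layer, bn in zip(self.layers, self.norms):
            out += layer.params + bn.params
        return out + self.head.params


# --------------------------------------------------------------------------
# training


def _mae_loss(pred: Tensor, target01: np.ndarray) -> Tensor:
    return (pred - target01.reshape(-1, 1)).abs().mean()


def _eval_loss(net, x: np.ndarray, y: np.ndarray) -> float:
    """Full-set MAE (0-100 scale) in inference mode."""
    pred = net.forward(x, training=False).data.ravel() * LABEL_SCALE
    return float(np.mean(np.abs(pred - y)))


def _train(net, spec: ModelSpec, train: FeatureWindowSet, val: FeatureWindowSet | None) -> TrainedModel:
    if len(train) == 0:
        raise ValueError("empty training set")
    x, y = train.windows, train.labels
    opt_cls = Adam if spec.optimizer == "adam" else Adamax
    opt = opt_cls(net.params, lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(len(train))
        batch_losses = []
        for lo in range(0, len(train), spec.batch_size):
            idx = order[lo : lo + spec.batch_size]
            opt.zero_grad()
            pred = net.forward(x[idx], training=True)
            loss = _mae_loss(pred, y[idx] / LABEL_SCALE)
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data) * LABEL_SCALE)
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(batch_losses))}
        if val is not None and len(val) > 0:
            entry["val_loss"] = _eval_loss(net, val.windows, val.labels)
        history.append(entry)
    return TrainedModel(spec=spec, net=net, history=history)


def train_mlp(train: FeatureWindowSet, val: FeatureWindowSet | None, spec: ModelSpec | None = None) -> TrainedModel:
    """Train the feedforward regressor (Adam, 30 epochs by default).

    Features must already be standardized with training-set statistics;
    labels are on the 0-100 scale and are divided by 100 internally.
    """
    spec = spec or ModelSpec(kind="mlp")
    if spec.kind != "mlp":
        raise ValueError("spec.kind must be 'mlp'")
    return _train(_MLPNet(spec), spec, train, val)


def train_lstm(train: FeatureWindowSet, val: FeatureWindowSet | None, spec: ModelSpec | None = None) -> TrainedModel:
    """Train the stacked-LSTM regressor (Adamax, 15 epochs by default)."""
    spec = spec or ModelSpec(kind="lstm")
    if spec.kind != "lstm":
        raise ValueError("spec.kind must be 'lstm'")
    return _train(_LSTMNet(spec), spec, train, val)


def predict(m: TrainedModel, windows: np.ndarray | FeatureWindowSet) -> np.ndarray:
    """Predicted pain scores (0-100), one per window, in inference mode."""
    x = windows.windows if isinstance(windows, FeatureWindowSet) else np.asarray(windows, dtype=float)
    if x.ndim != 2 or x.shape[1] != WINDOW_LEN:
        raise ValueError(f"windows must be (n, {WINDOW_LEN})")
    return m.net.forward(x, training=False).data.ravel() * LABEL_SCALE
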