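"""Feed-forward network trained by Levenberg-Marquardt for response prediction.

A single-hidden-layer network (k inputs, H sigmoidal hidden units, one linear
output) maps medium composition to a fermentation response:

    f(x) = w2 . act(W1 x + b1) + b2

Training minimizes squared error on a random 70/15/15 train/validation/test
split of the runs with the damped Gauss-Newton (Levenberg-Marquardt) update

    (J'J + mu I) delta = J'e,

where J is the analytic Jacobian of the outputs with respect to all weights.
The damping mu shrinks after each accepted step and grows on rejection, so
the iteration moves between gradient descent (large mu) and Gauss-Newton
(small mu).  Rising validation error stops training early and the weights of
the best validation epoch are returned.

Inputs and targets are min-max normalized to [-1, +1] before training and
predictions are mapped back to the original response scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetSpec", "NetFit", "AnnModel", "normalize", "denormalize",
           "RangeScaler", "split_data", "forward", "jacobian", "train_lm",
           "fit_ann"]


def normalize(x, xmin: float, xmax: float):
    """Affine map of [xmin, xmax] onto [-1, +1]: (2x - (xmax+xmin))/(xmax-xmin)."""
    if not xmax > xmin:
        raise ValueError("xmax must exceed xmin")
    return (2.0 * np.asarray(x, dtype=float) - (xmax + xmin)) / (xmax - xmin)


def denormalize(y, xmin: float, xmax: float):
    """Inverse of :func:`normalize`."""
    if not xmax > xmin:
        raise ValueError("xmax must exceed xmin")
    return (np.asarray(y, dtype=float) * (xmax - xmin) + (xmax + xmin)) / 2.0


class RangeScaler:
    """Per-column min-max normalization to [-1, +1] with exact inverse."""

    def __init__(self):
        self.xmin: np.ndarray | None = None
        self.xmax: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "RangeScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.xmin = X.min(axis=0)
        self.xmax = X.max(axis=0)
        if np.any(self.xmax <= self.xmin):
            raise ValueError("constant column cannot be range-normalized")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (2.0 * np.asarray(X, dtype=float) - (self.xmax + self.xmin)) / (self.xmax - self.xmin)

    def inverse(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) * (self.xmax - self.xmin) + (self.xmax + self.xmin)) / 2.0


def split_data(n: int, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Random disjoint train/validation/test index sets covering range(n).

    Validation and test sizes are the rounded fractions of n; training takes
    the remainder (50 runs -> 34/8/8).  Deterministic for a given seed.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    n_val = int(np.floor(fractions[1] * n + 0.5))
    n_test = int(np.floor(fractions[2] * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return (np.sort(perm[:n - n_val - n_test]),
            np.sort(perm[n - n_val - n_test:n - n_test]),
            np.sort(perm[n - n_test:]))


@dataclass
class NetSpec:
    """Architecture and training hyperparameters."""

    n_inputs: int = 5
    n_hidden: int = 12
    activation: str = "tanh"        # "tanh" or "logistic"
    fractions: tuple = (0.70, 0.15, 0.15)
    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    mu_max: float = 1e10
    max_validation_failures: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")
        if self.activation not in ("tanh", "logistic"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass
class NetFit:
    """Trained weights plus the split and per-set goodness of fit."""

    spec: NetSpec
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    idx_train: np.ndarray = field(default_factory=lambda: np.array([], int))
    idx_val: np.ndarray = field(default_factory=lambda: np.array([], int))
    idx_test: np.ndarray = field(default_factory=lambda: np.array([], int))
    mse: dict = field(default_factory=dict)
    r2: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)   # (epoch, mu, train_mse, val_mse)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.__dict__ | {"fractions": list(self.spec.fractions)},
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "split": {"train": self.idx_train.tolist(), "val": self.idx_val.tolist(),
                      "test": self.idx_test.tolist()},
            "mse": self.mse, "r2": self.r2, "best_epoch": self.best_epoch,
        }


def _activation(name: str):
    if name == "tanh":
        return np.tanh, lambda h: 1.0 - h ** 2
    return (lambda z: 1.0 / (1.0 + np.exp(-z))), lambda h: h * (1.0 - h)


def forward(fit: NetFit, X: np.ndarray) -> np.ndarray:
    """Network outputs for normalized inputs X (n x k or length-k vector)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != fit.W1.shape[1]:
        raise ValueError(f"expected {fit.W1.shape[1]} inputs, got {X.shape[1]}")
    act, _ = _activation(fit.spec.activation)
    H = act(X @ fit.W1.T + fit.b1)
    return H @ fit.w2 + fit.b2


def jacobian(fit: NetFit, X: np.ndarray) -> np.ndarray:
    """Analytic d out / d theta, theta = (W1 rows, b1, w2, b2); shape n x p."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    act, dact = _activation(fit.spec.activation)
    H = act(X @ fit.W1.T + fit.b1)          # n x Hn
    G = dact(H) * fit.w2                    # n x Hn, dout/dz_j
    n = len(X)
    JW1 = (G[:, :, None] * X[:, None, :]).reshape(n, -1)
    return np.hstack([JW1, G, H, np.ones((n, 1))])


def _pack(fit: NetFit) -> np.ndarray:
    return np.concatenate([fit.W1.ravel(), fit.b1, fit.w2, [fit.b2]])


def _unpack(theta: np.ndarray, spec: NetSpec) -> tuple:
    H, k = spec.n_hidden, spec.n_inputs
    W1 = theta[:H * k].reshape(H, k)
    b1 = theta[H * k:H * k + H]
    w2 = theta[H * k + H:H * k + 2 * H]
    b2 = float(theta[-1])
    return W1, b1, w2, b2


def _init(spec: NetSpec, rng: np.random.Generator) -> np.ndarray:
    H, k = spec.n_hidden, spec.n_inputs
    W1 = rng.uniform(-0.5, 0.5, (H, k)) / np.sqrt(k)
    b1 = rng.uniform(-0.5, 0.5, H)
    w2 = rng.uniform(-0.5, 0.5, H) / np.sqrt(H)
    b2 = rng.uniform(-0.5, 0.5)
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else float("nan")


def train_lm(spec: NetSpec, X: np.ndarray, y: np.ndarray) -> NetFit:
    """Levenberg-Marquardt training on normalized data, with early stopping.

    X and y are expected on the [-1, +1] scale (see :func:`normalize`).  The
    returned fit carries the weights of the epoch with the lowest validation
    mse, the split indices and the training trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if k != spec.n_inputs:
        raise ValueError(f"spec expects {spec.n_inputs} inputs, data has {k}")
    idx_tr, idx_val, idx_te = split_data(n, spec.fractions, spec.seed)
    rng = np.random.default_rng(spec.seed)
    theta = _init(spec, rng)
    fit = NetFit(spec, *_unpack(theta, spec), idx_train=idx_tr,
                 idx_val=idx_val, idx_test=idx_te)
    Xtr, ytr = X[idx_tr], y[idx_tr]
    Xval, yval = X[idx_val], y[idx_val]

    def sse(th):
        W1, b1, w2, b2 = _unpack(th, spec)
        tmp = NetFit(spec, W1, b1, w2, b2)
        e = ytr - forward(tmp, Xtr)
        return float(e @ e), tmp

    mu = spec.mu0
    best_theta = theta.copy()
    cur_sse, cur_net = sse(theta)
    best_val = float(np.mean((yval - forward(cur_net, Xval)) ** 2)) if len(idx_val) else np.inf
    best_epoch = 0
    val_fail = 0
    p = len(theta)
    for epoch in range(1, spec.max_epochs + 1):
        e = ytr - forward(cur_net, Xtr)
        J = jacobian(cur_net, Xtr)
        JtJ = J.T @ J
        Jte = J.T @ e
        accepted = False
        while mu <= spec.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(p), Jte)
            except np.linalg.LinAlgError:
                mu *= spec.mu_up
                continue
            trial = theta + delta
            trial_sse, trial_net = sse(trial)
            if not np.isfinite(trial_sse):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; trace: {fit.trace[-5:]}")
            if trial_sse < cur_sse:
                theta, cur_sse, cur_net = trial, trial_sse, trial_net
                mu = max(mu * spec.mu_down, 1e-20)
                accepted = True
                break
            mu *= spec.mu_up
        if not accepted:
            break  # mu overflow: no descent direction left
        val_mse = float(np.mean((yval - forward(cur_net, Xval)) ** 2)) if len(idx_val) else np.nan
        fit.trace.append((epoch, mu, cur_sse / len(ytr), val_mse))
        if len(idx_val) == 0:
            best_theta, best_epoch = theta.copy(), epoch  # no early stopping
        elif val_mse < best_val:
            best_val, best_theta, best_epoch = val_mse, theta.copy(), epoch
            val_fail = 0
        else:
            val_fail += 1
            if val_fail >= spec.max_validation_failures:
                break
        if cur_sse / len(ytr) < 1e-14:
            if val_mse <= best_val:
                best_val, best_theta, best_epoch = val_mse, theta.copy(), epoch
            break

    if len(idx_val) == 0:  # no validation set: keep final weights
        best_theta = theta

    fit.W1, fit.b1, fit.w2, fit.b2 = _unpack(best_theta, spec)
    fit.best_epoch = best_epoch
    for name, idx in (("train", idx_tr), ("val", idx_val), ("test", idx_te),
                      ("overall", np.arange(n))):
        if len(idx) == 0:
            continue
        pred = forward(fit, X[idx])
        fit.mse[name] = float(np.mean((y[idx] - pred) ** 2))
        fit.r2[name] = _r2(y[idx], pred)
    return fit


@dataclass
class AnnModel:
    """Network plus the input/target scalers, predicting on the original scale."""

    net: NetFit
    x_scaler: RangeScaler
    y_scaler: RangeScaler

    def predict(self, X_actual: np.ndarray) -> np.ndarray:
        Z = self.x_scaler.transform(np.atleast_2d(np.asarray(X_actual, dtype=float)))
        out = forward(self.net, Z)
        return self.y_scaler.inverse(out[:, None]).ravel()

    def r2(self, subset: str = "overall") -> float:
        return self.net.r2[subset]


def fit_ann(X_actual: np.ndarray, y: np.ndarray, spec: NetSpec | None = None,
            **spec_kwargs) -> AnnModel:
    """Normalize, train and wrap: the convenience entry point for run tables."""
    X_actual = np.atleast_2d(np.asarray(X_actual, dtype=float))
    if spec is None:
        spec = NetSpec(n_inputs=X_actual.shape[1], **spec_kwargs)
    xs = RangeScaler().fit(X_actual)
    ys = RangeScaler().fit(np.asarray(y, dtype=float).reshape(-1, 1))
    net = train_lm(spec, xs.transform(X_actual),
                   ys.transform(np.asarray(y, dtype=float).reshape(-1, 1)).ravel())
    return AnnModel(net, xs, ys)
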