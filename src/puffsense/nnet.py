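"""Two-layer feedforward regressor trained with Levenberg-Marquardt.

Architecture 4 -> H -> 3: a sigmoid hidden layer (tanh by default, logistic
selectable) and a linear output layer.  Inputs and outputs are min-max
normalized to [-1, 1] with bounds fitted on the training split.  Training
minimizes the summed squared error of the normalized residuals with damped
Gauss-Newton steps

    (J^T J + mu I) delta = -J^T r

using an exact per-sample backprop Jacobian, an adaptive damping factor and
validation-based early stopping (the returned parameters are those of the
best validation epoch).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkParameters",
    "TrainingConfig",
    "TrainingHistory",
    "init_network",
    "count_parameters",
    "forward",
    "train_lm",
    "lm_step",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("tanh", "logistic")


def _sigma(z: np.ndarray, tag: str) -> np.ndarray:
    if tag == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))


def _sigma_prime(h: np.ndarray, tag: str) -> np.ndarray:
    # expressed in terms of the activation value h = sigma(z)
    if tag == "tanh":
        return 1.0 - h**2
    return h * (1.0 - h)


@dataclass
class NetworkParameters:
    """Weights, biases, normalization bounds and the activation tag."""

    hidden_weights: np.ndarray  # (H, n_in)
    hidden_bias: np.ndarray  # (H,)
    output_weights: np.ndarray  # (n_out, H)
    output_bias: np.ndarray  # (n_out,)
    input_min: np.ndarray | None = None
    input_max: np.ndarray | None = None
    output_min: np.ndarray | None = None
    output_max: np.ndarray | None = None
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        h, n_in = self.hidden_weights.shape
        if self.hidden_bias.shape != (h,):
            raise ValueError("hidden_bias shape mismatch")
        n_out = self.output_weights.shape[0]
        if self.output_weights.shape != (n_out, h):
            raise ValueError("output_weights shape mismatch")
        if self.output_bias.shape != (n_out,):
            raise ValueError("output_bias shape mismatch")

    @property
    def layer_size(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.output_weights.shape[0]

    @property
    def normalization_fitted(self) -> bool:
        return self.input_min is not None

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.hidden_weights.copy(),
            self.hidden_bias.copy(),
            self.output_weights.copy(),
            self.output_bias.copy(),
            None if self.input_min is None else self.input_min.copy(),
            None if self.input_max is None else self.input_max.copy(),
            None if self.output_min is None else self.output_min.copy(),
            None if self.output_max is None else self.output_max.copy(),
            self.activation,
        )

    # -- flat parameter vector (ordering: W1, b1, W2, b2) ------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.hidden_weights.ravel(),
                self.hidden_bias,
                self.output_weights.ravel(),
                self.output_bias,
            ]
        )

    def set_vector(self, vec: np.ndarray) -> None:
        h, n_in, n_out = self.layer_size, self.n_inputs, self.n_outputs
        i = 0
        self.hidden_weights = vec[i : i + h * n_in].reshape(h, n_in)
        i += h * n_in
        self.hidden_bias = vec[i : i + h]
        i += h
        self.output_weights = vec[i : i + n_out * h].reshape(n_out, h)
        i += n_out * h
        self.output_bias = vec[i : i + n_out]


def count_parameters(params: NetworkParameters) -> int:
    """H*n_in + H + n_out*H + n_out (= 67 for the default 4 -> 8 -> 3 net)."""
    h, n_in, n_out = params.layer_size, params.n_inputs, params.n_outputs
    return h * n_in + h + n_out * h + n_out


def init_network(
    layer_size: int = 8,
    n_inputs: int = 4,
    n_outputs: int = 3,
    seed: int | np.random.Generator | None = None,
    activation: str = "tanh",
) -> NetworkParameters:
    """Nguyen-Widrow-style initialization on the normalized [-1, 1] range."""
    if layer_size < 1:
        raise ValueError("layer_size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(layer_size, n_inputs))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    beta = 0.7 * layer_size ** (1.0 / n_inputs)
    w = beta * w / np.where(norms > 0, norms, 1.0)
    if layer_size > 1:
        b = beta * np.linspace(-1.0, 1.0, layer_size) * np.sign(w[:, 0])
    else:
        b = np.zeros(1)
    w2 = rng.uniform(-0.5, 0.5, size=(n_outputs, layer_size))
    b2 = np.zeros(n_outputs)
    return NetworkParameters(w, b, w2, b2, activation=activation)


# ---------------------------------------------------------------------------
# Normalization


def _fit_minmax(arr: np.ndarray):
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    span = hi - lo
    # constant columns map to 0 in normalized space
    hi = np.where(span > 0, hi, lo + 1.0)
    return lo, hi


def _normalize(arr: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return 2.0 * (arr - lo) / (hi - lo) - 1.0


def _denormalize(arr: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return (arr + 1.0) / 2.0 * (hi - lo) + lo


def fit_normalization(params: NetworkParameters, X: np.ndarray, Y: np.ndarray) -> None:
    params.input_min, params.input_max = _fit_minmax(np.asarray(X, dtype=float))
    params.output_min, params.output_max = _fit_minmax(np.asarray(Y, dtype=float))


# ---------------------------------------------------------------------------
# Forward pass and Jacobian


def _forward_normalized(params: NetworkParameters, xn: np.ndarray):
    z = xn @ params.hidden_weights.T + params.hidden_bias
    h = _sigma(z, params.activation)
    yn = h @ params.output_weights.T + params.output_bias
    return yn, h


def forward(params: NetworkParameters, features) -> np.ndarray:
    """Denormalized prediction for one feature vector or a batch."""
    if not params.normalization_fitted:
        raise ValueError("normalization bounds not fitted; train or load a model first")
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != params.n_inputs:
        raise ValueError(f"expected {params.n_inputs} features, got {x2.shape[1]}")
    xn = _normalize(x2, params.input_min, params.input_max)
    yn, _ = _forward_normalized(params, xn)
    y = _denormalize(yn, params.output_min, params.output_max)
    return y[0] if single else y


def _jacobian_and_residuals(params: NetworkParameters, xn: np.ndarray, tn: np.ndarray):
    """Residuals r = yn - tn (stacked over samples then outputs) and the
    exact Jacobian dr/dtheta, shape (n*n_out, P)."""
    n, n_in = xn.shape
    h_size, n_out = params.layer_size, params.n_outputs
    yn, h = _forward_normalized(params, xn)
    r = (yn - tn).reshape(-1)  # sample-major

    sp = _sigma_prime(h, params.activation)  # (n, H)
    # dyk/dW1[i,j] = W2[k,i] sp[i] x[j]; dyk/db1[i] = W2[k,i] sp[i]
    g = params.output_weights[None, :, :] * sp[:, None, :]  # (n, n_out, H)
    j_w1 = np.einsum("nkh,nj->nkhj", g, xn).reshape(n * n_out, h_size * n_in)
    j_b1 = g.reshape(n * n_out, h_size)
    # dyk/dW2[k,:] = h; dyk/db2[k] = 1
    eye = np.eye(n_out)
    j_w2 = np.einsum("kl,nh->nklh", eye, h).reshape(n * n_out, n_out * h_size)
    j_b2 = np.tile(eye, (n, 1))
    return np.concatenate([j_w1, j_b1, j_w2, j_b2], axis=1), r


def lm_step(J: np.ndarray, r: np.ndarray, mu: float) -> np.ndarray:
    """Solve the damped normal equations (J^T J + mu I) delta = -J^T r.

    mu = 0 gives the Gauss-Newton step; mu -> inf approaches -grad/mu
    (scaled gradient descent).
    """
    jtj = J.T @ J
    g = J.T @ r
    return np.linalg.solve(jtj + mu * np.eye(jtj.shape[0]), -g)


@dataclass(frozen=True)
class TrainingConfig:
    layer_size: int = 8
    train_fraction: float = 0.85
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_raise: float = 10.0
    mu_lower: float = 0.1
    mu_max: float = 1e10
    patience: int = 6
    min_gradient: float = 1e-10
    activation: str = "tanh"
    seed: int = 0
    split_seed: int | None = None  # None: derive the split from `seed`

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch normalized-scale MSEs and damping; lengths equal epochs run."""

    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    mu: list = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1

    @property
    def epochs_completed(self) -> int:
        return len(self.train_mse)


def train_lm(X, Y, config: TrainingConfig | None = None):
    """Train on paired features/targets; returns (params, history).

    The data are split (seeded permutation) into training and validation
    parts; the parameters returned are those at the best validation epoch.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching sample counts")
    n = X.shape[0]
    if n < 10:
        raise ValueError("at least 10 samples are required")
    if np.any(Y.max(axis=0) - Y.min(axis=0) == 0):
        raise ValueError("degenerate (constant) target column; nothing to fit")

    rng = np.random.default_rng(config.seed)
    split_rng = (
        rng if config.split_seed is None else np.random.default_rng(config.split_seed)
    )
    perm = split_rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    idx_train, idx_val = perm[:n_train], perm[n_train:]

    params = init_network(
        config.layer_size, X.shape[1], Y.shape[1], seed=rng, activation=config.activation
    )
    fit_normalization(params, X[idx_train], Y[idx_train])
    xn_train = _normalize(X[idx_train], params.input_min, params.input_max)
    tn_train = _normalize(Y[idx_train], params.output_min, params.output_max)
    xn_val = _normalize(X[idx_val], params.input_min, params.input_max)
    tn_val = _normalize(Y[idx_val], params.output_min, params.output_max)

    def val_mse(p):
        yn, _ = _forward_normalized(p, xn_val)
        return float(np.mean((yn - tn_val) ** 2))

    history = TrainingHistory()
    mu = config.mu_init
    best_val = math.inf
    best_params = params.copy()
    fails = 0
    theta = params.to_vector()
    J, r = _jacobian_and_residuals(params, xn_train, tn_train)
    sse = float(r @ r)

    for epoch in range(config.max_epochs):
        accepted = False
        while mu <= config.mu_max:
            delta = lm_step(J, r, mu)
            trial = theta + delta
            params.set_vector(trial)
            yn, _ = _forward_normalized(params, xn_train)
            trial_sse = float(np.sum((yn - tn_train.reshape(yn.shape)) ** 2))
            if trial_sse < sse:
                theta, sse = trial, trial_sse
                mu = max(mu * config.mu_lower, 1e-20)
                accepted = True
                break
            mu *= config.mu_raise
        if not accepted:
            params.set_vector(theta)
            history.stop_reason = "mu_overflow"
            break

        J, r = _jacobian_and_residuals(params, xn_train, tn_train)
        history.train_mse.append(sse / r.size)
        v = val_mse(params)
        history.val_mse.append(v)
        history.mu.append(mu)

        if v < best_val:
            best_val = v
            best_params = params.copy()
            history.best_epoch = epoch
            fails = 0
        else:
            fails += 1
        if fails >= config.patience:
            history.stop_reason = "validation_patience"
            break
        if np.linalg.norm(J.T @ r) < config.min_gradient:
            history.stop_reason = "min_gradient"
            break
    else:
        history.stop_reason = "max_epochs"

    return best_params, history


# ---------------------------------------------------------------------------
# Persistence (JSON, lossless round-trip)


def save_model(params: NetworkParameters, path) -> None:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    payload = {
        "format": "puffsense-nn",
        "version": 1,
        "activation": params.activation,
        "hidden_weights": arr(params.hidden_weights),
        "hidden_bias": arr(params.hidden_bias),
        "output_weights": arr(params.output_weights),
        "output_bias": arr(params.output_bias),
        "input_min": arr(params.input_min),
        "input_max": arr(params.input_max),
        "output_min": arr(params.output_min),
        "output_max": arr(params.output_max),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> NetworkParameters:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    required = ("format", "activation", "hidden_weights", "hidden_bias",
                "output_weights", "output_bias")
    missing = [k for k in required if k not in payload]
    if missing or payload.get("format") != "puffsense-nn":
        raise ValueError(f"{path}: not a puffsense model file (missing {missing})")

    def arr(key):
        v = payload.get(key)
        return None if v is None else np.asarray(v, dtype=float)

    return NetworkParameters(
        arr("hidden_weights"),
        arr("hidden_bias"),
        arr("output_weights"),
        arr("output_bias"),
        arr("input_min"),
        arr("input_max"),
        arr("output_min"),
        arr("output_max"),
        payload["activation"],
    )
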