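"""Small dense networks trained with Adam under a value-weighted squared error.

Each sub-network maps its predictor genes to its target genes through one
fully connected hidden layer (rectified linear), a training-time dropout
layer, and a softplus output layer, so predictions are non-negative in
log space by construction while every output entry keeps a nonzero
gradient (a hard-rectified output would freeze any entry whose
pre-activation goes negative). The loss for one cell is

    loss_c = sum_i  Y_i * (Y_i - Yhat_i)^2

which weights each target gene by its own (log) expression: zeros carry no
penalty, so the network is pushed to fit confidently measured values
rather than the missing ones it is meant to replace. Batches average this
per-cell loss.

Everything here is plain float32 numpy; the matrices involved (hundreds of
inputs, 256 hidden units, up to 512 outputs) are small enough that BLAS
matmuls dominate and a deep-learning framework would add nothing but
dependency weight.
"""

from __future__ import annotations

import numpy as np

from .io import ValidationError


def weighted_mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Value-weighted squared error for one cell: sum_i y_i (y_i - yhat_i)^2."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have the same shape")
    if y_true.size and y_true.min() < 0:
        raise ValidationError("weights (true values) must be non-negative")
    return float(np.sum(y_true * (y_true - y_pred) ** 2))


def batch_weighted_mse(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Mean over cells of the per-cell weighted squared error."""
    Y = np.asarray(Y, dtype=np.float64)
    Yhat = np.asarray(Yhat, dtype=np.float64)
    if Y.shape != Yhat.shape:
        raise ValidationError("shape mismatch")
    return float(np.mean(np.sum(Y * (Y - Yhat) ** 2, axis=1)))


class SubNetwork:
    """One per-subset dense network.

    Parameters
    ----------
    n_in, n_out : int
        Number of predictor and target genes.
    hidden_size : int
        Width of the single hidden layer (ignored for ``none_hidden``).
    dropout_rate : float
        Fraction of hidden units masked per training step.
    architecture : {"relu", "linear", "none_hidden"}
        ``relu`` is the standard model (ReLU hidden, softplus output);
        ``linear`` keeps the same layers with identity activations (output clipped at zero at imputation
        time); ``none_hidden`` is a single affine map.
    learning_rate : float
        Adam step size (beta1=0.9, beta2=0.999, eps=1e-8).
    seed : int
        Seeds weight initialisation, batch shuffling and dropout masks.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden_size: int = 256,
        dropout_rate: float = 0.2,
        architecture: str = "relu",
        learning_rate: float = 1e-4,
        seed: int = 0,
    ) -> None:
        if n_in < 1:
            raise ValidationError("network needs at least one predictor gene")
        if n_out < 1:
            raise ValidationError("network needs at least one target gene")
        if architecture not in ("relu", "linear", "none_hidden"):
            raise ValidationError(f"unknown architecture {architecture!r}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        self.n_in = n_in
        self.n_out = n_out
        self.hidden_size = hidden_size
        self.dropout_rate = float(dropout_rate)
        self.architecture = architecture
        self.learning_rate = float(learning_rate)
        self.rng = np.random.default_rng(seed)

        def he(n_rows: int, n_cols: int) -> np.ndarray:
            scale = np.sqrt(2.0 / n_rows)
            return (self.rng.standard_normal((n_rows, n_cols)) * scale).astype(np.float32)

        if architecture == "none_hidden":
            self.params = {
                "W": he(n_in, n_out),
                "b": np.zeros(n_out, dtype=np.float32),
            }
        else:
            self.params = {
                "W1": he(n_in, hidden_size),
                "b1": np.zeros(hidden_size, dtype=np.float32),
                "W2": he(hidden_size, n_out),
                "b2": np.zeros(n_out, dtype=np.float32),
            }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _hidden_act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.architecture == "relu" else z

    def _output_act(self, z: np.ndarray) -> np.ndarray:
        # softplus: non-negative like a rectifier, but never gradient-dead
        return np.logaddexp(0.0, z) if self.architecture == "relu" else z

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout inactive)."""
        X = np.asarray(X, dtype=np.float32)
        if self.architecture == "none_hidden":
            return X @ self.params["W"] + self.params["b"]
        h = self._hidden_act(X @ self.params["W1"] + self.params["b1"])
        return self._output_act(h @ self.params["W2"] + self.params["b2"])

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        return batch_weighted_mse(Y, self.predict(X))

    # ------------------------------------------------------------------
    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= (self.learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(
                np.float32
            )

    def _train_batch(self, X: np.ndarray, Y: np.ndarray) -> None:
        B = X.shape[0]
        p = self.params
        if self.architecture == "none_hidden":
            Z = X @ p["W"] + p["b"]
            dZ = (2.0 / B) * Y * (Z - Y)
            self._adam_step({"W": X.T @ dZ, "b": dZ.sum(axis=0)})
            return

        Z1 = X @ p["W1"] + p["b1"]
        H = self._hidden_act(Z1)
        if self.dropout_rate > 0.0:
            keep = 1.0 - self.dropout_rate
            mask = (self.rng.random(H.shape) < keep).astype(np.float32) / keep
            Hd = H * mask
        else:
            mask = None
            Hd = H
        Z2 = Hd @ p["W2"] + p["b2"]
        Yhat = self._output_act(Z2)

        dYhat = (2.0 / B) * Y * (Yhat - Y)
        if self.architecture == "relu":
            dZ2 = dYhat / (1.0 + np.exp(-Z2))  # softplus' = sigmoid
        else:
            dZ2 = dYhat
        dW2 = Hd.T @ dZ2
        db2 = dZ2.sum(axis=0)
        dH = dZ2 @ p["W2"].T
        if mask is not None:
            dH = dH * mask
        dZ1 = dH * (Z1 > 0) if self.architecture == "relu" else dH
        self._adam_step(
            {"W1": X.T @ dZ1, "b1": dZ1.sum(axis=0), "W2": dW2, "b2": db2}
        )

    def train_epoch(self, X: np.ndarray, Y: np.ndarray, batch_size: int = 64) -> None:
        """One pass over the training cells in shuffled mini-batches."""
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        order = self.rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            idx = order[start : start + batch_size]
            self._train_batch(X[idx], Y[idx])

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k] = v.copy()


def expected_param_count(
    n_in: int, n_out: int, hidden_size: int, architecture: str = "relu"
) -> int:
    """Closed-form trainable-parameter count for a plan's network."""
    if architecture == "none_hidden":
        return n_in * n_out + n_out
    return n_in * hidden_size + hidden_size + hidden_size * n_out + n_out


def fit_subnetwork(
    net: SubNetwork,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    batch_size: int = 64,
    max_epochs: int = 500,
    patience: int = 5,
) -> dict[str, list[float]]:
    """Train with early stopping on held-out loss; restore the best weights.

    Stops when the test loss has not improved (strictly) for ``patience``
    consecutive epochs, or at ``max_epochs``. Returns the per-epoch
    train/test loss log.
    """
    X_train = np.asarray(X_train, dtype=np.float32)
    Y_train = np.asarray(Y_train, dtype=np.float32)
    X_test = np.asarray(X_test, dtype=np.float32)
    Y_test = np.asarray(Y_test, dtype=np.float32)
    log: dict[str, list[float]] = {"train_loss": [], "test_loss": []}
    best_loss = np.inf
    best_weights = net.get_weights()
    stale = 0
    for _ in range(max_epochs):
        net.train_epoch(X_train, Y_train, batch_size=batch_size)
        train_loss = net.loss(X_train, Y_train)
        test_loss = net.loss(X_test, Y_test)
        log["train_loss"].append(train_loss)
        log["test_loss"].append(test_loss)
        if test_loss < best_loss:
            best_loss = test_loss
            best_weights = net.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    net.set_weights(best_weights)
    return log
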