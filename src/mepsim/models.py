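"""Learners: generalized linear models and a feedforward neural network.

Both families expose the scikit-learn estimator contract (``fit``,
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) and accept either a plain matrix, a DataFrame or a
:class:`~mepsim.transforms.PreparedDesign`; fitting records the column
schema and prediction validates against it.

The network is a fully connected multilayer perceptron trained by
mini-batch adaptive-moment gradient descent with backpropagation. The
default protocol: five hidden layers of 50 rectified-linear nodes, batch
normalization, dropout proportion 0.001, batches of 1000, learning rate
0.1 with weight decay 1e-4, the rate divided by 10 every 300 epochs, at
most 1500 epochs, 15% of the training data held out for validation, and an
early-stopping check every 50 epochs that halts after ``patience``
consecutive checks without a relative validation-loss improvement of at
least ``tol``, restoring the best-validation checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit as _expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .errors import (
    CollinearityError,
    InvalidSpecError,
    SchemaError,
    TrainingDivergedError,
)
from .transforms import PreparedDesign

__all__ = [
    "MLPConfig",
    "MLPNetwork",
    "GLM",
    "fit_glm",
    "fit_mlp",
    "predict",
    "evaluate",
]


def _unpack_design(X):
    """Return (matrix, column names) from design/DataFrame/array input."""
    if isinstance(X, PreparedDesign):
        return np.asarray(X.M, dtype=float), list(X.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    M = np.atleast_2d(np.asarray(X, dtype=float))
    return M, [f"x{i + 1}" for i in range(M.shape[1])]


def _check_schema(columns, schema):
    if columns != schema:
        raise SchemaError(
            f"design columns {columns} do not match the fitted schema {schema}"
        )


# ---------------------------------------------------------------------------
# generalized linear models


class GLM(BaseEstimator):
    """Least-squares (identity link) or maximum-likelihood logistic model.

    Deterministic given its inputs. Rank-deficient designs raise
    :class:`CollinearityError` naming the offending columns.
    """

    def __init__(self, link="identity"):
        self.link = link

    @property
    def family(self):
        return "linear" if self.link == "identity" else "logistic"

    def fit(self, X, y):
        if self.link not in ("identity", "expit"):
            raise InvalidSpecError(f"unknown link {self.link!r}")
        M, cols = _unpack_design(X)
        y = np.asarray(y, dtype=float).ravel()
        n, d = M.shape
        if n != y.size:
            raise InvalidSpecError("X and y have different lengths")
        if n <= d:
            raise InvalidSpecError(f"need n > d, got n={n}, d={d}")
        A = np.column_stack([np.ones(n), M])
        # QR-based rank diagnostic: tiny diagonal of R flags the collinear column
        R = np.linalg.qr(A, mode="r")
        diag = np.abs(np.diag(R))
        bad = diag < 1e-10 * max(1.0, diag.max())
        if bad.any():
            names = ["(intercept)"] + cols
            culprits = [names[i] for i in np.flatnonzero(bad)]
            raise CollinearityError(
                f"design is rank deficient; collinear columns: {culprits}",
                columns=culprits,
            )
        if self.link == "identity":
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            # unpenalized maximum likelihood
            clf = LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10
            )
            clf.fit(M, y.astype(int))
            self.intercept_ = float(clf.intercept_[0])
            self.coef_ = clf.coef_.ravel().copy()
        self.input_schema_ = cols
        self.n_features_in_ = d
        return self

    def predict(self, X):
        M, cols = _unpack_design(X)
        _check_schema(cols, self.input_schema_)
        lin = self.intercept_ + M @ self.coef_
        return _expit(lin) if self.link == "expit" else lin


# ---------------------------------------------------------------------------
# neural network


@dataclass
class MLPConfig:
    """Hyperparameters of the network training protocol (defaults as above)."""

    layer_sizes: tuple = (50, 50, 50, 50, 50)
    activation: str = "relu"
    output_link: str = "identity"
    dropout: float = 0.001
    batch_norm: bool = True
    batch_size: int = 1000
    learning_rate: float = 0.1
    weight_decay: float = 1e-4
    lr_drop_every: int = 300
    lr_drop_factor: float = 10.0
    max_epochs: int = 1500
    early_stop_every: int = 50
    val_fraction: float = 0.15
    seed: int = 0
    optimizer: str = "adam"
    standardize: bool = True
    tol: float = 1e-4
    patience: int = 3

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise InvalidSpecError("dropout must be in [0, 1)")
        if not (0 < self.val_fraction < 1):
            raise InvalidSpecError("val_fraction must be in (0, 1)")
        for name in ("batch_size", "lr_drop_every", "max_epochs", "early_stop_every"):
            if getattr(self, name) < 1:
                raise InvalidSpecError(f"{name} must be a positive count")


_ACTIVATIONS = {
    "relu": (lambda a: np.maximum(a, 0.0), lambda a: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
}


class _Adam:
    def __init__(self, params, weight_decay):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads, lr):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params, weight_decay):
        self.wd = weight_decay

    def step(self, params, grads, lr):
        for p, g in zip(params, grads):
            if self.wd:
                g = g + self.wd * p
            p -= lr * g


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class MLPNetwork(BaseEstimator):
    """Fully connected feedforward network (see module docstring).

    Fully reproducible given ``seed``: initialization, the validation
    split, batch shuffling and dropout masks all flow from one generator.

    Attributes (after ``fit``)
    --------------------------
    training_log_ : DataFrame with epoch, train_loss, val_loss, lr
    n_epochs_ : epochs actually run
    best_val_loss_ : validation loss of the restored checkpoint
    """

    def __init__(self, layer_sizes=(50, 50, 50, 50, 50), activation="relu",
                 output_link="identity", dropout=0.001, batch_norm=True,
                 batch_size=1000, learning_rate=0.1, weight_decay=1e-4,
                 lr_drop_every=300, lr_drop_factor=10.0, max_epochs=1500,
                 early_stop_every=50, val_fraction=0.15, seed=0,
                 optimizer="adam", standardize=True, tol=1e-4, patience=3):
        self.layer_sizes = layer_sizes
        self.activation = activation
        self.output_link = output_link
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.lr_drop_every = lr_drop_every
        self.lr_drop_factor = lr_drop_factor
        self.max_epochs = max_epochs
        self.early_stop_every = early_stop_every
        self.val_fraction = val_fraction
        self.seed = seed
        self.optimizer = optimizer
        self.standardize = standardize
        self.tol = tol
        self.patience = patience

    @property
    def family(self):
        return "mlp"

    @classmethod
    def from_config(cls, config: MLPConfig):
        return cls(**asdict(config))

    # -- parameter bookkeeping -------------------------------------------
    def _init_params(self, d_in, rng):
        sizes = [d_in, *self.layer_sizes, 1]
        self._W, self._b = [], []
        self._gamma, self._beta = [], []
        phi, _ = _ACTIVATIONS[self.activation]
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            scale = np.sqrt(2.0 / fan_in)  # He initialization for rectifiers
            self._W.append(rng.normal(0.0, scale, size=(fan_in, sizes[i + 1])))
            self._b.append(np.zeros(sizes[i + 1]))
        n_hidden = len(self.layer_sizes)
        self._use_bn = self.batch_norm and n_hidden > 0
        if self._use_bn:
            for h in self.layer_sizes:
                self._gamma.append(np.ones(h))
                self._beta.append(np.zeros(h))
            self._run_mean = [np.zeros(h) for h in self.layer_sizes]
            self._run_var = [np.ones(h) for h in self.layer_sizes]

    def _params(self):
        return [*self._W, *self._b, *self._gamma, *self._beta]

    def _snapshot(self):
        state = [p.copy() for p in self._params()]
        if self._use_bn:
            state += [m.copy() for m in self._run_mean]
            state += [v.copy() for v in self._run_var]
        return state

    def _restore(self, state):
        params = self._params()
        for p, s in zip(params, state):
            p[...] = s
        if self._use_bn:
            h = len(self.layer_sizes)
            for i in range(h):
                self._run_mean[i][...] = state[len(params) + i]
                self._run_var[i][...] = state[len(params) + h + i]

    # -- forward / backward ----------------------------------------------
    def _forward(self, X, training, rng=None):
        phi, dphi = _ACTIVATIONS[self.activation]
        caches = []
        h = X
        n_hidden = len(self.layer_sizes)
        for i in range(n_hidden):
            a = h @ self._W[i] + self._b[i]
            cache = {"h_in": h, "a": a}
            if self._use_bn:
                if training:
                    mu = a.mean(axis=0)
                    var = a.var(axis=0)
                    self._run_mean[i] = (1 - _BN_MOMENTUM) * self._run_mean[i] + _BN_MOMENTUM * mu
                    self._run_var[i] = (1 - _BN_MOMENTUM) * self._run_var[i] + _BN_MOMENTUM * var
                else:
                    mu, var = self._run_mean[i], self._run_var[i]
                inv = 1.0 / np.sqrt(var + _BN_EPS)
                ahat = (a - mu) * inv
                z = self._gamma[i] * ahat + self._beta[i]
                cache.update(ahat=ahat, inv=inv)
            else:
                z = a
            act = phi(z)
            cache["z"] = z
            if training and self.dropout > 0:
                mask = (rng.random(act.shape) >= self.dropout) / (1.0 - self.dropout)
                act = act * mask
                cache["mask"] = mask
            caches.append(cache)
            h = act
        out = (h @ self._W[n_hidden] + self._b[n_hidden]).ravel()
        return out, h, caches

    def _backward(self, X, dout, h_last, caches):
        phi, dphi = _ACTIVATIONS[self.activation]
        n_hidden = len(self.layer_sizes)
        gW = [None] * len(self._W)
        gb = [None] * len(self._b)
        ggamma = [None] * len(self._gamma)
        gbeta = [None] * len(self._beta)
        m = X.shape[0]
        dout = dout.reshape(-1, 1)
        gW[n_hidden] = h_last.T @ dout
        gb[n_hidden] = dout.sum(axis=0)
        dh = dout @ self._W[n_hidden].T
        for i in range(n_hidden - 1, -1, -1):
            c = caches[i]
            if "mask" in c:
                dh = dh * c["mask"]
            dz = dh * dphi(c["z"])
            if self._use_bn:
                ggamma[i] = (dz * c["ahat"]).sum(axis=0)
                gbeta[i] = dz.sum(axis=0)
                # batch-norm backward
                dahat = dz * self._gamma[i]
                da = c["inv"] * (
                    dahat
                    - dahat.mean(axis=0)
                    - c["ahat"] * (dahat * c["ahat"]).mean(axis=0)
                )
            else:
                da = dz
            gW[i] = c["h_in"].T @ da
            gb[i] = da.sum(axis=0)
            dh = da @ self._W[i].T
        return [*gW, *gb, *[g for g in ggamma if g is not None],
                *[g for g in gbeta if g is not None]]

    def _loss_and_grad(self, pred, y):
        m = y.size
        if self.output_link == "identity":
            r = pred - y
            return float(np.mean(r * r)), (2.0 / m) * r
        # binary cross-entropy on the logits, numerically stable
        z = pred
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        return loss, (_expit(z) - y) / m

    def _eval_loss(self, X, y):
        pred, _, _ = self._forward(X, training=False)
        loss, _ = self._loss_and_grad(pred, y)
        return loss

    # -- API ---------------------------------------------------------------
    def fit(self, X, y):
        if self.output_link not in ("identity", "expit"):
            raise InvalidSpecError(f"unknown output link {self.output_link!r}")
        if self.activation not in _ACTIVATIONS:
            raise InvalidSpecError(f"unknown activation {self.activation!r}")
        M, cols = _unpack_design(X)
        y = np.asarray(y, dtype=float).ravel()
        n, d = M.shape
        if y.size != n:
            raise InvalidSpecError("X and y have different lengths")
        rng = np.random.default_rng(self.seed)

        # validation split (stratified by class for binary outcomes)
        n_val = max(1, int(round(self.val_fraction * n)))
        if self.output_link == "expit":
            idx = np.arange(n)
            val_idx = []
            for cls in (0.0, 1.0):
                members = idx[y == cls]
                members = members[rng.permutation(members.size)]
                take = max(1, int(round(self.val_fraction * members.size))) if members.size else 0
                val_idx.append(members[:take])
            val_idx = np.sort(np.concatenate(val_idx))
        else:
            perm = rng.permutation(n)
            val_idx = np.sort(perm[:n_val])
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        self.val_indices_ = np.flatnonzero(val_mask)
        Xtr, ytr = M[~val_mask], y[~val_mask]
        Xva, yva = M[val_mask], y[val_mask]

        # standardization (training statistics, frozen for prediction)
        if self.standardize:
            self._x_mean = Xtr.mean(axis=0)
            self._x_sd = Xtr.std(axis=0)
            self._x_sd[self._x_sd == 0] = 1.0
        else:
            self._x_mean = np.zeros(d)
            self._x_sd = np.ones(d)
        if self.output_link == "identity" and self.standardize:
            self._y_mean = float(ytr.mean())
            self._y_sd = float(ytr.std()) or 1.0
        else:
            self._y_mean, self._y_sd = 0.0, 1.0
        Xtr = (Xtr - self._x_mean) / self._x_sd
        Xva = (Xva - self._x_mean) / self._x_sd
        ytr_s = (ytr - self._y_mean) / self._y_sd
        yva_s = (yva - self._y_mean) / self._y_sd

        self._init_params(d, rng)
        params = self._params()
        opt = (_Adam if self.optimizer == "adam" else _SGD)(params, self.weight_decay)

        n_tr = Xtr.shape[0]
        bs = min(self.batch_size, n_tr)
        log_rows = []
        best_val = np.inf
        best_state = None
        bad_checks = 0
        # losses are reported on the original outcome scale
        scale2 = self._y_sd**2 if self.output_link == "identity" else 1.0

        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            lr = self.learning_rate / self.lr_drop_factor ** ((epoch - 1) // self.lr_drop_every)
            order = rng.permutation(n_tr)
            running, seen = 0.0, 0
            for start in range(0, n_tr, bs):
                take = order[start:start + bs]
                xb, yb = Xtr[take], ytr_s[take]
                pred, h_last, caches = self._forward(xb, training=True, rng=rng)
                loss, dout = self._loss_and_grad(pred, yb)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite training loss at epoch {epoch}", epoch=epoch
                    )
                grads = self._backward(xb, dout, h_last, caches)
                opt.step(params, grads, lr)
                running += loss * len(take)
                seen += len(take)
            train_loss = running / seen * scale2
            val_loss = np.nan
            if epoch % self.early_stop_every == 0 or epoch == self.max_epochs:
                val_loss = self._eval_loss(Xva, yva_s) * scale2
                improved = val_loss < best_val * (1.0 - self.tol)
                if improved or best_state is None:
                    best_val = val_loss
                    best_state = self._snapshot()
                    bad_checks = 0
                else:
                    bad_checks += 1
                log_rows.append((epoch, train_loss, val_loss, lr))
                if bad_checks >= self.patience and epoch % self.early_stop_every == 0:
                    break
            else:
                log_rows.append((epoch, train_loss, val_loss, lr))

        if best_state is not None:
            self._restore(best_state)
        self.best_val_loss_ = float(best_val)
        self.n_epochs_ = epoch
        self.training_log_ = pd.DataFrame(
            log_rows, columns=["epoch", "train_loss", "val_loss", "lr"]
        )
        self.input_schema_ = cols
        self.n_features_in_ = d
        return self

    def predict(self, X):
        M, cols = _unpack_design(X)
        _check_schema(cols, self.input_schema_)
        Xs = (M - self._x_mean) / self._x_sd
        pred, _, _ = self._forward(Xs, training=False)
        if self.output_link == "identity":
            return pred * self._y_sd + self._y_mean
        return _expit(pred)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_glm(design, y, link="identity"):
    """Fit a generalized linear model on a prepared design."""
    return GLM(link=link).fit(design, y)


def fit_mlp(design, y, config=None, **overrides):
    """Fit the network under ``config`` (an :class:`MLPConfig`)."""
    cfg = asdict(config or MLPConfig())
    cfg.update(overrides)
    return MLPNetwork(**cfg).fit(design, y)


def predict(model, design):
    """Predict with a fitted model (probabilities under the expit link)."""
    return model.predict(design)


def evaluate(yhat, y, metric="mse"):
    """Mean squared error, or classification accuracy at the 0.5 threshold.

    Predicted probabilities of exactly 0.5 are classified positive.
    """
    yhat = np.asarray(yhat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if yhat.size == 0 or y.size == 0:
        raise InvalidSpecError("evaluate requires non-empty inputs")
    if yhat.size != y.size:
        raise InvalidSpecError("yhat and y have different lengths")
    if metric == "mse":
        return float(np.mean((yhat - y) ** 2))
    if metric == "accuracy":
        return float(np.mean((yhat >= 0.5).astype(float) == y))
    raise InvalidSpecError(f"unknown metric {metric!r}")
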