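"""Generators for error-prone replicate intake data and outcomes.

The data model mirrors how repeated 24-hour dietary recalls are treated in
nutritional epidemiology. A person's *usual intake* ``X`` of a dietary
component is a long-run average that is never observed directly; instead,
each of ``k`` recall days yields an error-prone surrogate ``X*``. On a
transformed (Box-Cox) scale the surrogate is additive,

    f(X*_{l,j}) = beta0_l + betaZ_l' Z + u_l + eps_{l,j},

with a person-level effect ``u ~ N(0, Sigma_u)`` shared across days
(between-person variation) and a day-level error ``eps_j ~ N(0, Sigma_eps)``
independent across days (within-person variation). Usual intake is the
conditional expectation of the surrogate over the day-level error,

    X_l = E[ f^{-1}(beta0_l + betaZ_l' Z + u_l + eps_l) | Z, u_l ],

evaluated here by Gauss-Hermite quadrature. Outcomes follow a generalized
regression model ``E[Y|X,Z] = g^{-1}(alpha0 + alpha' h(X, Z))`` for a known
link ``g`` and feature map ``h`` (ratios, products, logarithms, thresholds).

Two observation modes are supported:

``"boxcox"``
    the surrogate is observed on the raw intake scale,
    ``X* = f^{-1}(additive)``; replicates are skewed and strictly positive.
``"identity"``
    classical additive error on the raw scale, ``X* = X + eps`` with
    ``X = beta0 + betaZ'Z + u``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidSpecError

logger = logging.getLogger("mepsim")

_GH_NODES = 41
_PSD_TOL = 1e-8
_MAX_REJECTION_ROUNDS = 200

__all__ = [
    "ErrorModelSpec",
    "OutcomeModelSpec",
    "ReplicateDataset",
    "Scenario",
    "SCENARIO_NAMES",
    "draw_replicates",
    "true_usual_intake",
    "generate_outcome",
    "mean_response",
    "feature_matrix",
    "make_scenario",
    "simulate_dataset",
]


def _as_psd(name, S, p):
    S = np.asarray(S, dtype=float)
    if S.shape != (p, p):
        raise InvalidSpecError(f"{name} must be {p}x{p}, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise InvalidSpecError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(S)
    if w.min() < -_PSD_TOL * max(1.0, w.max()):
        raise InvalidSpecError(
            f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})"
        )
    return S


def _psd_factor(S):
    """Factor L with L L' = S, valid for singular PSD matrices."""
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


@dataclass(frozen=True)
class ErrorModelSpec:
    """Measurement-error model for ``p`` error-prone dietary components.

    Parameters
    ----------
    p, q : int
        Number of error-prone components and error-free covariates.
    lambda_bc : array_like, shape (p,)
        Box-Cox exponent per component (used when ``observation="boxcox"``).
    beta0 : array_like, shape (p,)
        Intercept per component on the transformed (additive) scale.
    betaZ : array_like, shape (p, q)
        Covariate coefficients on the transformed scale.
    Sigma_u, Sigma_eps : array_like, shape (p, p)
        Between-person and within-person covariance matrices.
    observation : {"boxcox", "identity"}
        Scale on which the surrogate is observed (see module docstring).
    """

    p: int
    q: int
    lambda_bc: np.ndarray
    beta0: np.ndarray
    betaZ: np.ndarray
    Sigma_u: np.ndarray
    Sigma_eps: np.ndarray
    observation: str = "boxcox"

    def __post_init__(self):
        if self.p < 1 or self.q < 0:
            raise InvalidSpecError("need p >= 1 and q >= 0")
        if self.observation not in ("boxcox", "identity"):
            raise InvalidSpecError(f"unknown observation mode {self.observation!r}")
        lam = np.broadcast_to(np.asarray(self.lambda_bc, float), (self.p,)).copy()
        b0 = np.broadcast_to(np.asarray(self.beta0, float), (self.p,)).copy()
        bZ = np.asarray(self.betaZ, dtype=float).reshape(self.p, self.q)
        object.__setattr__(self, "lambda_bc", lam)
        object.__setattr__(self, "beta0", b0)
        object.__setattr__(self, "betaZ", bZ)
        object.__setattr__(self, "Sigma_u", _as_psd("Sigma_u", self.Sigma_u, self.p))
        object.__setattr__(
            self, "Sigma_eps", _as_psd("Sigma_eps", self.Sigma_eps, self.p)
        )

    def additive_mean(self, Z):
        """Transformed-scale mean ``beta0 + betaZ Z`` for covariate rows ``Z``."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.q:
            raise InvalidSpecError(f"Z must have q={self.q} columns")
        return self.beta0[None, :] + Z @ self.betaZ.T


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Outcome model ``E[Y|X,Z] = g^{-1}(alpha0 + alpha' h(X,Z))``.

    ``link`` names ``g^{-1}`` (``identity`` or ``expit``); ``feature_map``
    names ``h`` (``linear``, ``ratio``, ``sim3_nonlinear``,
    ``sim4_threshold``); ``alpha`` stacks the intercept and feature
    coefficients; ``sigmaY2`` is the residual variance (identity link only).
    """

    link: str
    feature_map: str
    alpha: np.ndarray
    sigmaY2: float = 0.0

    def __post_init__(self):
        if self.link not in ("identity", "expit"):
            raise InvalidSpecError(f"unknown link {self.link!r}")
        if self.feature_map not in _FEATURE_MAPS:
            raise InvalidSpecError(f"unknown feature map {self.feature_map!r}")
        if self.sigmaY2 < 0:
            raise InvalidSpecError("sigmaY2 must be nonnegative")
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float).ravel())


@dataclass
class ReplicateDataset:
    """One simulated sample: outcomes, replicates, covariates and truth.

    ``Xstar`` has shape ``(n, p, k)``; ``Xtrue`` retains the usual-intake
    truth for diagnostics and error-free reference arms.
    """

    Y: np.ndarray
    Xstar: np.ndarray
    Z: np.ndarray
    Xtrue: np.ndarray
    n: int
    p: int
    q: int
    k: int
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        cols = {"y": self.Y}
        for l in range(self.p):
            for j in range(self.k):
                cols[f"x{l + 1}_rep{j + 1}"] = self.Xstar[:, l, j]
        for m in range(self.q):
            cols[f"z{m + 1}"] = self.Z[:, m]
        for l in range(self.p):
            cols[f"xtrue{l + 1}"] = self.Xtrue[:, l]
        return pd.DataFrame(cols)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# replicate generation


def _violates(spec, additive):
    """Domain violations of the raw-scale observation, per (person, day)."""
    lam = spec.lambda_bc[None, :, None]
    if spec.observation == "identity":
        bad = additive <= 0
    else:
        bad = np.where(lam == 0, False, lam * additive + 1 <= 0)
        # raw intakes must also be positive; for lam > 0 the domain bound
        # already implies it, for lam == 0 exp() is positive
    return bad.any(axis=1)


def draw_replicates(spec, n, k, Z=None, seed=None):
    """Draw ``k`` replicate surrogate measurements for ``n`` persons.

    Each person receives one between-person effect ``u_i ~ N(0, Sigma_u)``
    and independent day errors ``eps_{ij} ~ N(0, Sigma_eps)``. Day errors
    whose additive value falls outside the observation domain (inverse
    Box-Cox support, or a non-positive intake in identity mode) are redrawn;
    the rejection rate is logged and is negligible at the catalogued
    scenario parameters.

    Returns
    -------
    Xstar : ndarray, shape (n, p, k)
    u : ndarray, shape (n, p)
    """
    if n < 1 or k < 1:
        raise InvalidSpecError("need n >= 1 and k >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if Z is None:
        Z = np.zeros((n, spec.q))
    Z = np.asarray(Z, dtype=float).reshape(n, spec.q)
    if not np.all(np.isfinite(Z)):
        raise InvalidSpecError("Z contains non-finite values")

    Lu = _psd_factor(spec.Sigma_u)
    Le = _psd_factor(spec.Sigma_eps)
    u = rng.standard_normal((n, spec.p)) @ Lu.T
    eta = spec.additive_mean(Z) + u  # (n, p)

    eps = np.einsum("pq,njq->njp", Le, rng.standard_normal((n, k, spec.p)))
    eps = np.swapaxes(eps, 1, 2)  # (n, p, k)
    additive = eta[:, :, None] + eps

    rejected = 0
    bad = _violates(spec, additive)  # (n, k)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise DomainError(
                "replicate rejection did not converge; the error model places "
                "substantial mass outside the observation domain"
            )
        idx = np.argwhere(bad)
        rejected += len(idx)
        fresh = rng.standard_normal((len(idx), spec.p)) @ Le.T
        additive[idx[:, 0], :, idx[:, 1]] = eta[idx[:, 0]] + fresh
        bad = _violates(spec, additive)
    if rejected:
        logger.info(
            "draw_replicates: redrew %d of %d day errors (rate %.2e)",
            rejected, n * k, rejected / (n * k),
        )

    if spec.observation == "identity":
        Xstar = additive
    else:
        Xstar = np.empty_like(additive)
        for l in range(spec.p):
            lam = spec.lambda_bc[l]
            if lam == 0:
                Xstar[:, l, :] = np.exp(additive[:, l, :])
            else:
                Xstar[:, l, :] = np.power(lam * additive[:, l, :] + 1, 1.0 / lam)
    return np.ascontiguousarray(Xstar), u


def _gh_rule():
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return x, w / np.sqrt(np.pi)


def _true_intake(spec, Z, u):
    """Vectorized usual intake for all persons; shape (n, p)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    Z = np.zeros((u.shape[0], 0)) if spec.q == 0 else np.atleast_2d(np.asarray(Z, float))
    eta = spec.additive_mean(Z) + u
    if spec.observation == "identity":
        return eta
    nodes, weights = _gh_rule()
    out = np.empty_like(eta)
    for l in range(spec.p):
        lam = spec.lambda_bc[l]
        sig = np.sqrt(spec.Sigma_eps[l, l])
        y = eta[:, l, None] + np.sqrt(2.0) * sig * nodes[None, :]
        if lam == 0:
            vals = np.exp(y)
        else:
            # clamp: quadrature tails may cross the inverse Box-Cox support;
            # the clipped mass is below machine-level quadrature error
            vals = np.power(np.clip(lam * y + 1, 0.0, None), 1.0 / lam)
        out[:, l] = vals @ weights
    if not np.all(np.isfinite(out)):
        raise DomainError("usual-intake quadrature produced non-finite values")
    return out


def true_usual_intake(spec, Z_row=None, u_row=None):
    """Usual intake ``X = E[f^{-1}(beta0 + betaZ'Z + u + eps) | Z, u]``.

    Deterministic Gauss-Hermite quadrature (41 nodes) over the marginal
    within-person error of each component. With identity observation the
    expectation collapses to ``beta0 + betaZ'Z + u`` exactly.
    """
    Z_row = np.zeros(spec.q) if Z_row is None else np.asarray(Z_row, float)
    u_row = np.zeros(spec.p) if u_row is None else np.asarray(u_row, float)
    return _true_intake(spec, Z_row.reshape(1, -1), u_row.reshape(1, -1))[0]


# ---------------------------------------------------------------------------
# outcome generation


def _fm_linear(X, Z):
    return X


def _fm_ratio(X, Z):
    if X.shape[1] < 2:
        raise InvalidSpecError("ratio feature map needs p >= 2")
    return (X[:, 0] / X[:, 1])[:, None]


def _fm_sim3(X, Z):
    if X.shape[1] < 2 or Z.shape[1] < 3:
        raise InvalidSpecError("sim3_nonlinear needs p >= 2 and q >= 3")
    if np.any(X[:, :2] <= 0):
        raise DomainError("sim3_nonlinear: log of non-positive intake")
    x1, x2 = X[:, 0], X[:, 1]
    return np.column_stack(
        [x1, x2, x1 * x2, np.log(x1), np.log(x2), x1 / x2, Z[:, 2]]
    )


def _fm_sim4(X, Z):
    if X.shape[1] < 3:
        raise InvalidSpecError("sim4_threshold needs p >= 3")
    if np.any(X[:, 2] <= 0):
        raise DomainError("sim4_threshold: log of non-positive intake")
    bracket = (X[:, 0] >= 100).astype(float) - (X[:, 2] <= 30).astype(float)
    return np.column_stack([X[:, 1] * bracket, np.log(X[:, 2])])


_FEATURE_MAPS: dict[str, Callable] = {
    "linear": _fm_linear,
    "ratio": _fm_ratio,
    "sim3_nonlinear": _fm_sim3,
    "sim4_threshold": _fm_sim4,
}


def feature_matrix(spec, X, Z=None):
    """Evaluate the outcome feature map ``h(X, Z)``; shape (n, d_h)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.zeros((X.shape[0], 0)) if Z is None else np.atleast_2d(np.asarray(Z, float))
    H = _FEATURE_MAPS[spec.feature_map](X, Z)
    if spec.alpha.size != H.shape[1] + 1:
        raise InvalidSpecError(
            f"alpha has length {spec.alpha.size}, expected "
            f"{H.shape[1] + 1} (features + intercept)"
        )
    return H


def mean_response(spec, X, Z=None):
    """``E[Y|X,Z]`` under the outcome model (probability for the expit link)."""
    H = feature_matrix(spec, X, Z)
    lin = spec.alpha[0] + H @ spec.alpha[1:]
    if spec.link == "identity":
        return lin
    from scipy.special import expit

    return expit(lin)


def generate_outcome(spec, X, Z=None, seed=None):
    """Sample outcomes: Gaussian residuals (identity) or Bernoulli (expit)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = mean_response(spec, X, Z)
    if spec.link == "identity":
        if spec.sigmaY2 == 0:
            return mu
        return mu + rng.normal(0.0, np.sqrt(spec.sigmaY2), size=mu.shape)
    return (rng.random(mu.shape) < mu).astype(float)


# ---------------------------------------------------------------------------
# scenario catalogue


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of one simulation scenario."""

    name: str
    error: ErrorModelSpec
    outcome: OutcomeModelSpec
    sample_covariates: Callable
    n_train: int
    n_test: int
    k: int
    days_grid: tuple = ()
    replications: int = 1

    def describe(self):
        """Flat, human-editable key/value view of the parameterization.

        Keys match the override names accepted by :func:`make_scenario`,
        so a dumped description can be edited and fed back in.
        """
        e, o = self.error, self.outcome
        return {
            "name": self.name,
            "p": e.p, "q": e.q,
            "lambda_bc": e.lambda_bc.tolist(),
            "beta0": e.beta0.tolist(),
            "betaZ": e.betaZ.tolist(),
            "Sigma_u": e.Sigma_u.tolist(),
            "Sigma_eps": e.Sigma_eps.tolist(),
            "observation": e.observation,
            "link": o.link, "feature_map": o.feature_map,
            "alpha": o.alpha.tolist(), "sigmaY2": o.sigmaY2,
            "n_train": self.n_train, "n_test": self.n_test, "k": self.k,
            "days_grid": list(self.days_grid),
            "replications": self.replications,
        }


_SIGMA_U_2 = np.array([[20.0, 15.5], [15.5, 25.5]])
_SIGMA_EPS_2 = np.array([[38.0, 20.5], [20.5, 34.5]])
_SIGMA_Z = np.array(
    [
        [1.28, 0.21, -0.07, 0.32],
        [0.21, 1.98, 1.28, 0.34],
        [-0.07, 1.28, 1.91, 1.22],
        [0.32, 0.34, 1.22, 1.20],
    ]
)
_SIM4_MU = np.array([100.0, 50.0, 30.0])
_SIM4_SIGMA = np.array([[25.0, 20.0, 5.0], [20.0, 20.0, 8.0], [5.0, 8.0, 21.0]])
_SIM4_SIGMA_EPS = np.array(
    [[16.0, 32.0, 16.0], [32.0, 80.0, 36.0], [16.0, 36.0, 53.0]]
)

SCENARIO_NAMES = ("sim1", "sim2", "sim3a", "sim3b", "sim4")


def _no_covariates(n, rng):
    return np.zeros((n, 0))


def _z_normal4(n, rng):
    return rng.standard_normal((n, 4)) @ _psd_factor(_SIGMA_Z).T


def _sim12(lam):
    error = ErrorModelSpec(
        p=2, q=0, lambda_bc=np.full(2, lam), beta0=np.array([36.0, 27.5]),
        betaZ=np.zeros((2, 0)), Sigma_u=_SIGMA_U_2, Sigma_eps=_SIGMA_EPS_2,
        observation="boxcox",
    )
    outcome = OutcomeModelSpec(
        link="identity", feature_map="ratio", alpha=np.array([98.5, 4.0]),
        sigmaY2=1.0,
    )
    return error, outcome


def _sim3(variant):
    if variant == "a":
        b0, alpha = 100.0, np.array([350.0, 2, -1, 3, 2, 1, -4, 1.0])
    else:
        b0, alpha = 50.0, np.array([350.0, 1, -1, 50, 25, 25, -1, 1.0])
    betaZ = np.array([[2.0, 0.0, -1.0, 0.5], [0.0, 2.0, 1.0, -0.5]])
    error = ErrorModelSpec(
        p=2, q=4, lambda_bc=np.ones(2), beta0=np.array([b0, b0]), betaZ=betaZ,
        Sigma_u=_SIGMA_U_2, Sigma_eps=_SIGMA_EPS_2, observation="identity",
    )
    outcome = OutcomeModelSpec(
        link="identity", feature_map="sim3_nonlinear", alpha=alpha, sigmaY2=1.0
    )
    return error, outcome


def make_scenario(name, overrides=None):
    """Scenario catalogue with the published parameterizations.

    ``overrides`` is a flat mapping of field name to value, applied to the
    error model (e.g. ``lambda_bc``, ``observation``) or the outcome model
    (e.g. ``alpha``, ``sigmaY2``).
    """
    if name == "sim1":
        error, outcome = _sim12(0.35)
        scn = Scenario(
            name=name, error=error, outcome=outcome,
            sample_covariates=_no_covariates, n_train=12000, n_test=12000,
            k=10, days_grid=(2, 4, 6, 8, 10), replications=1,
        )
    elif name == "sim2":
        error, outcome = _sim12(0.5)
        scn = Scenario(
            name=name, error=error, outcome=outcome,
            sample_covariates=_no_covariates, n_train=12000, n_test=12000,
            k=10, days_grid=(2, 4, 6, 8, 10), replications=1,
        )
    elif name in ("sim3a", "sim3b"):
        error, outcome = _sim3(name[-1])
        scn = Scenario(
            name=name, error=error, outcome=outcome,
            sample_covariates=_z_normal4, n_train=40000, n_test=40000, k=2,
            replications=100,
        )
    elif name == "sim4":
        error = ErrorModelSpec(
            p=3, q=0, lambda_bc=np.ones(3), beta0=_SIM4_MU,
            betaZ=np.zeros((3, 0)), Sigma_u=_SIM4_SIGMA,
            Sigma_eps=_SIM4_SIGMA_EPS, observation="identity",
        )
        outcome = OutcomeModelSpec(
            link="expit", feature_map="sim4_threshold",
            alpha=np.array([-1.0, 1.0 / 30.0, 0.25]), sigmaY2=0.0,
        )
        scn = Scenario(
            name=name, error=error, outcome=outcome,
            sample_covariates=_no_covariates, n_train=10000, n_test=10000,
            k=2, replications=100,
        )
    else:
        raise InvalidSpecError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )

    if overrides:
        err_kw, out_kw, scn_kw = {}, {}, {}
        for key, value in overrides.items():
            if key in ErrorModelSpec.__dataclass_fields__:
                err_kw[key] = value
            elif key in OutcomeModelSpec.__dataclass_fields__:
                out_kw[key] = value
            elif key in ("n_train", "n_test", "k", "days_grid", "replications"):
                scn_kw[key] = value
            else:
                raise InvalidSpecError(f"unknown scenario override {key!r}")
        scn = replace(
            scn,
            error=replace(scn.error, **err_kw) if err_kw else scn.error,
            outcome=replace(scn.outcome, **out_kw) if out_kw else scn.outcome,
            **scn_kw,
        )
    return scn


def simulate_dataset(scenario, n, k, seed):
    """Draw one full sample ``{Y_i, X*_i, Z_i}`` plus retained truth.

    All randomness flows from ``seed`` through named SeedSequence
    substreams (covariates, replicates, outcome), so identical seeds give
    bit-identical datasets.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_cov, s_rep, s_out = ss.spawn(3)
    rng_cov = np.random.default_rng(s_cov)
    Z = scenario.sample_covariates(n, rng_cov)
    Xstar, u = draw_replicates(
        scenario.error, n, k, Z=Z, seed=np.random.default_rng(s_rep)
    )
    Xtrue = _true_intake(scenario.error, Z, u)
    Y = generate_outcome(
        scenario.outcome, Xtrue, Z, seed=np.random.default_rng(s_out)
    )
    return ReplicateDataset(
        Y=Y, Xstar=Xstar, Z=Z, Xtrue=Xtrue, n=n, p=scenario.error.p,
        q=scenario.error.q, k=k, meta={"scenario": scenario.name},
    )
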