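"""Closed-form variance-reduction quantities for replicate averaging.

Averaging ``k`` replicates of an additively error-prone measurement divides
the error variance by ``k``. When the additive structure only holds on a
log scale, averaging on the raw scale is less efficient: the average of
``k`` multiplicative lognormal errors ``exp(eps_j)``, ``eps_j ~ N(0, s2)``,
is equivalent (by variance matching) to a *single* multiplicative error
with log-scale variance

    sigma2_reduced = log[ (1 + sqrt(1 + 4 (e^{2 s2} - e^{s2}) / k)) / 2 ],

which satisfies ``s2/k <= sigma2_reduced <= s2`` for ``k >= 2``: averaging
still helps, but by less than the additive factor ``1/k``. Transforming to
the additive scale before averaging recovers the full reduction (the
Jensen-type inequality checked by :func:`lemma1_gap`).

The module also provides the conditional error variance of the
normal-normal replicate model and a nonnegative least-squares fit of the
test-MSE scaling decomposition ``sigmaY2 + C1/k + C2/n^{1-delta}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize

from .errors import DomainError, InvalidSpecError

__all__ = [
    "averaged_error_variance",
    "sigma_reduced_log",
    "lemma1_gap",
    "Lemma1Result",
    "conditional_error_variance",
    "fit_mse_scaling",
    "MseScalingFit",
    "tradeoff_table",
]


def averaged_error_variance(sigma2, k):
    """Additive-scale error variance after averaging ``k`` replicates: ``sigma2/k``."""
    if k < 1:
        raise InvalidSpecError("k must be >= 1")
    if sigma2 < 0:
        raise InvalidSpecError("sigma2 must be nonnegative")
    return sigma2 / k


def sigma_reduced_log(sigma2, k):
    """Log-scale variance equivalent to averaging ``k`` lognormal errors.

    Derived by matching raw-scale variances:
    ``var[(1/k) sum exp(eps_j)] = (e^{2 s2} - e^{s2})/k`` must equal
    ``e^{2 r} - e^{r}`` for the single-error variance ``r``; solving the
    quadratic in ``e^r`` gives the closed form above. At ``k = 1`` the
    matching condition collapses and the result equals ``sigma2``.
    """
    if k < 1:
        raise InvalidSpecError("k must be >= 1")
    if sigma2 < 0:
        raise InvalidSpecError("sigma2 must be nonnegative")
    if sigma2 == 0:
        return 0.0
    c = (np.exp(2.0 * sigma2) - np.exp(sigma2)) / k
    return float(np.log(0.5 * (1.0 + np.sqrt(1.0 + 4.0 * c))))


class Lemma1Result(NamedTuple):
    """Monte-Carlo estimates of the transform-then-average comparison."""

    lhs: float  # var[ f(Omega + mean(eps)) | Omega ]
    rhs: float  # var[ mean(f(Omega + eps_i)) | Omega ]
    lhs_se: float
    rhs_se: float
    gap_se: float  # standard error of (rhs - lhs) under common random numbers


_TRANSFORMS = {
    "exp": np.exp,
    "cube": lambda x: x**3,
    "affine": None,  # handled with explicit slope
}


def lemma1_gap(f, sigma2, k, mc_draws=1_000_000, seed=0, omega=0.0, slope=3.0,
               intercept=1.0, n_batches=100):
    """Compare transform-then-average against average-of-transformed errors.

    For a smooth transform ``f`` and iid ``eps_i ~ N(0, sigma2)`` at a fixed
    person effect ``Omega``, estimates

    * lhs: ``var[f(Omega + eps_bar) | Omega]`` — average first, transform once;
    * rhs: ``var[(1/k) sum f(Omega + eps_i) | Omega]`` — transform each day.

    For convexly curved transforms (``exp``, ``cube``) lhs <= rhs; for an
    affine transform the two coincide exactly (common random numbers make
    the equality exact draw-by-draw). Standard errors come from batch means
    (``n_batches`` batches).
    """
    if f not in _TRANSFORMS:
        raise InvalidSpecError(f"unknown transform {f!r}; expected {tuple(_TRANSFORMS)}")
    if k < 2:
        raise InvalidSpecError("lemma1_gap needs k >= 2")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=(int(mc_draws), int(k)))
    if f == "affine":
        func = lambda x: intercept + slope * x
    else:
        func = _TRANSFORMS[f]
    a = func(omega + eps.mean(axis=1))  # transform the averaged value
    b = func(omega + eps).mean(axis=1)  # average the transformed values

    def batch_vars(x):
        xb = x[: (len(x) // n_batches) * n_batches].reshape(n_batches, -1)
        return xb.var(axis=1, ddof=1)

    va, vb = batch_vars(a), batch_vars(b)
    return Lemma1Result(
        lhs=float(np.var(a, ddof=1)),
        rhs=float(np.var(b, ddof=1)),
        lhs_se=float(va.std(ddof=1) / np.sqrt(n_batches)),
        rhs_se=float(vb.std(ddof=1) / np.sqrt(n_batches)),
        gap_se=float((vb - va).std(ddof=1) / np.sqrt(n_batches)),
    )


def conditional_error_variance(sigmaV2, sigmaX2, k=1):
    """``var(V_bar | X_bar*)`` in the normal-normal classical error model.

    With truth ``X ~ N(mu, sigmaX2)`` and ``X_bar* = X + V_bar``,
    ``V_bar`` the mean of ``k`` iid ``N(0, sigmaV2)`` errors, the posterior
    error variance is ``sigmaV2 sigmaX2 / (sigmaV2 + k sigmaX2)`` — the
    irreducible excess prediction variance carried by the surrogate. It
    vanishes as ``k`` grows: with enough replicates, error-prone prediction
    approaches error-free prediction.
    """
    if k < 1:
        raise InvalidSpecError("k must be >= 1")
    if sigmaV2 < 0 or sigmaX2 < 0:
        raise InvalidSpecError("variances must be nonnegative")
    if sigmaV2 == 0 and sigmaX2 == 0:
        raise DomainError("sigmaV2 and sigmaX2 cannot both be zero")
    return sigmaV2 * sigmaX2 / (sigmaV2 + k * sigmaX2)


@dataclass
class MseScalingFit:
    """Nonnegative decomposition of test MSE into floor, 1/k and 1/n terms."""

    sigmaY2_hat: float
    C1_hat: float
    C2_hat: float
    delta: float
    residuals: np.ndarray
    rmse: float

    def predict(self, n, k):
        n = np.asarray(n, dtype=float)
        k = np.asarray(k, dtype=float)
        return self.sigmaY2_hat + self.C1_hat / k + self.C2_hat / n ** (1.0 - self.delta)


def fit_mse_scaling(results, delta=0.0):
    """Fit ``mse = sigmaY2 + C1/k + C2/n^{1-delta}`` by nonnegative least squares.

    Parameters
    ----------
    results : DataFrame or record array
        Must expose columns ``n``, ``k`` and ``value`` (test MSE).
    delta : float
        Convergence-slack exponent; 0 is the near-parametric best case.
    """
    n = np.asarray(results["n"], dtype=float)
    k = np.asarray(results["k"], dtype=float)
    y = np.asarray(results["value"], dtype=float)
    pairs = {(a, b) for a, b in zip(n, k)}
    if len(pairs) < 3:
        raise InvalidSpecError("need >= 3 distinct (n, k) pairs")
    A = np.column_stack([np.ones_like(n), 1.0 / k, 1.0 / n ** (1.0 - delta)])
    if np.linalg.matrix_rank(A) < 3:
        raise InvalidSpecError("degenerate design: (n, k) grid does not separate terms")
    coef, rnorm = optimize.nnls(A, y)
    resid = y - A @ coef
    return MseScalingFit(
        sigmaY2_hat=float(coef[0]), C1_hat=float(coef[1]), C2_hat=float(coef[2]),
        delta=float(delta), residuals=resid, rmse=float(np.sqrt(np.mean(resid**2))),
    )


def tradeoff_table(sigmaV2, sigmaX2, budget, k_values=(1, 2, 4, 5, 8, 10)):
    """Sample-size versus replicate-count trade-off at a fixed budget.

    For a total measurement budget ``n * k = budget``, tabulates the
    conditional error variance floor for each feasible replicate count —
    the quantity a designer trades against the sample size available for
    model estimation.
    """
    rows = []
    for k in k_values:
        if budget % k:
            continue
        rows.append(
            {
                "k": int(k),
                "n": int(budget // k),
                "cond_error_var": conditional_error_variance(sigmaV2, sigmaX2, k),
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)
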