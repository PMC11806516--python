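"""Box-Cox machinery and replicate-preparation strategies.

Error-prone replicate measurements ``X*`` (shape ``n x p x k``: person,
dietary component, day) are turned into a flat predictor matrix by one of
three strategies:

``average``
    per-component arithmetic mean over the replicate days;
``concatenate``
    every replicate as its own column (component-major order);
``transformed_average``
    estimate a Box-Cox exponent per component on the pooled replicates,
    transform every replicate, and average on the transformed scale.

The transformed average is motivated by transformation-to-additivity: when
the within-person error is additive and homoscedastic only after a monotone
transform, averaging on the transformed scale achieves the full 1/k error
variance reduction, whereas averaging on the raw scale does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import DomainError, InvalidSpecError

STRATEGIES = ("average", "concatenate", "transformed_average")

__all__ = [
    "STRATEGIES",
    "PreparedDesign",
    "ReplicatePreparer",
    "boxcox",
    "boxcox_inverse",
    "estimate_lambda",
    "prepare",
]


def boxcox(x, lam):
    """Box-Cox transform ``(x**lam - 1)/lam`` (``log x`` at ``lam == 0``).

    Parameters
    ----------
    x : array_like
        Strictly positive values.
    lam : float
        Transform exponent.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("boxcox requires strictly positive inputs")
    return special.boxcox(x, lam)


def boxcox_inverse(y, lam):
    """Inverse Box-Cox transform ``(lam*y + 1)**(1/lam)`` (``exp`` at ``lam == 0``)."""
    y = np.asarray(y, dtype=float)
    if lam != 0 and np.any(lam * y + 1 <= 0):
        raise DomainError(
            "boxcox_inverse domain violation: lam*y + 1 must be positive"
        )
    return special.inv_boxcox(y, lam)


def estimate_lambda(replicates, grid=(-1.0, 2.0), step=0.01):
    """Profile-likelihood Box-Cox exponent for pooled replicate measurements.

    The exponent maximises the normal log-likelihood of the transformed,
    pooled values (all persons and all replicate days of one component).
    The profile likelihood is evaluated on a bounded grid and the maximiser
    refined by golden-section search between its grid neighbours.

    Parameters
    ----------
    replicates : ndarray
        Positive values; any shape (flattened internally). For a full
        ``n x p x k`` replicate array, call once per component.

    Returns
    -------
    float
    """
    x = np.asarray(replicates, dtype=float).ravel()
    if x.size < 30:
        raise InvalidSpecError("estimate_lambda needs at least 30 pooled values")
    if np.any(x <= 0):
        raise DomainError("estimate_lambda requires strictly positive values")

    lo, hi = grid
    lams = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    best = int(np.argmax(llf))
    a = lams[max(best - 1, 0)]
    b = lams[min(best + 1, len(lams) - 1)]
    if a == b:
        return float(lams[best])
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x), bracket=None, bounds=(a, b),
        method="bounded", options={"xatol": 1e-6},
    )
    return float(res.x)


@dataclass
class PreparedDesign:
    """Predictor matrix produced by one preparation strategy.

    Attributes
    ----------
    M : ndarray, shape (n, d)
        Predictor matrix; rows align one-to-one with the dataset's persons.
    columns : list of str
        Column names (schema used by the learners for validation).
    strategy : str
        One of :data:`STRATEGIES`, or a scenario-specific arm label.
    lambda_hat : ndarray or None
        Estimated Box-Cox exponent per component (``transformed_average`` only).
    k_used : int
        Number of replicate days the design assumes.
    """

    M: np.ndarray
    columns: list[str]
    strategy: str
    lambda_hat: np.ndarray | None = None
    k_used: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def n(self):
        return self.M.shape[0]

    @property
    def d(self):
        return self.M.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.M, columns=self.columns)

    def to_csv(self, path):
        """Write the matrix as CSV plus a ``<path>.meta.json`` sidecar with
        the strategy, replicate count and any estimated exponents."""
        import json

        self.to_frame().to_csv(path, index=False)
        meta = {
            "strategy": self.strategy,
            "k_used": int(self.k_used),
            "lambda_hat": None if self.lambda_hat is None
            else [float(v) for v in np.atleast_1d(self.lambda_hat)],
            **self.meta,
        }
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


class ReplicatePreparer:
    """Build predictor matrices from replicate measurements (sklearn-style).

    ``fit`` estimates any data-dependent state (the Box-Cox exponents of the
    ``transformed_average`` strategy) on training data; ``transform`` then
    applies the frozen state, so test-set preparation never re-estimates.

    Parameters
    ----------
    strategy : {"average", "concatenate", "transformed_average"}
    days_used : int, optional
        Use only the first ``days_used`` replicates (replicates are
        exchangeable by construction). Default: all.
    retransform : bool
        For ``transformed_average``, map the transformed-scale mean back to
        the raw scale through the inverse Box-Cox (sensitivity option).
        Default False: learners receive the transformed-scale mean.
    lambda_override : array_like, optional
        Fix the per-component exponents instead of estimating them.
    """

    def __init__(self, strategy="average", days_used=None, retransform=False,
                 lambda_override=None):
        self.strategy = strategy
        self.days_used = days_used
        self.retransform = retransform
        self.lambda_override = lambda_override

    def get_params(self, deep=True):
        return {
            "strategy": self.strategy,
            "days_used": self.days_used,
            "retransform": self.retransform,
            "lambda_override": self.lambda_override,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- internal helpers -------------------------------------------------
    def _replicates(self, dataset):
        Xstar = np.asarray(dataset.Xstar, dtype=float)
        k = Xstar.shape[2]
        j = k if self.days_used is None else int(self.days_used)
        if j < 1 or j > k:
            raise InvalidSpecError(
                f"days_used={j} outside the available replicate count k={k}"
            )
        return Xstar[:, :, :j], j

    def fit(self, dataset, y=None):
        if self.strategy not in STRATEGIES:
            raise InvalidSpecError(f"unknown preparation strategy {self.strategy!r}")
        Xrep, j = self._replicates(dataset)
        self.k_used_ = j
        self.p_ = Xrep.shape[1]
        if self.strategy == "transformed_average":
            if self.lambda_override is not None:
                lam = np.broadcast_to(
                    np.asarray(self.lambda_override, dtype=float), (self.p_,)
                ).copy()
            else:
                lam = np.array(
                    [estimate_lambda(Xrep[:, l, :]) for l in range(self.p_)]
                )
            self.lambda_hat_ = lam
        else:
            self.lambda_hat_ = None
        return self

    def transform(self, dataset):
        if not hasattr(self, "k_used_"):
            raise InvalidSpecError("ReplicatePreparer must be fit before transform")
        Xrep, j = self._replicates(dataset)
        p = Xrep.shape[1]
        if p != self.p_:
            raise InvalidSpecError(
                f"dataset has p={p} components, preparer was fit with p={self.p_}"
            )
        Z = np.asarray(dataset.Z, dtype=float)

        if self.strategy == "average":
            M = Xrep.mean(axis=2)
            cols = [f"x{l + 1}_avg" for l in range(p)]
        elif self.strategy == "concatenate":
            # component-major: x1_rep1, x1_rep2, ..., x2_rep1, ...
            M = Xrep.reshape(Xrep.shape[0], p * j)
            cols = [
                f"x{l + 1}_rep{r + 1}" for l in range(p) for r in range(j)
            ]
        else:  # transformed_average
            lam = self.lambda_hat_
            T = np.stack(
                [boxcox(Xrep[:, l, :], lam[l]) for l in range(p)], axis=1
            )
            M = T.mean(axis=2)
            if self.retransform:
                M = np.stack(
                    [boxcox_inverse(M[:, l], lam[l]) for l in range(p)], axis=1
                )
            cols = [f"x{l + 1}_bcavg" for l in range(p)]

        if Z.size:
            M = np.hstack([M, Z])
            cols = cols + [f"z{m + 1}" for m in range(Z.shape[1])]
        return PreparedDesign(
            M=np.ascontiguousarray(M, dtype=float),
            columns=cols,
            strategy=self.strategy,
            lambda_hat=None if self.lambda_hat_ is None else self.lambda_hat_.copy(),
            k_used=j,
            meta={"retransform": self.retransform},
        )

    def fit_transform(self, dataset, y=None):
        return self.fit(dataset).transform(dataset)


def prepare(dataset, strategy, days_used=None, **kwargs):
    """One-shot preparation: fit the strategy on ``dataset`` and apply it.

    For train/test pairs construct a :class:`ReplicatePreparer`, ``fit`` it on
    the training dataset and ``transform`` both, so that estimated Box-Cox
    exponents are frozen at their training values.
    """
    return ReplicatePreparer(
        strategy=strategy, days_used=days_used, **kwargs
    ).fit_transform(dataset)
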