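"""Fixed-effect and conventional random-effects pooling.

The conventional model treats each study's log-RR ``theta_j`` as
``N(theta, v_j + tau^2)`` and pools with inverse-variance weights
``w_j = 1/(v_j + tau^2)``.  Three estimators of the between-study variance
``tau^2`` are provided:

* DerSimonian-Laird (``tau2_dl``) -- closed-form moment estimator from
  Cochran's Q;
* Mandel-Paule (``tau2_mp``) -- the root of the generalized Q statistic
  equated to its degrees of freedom (unique: the statistic is strictly
  decreasing in tau^2);
* REML (``tau2_reml``) -- Fisher scoring on the restricted likelihood of
  the normal-normal marginal model, truncated at zero.

``pool`` with ``tau2 = 0`` is the fixed-effect analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .core import MetaDataset, PooledResult, Z95
from .effects import dataset_effects

__all__ = [
    "Tau2Estimate",
    "cochran_q",
    "tau2_dl",
    "tau2_mp",
    "tau2_reml",
    "tau2_qprofile_ci",
    "pool",
    "fit_rem",
]

_TAU2_METHODS = {"DL", "MP", "REML"}


@dataclass
class Tau2Estimate:
    tau2: float
    method: str
    iterations: int = 0
    converged: bool = True
    ci_low: float | None = None
    ci_high: float | None = None


def _check(theta: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    if theta.shape != v.shape or theta.ndim != 1:
        raise ValueError("theta_j and v_j must be 1-d arrays of equal length")
    if len(theta) < 2:
        raise ValueError("heterogeneity estimation requires K >= 2 studies")
    if np.any(v <= 0):
        raise ValueError("all within-study variances must be positive")
    return theta, v


def cochran_q(theta: np.ndarray, v: np.ndarray, tau2: float = 0.0) -> float:
    """Generalized Cochran Q at heterogeneity ``tau2`` (0 gives the usual Q)."""
    theta, v = _check(theta, v)
    w = 1.0 / (v + tau2)
    mean = np.sum(w * theta) / np.sum(w)
    return float(np.sum(w * (theta - mean) ** 2))


def tau2_dl(theta: np.ndarray, v: np.ndarray) -> Tau2Estimate:
    theta, v = _check(theta, v)
    k = len(theta)
    w = 1.0 / v
    q = cochran_q(theta, v)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return Tau2Estimate(max(0.0, (q - (k - 1)) / denom), "DL")


def tau2_mp(theta: np.ndarray, v: np.ndarray, tol: float = 1e-10) -> Tau2Estimate:
    theta, v = _check(theta, v)
    k = len(theta)
    if cochran_q(theta, v) <= k - 1:
        return Tau2Estimate(0.0, "MP")
    hi = 1.0
    it = 0
    while cochran_q(theta, v, hi) > k - 1:  # grow bracket; Q is decreasing in tau2
        hi *= 2.0
        it += 1
        if it > 200:
            return Tau2Estimate(hi, "MP", iterations=it, converged=False)
    root = brentq(lambda t2: cochran_q(theta, v, t2) - (k - 1), 0.0, hi, xtol=tol)
    return Tau2Estimate(float(root), "MP", iterations=it)


def tau2_reml(
    theta: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> Tau2Estimate:
    theta, v = _check(theta, v)
    t2 = max(tau2_dl(theta, v).tau2, 1e-8)  # DL start
    for it in range(1, max_iter + 1):
        w = 1.0 / (v + t2)
        mean = np.sum(w * theta) / np.sum(w)
        resid2 = (theta - mean) ** 2
        # Fisher scoring step on the restricted likelihood
        num = np.sum(w**2 * resid2) - np.sum(w) + np.sum(w**2) / np.sum(w)
        den = np.sum(w**2) - 2.0 * np.sum(w**3) / np.sum(w) + (np.sum(w**2) / np.sum(w)) ** 2
        step = num / den
        t2_new = max(0.0, t2 + step)
        if abs(t2_new - t2) < tol:
            return Tau2Estimate(float(t2_new), "REML", iterations=it)
        t2 = t2_new
    return Tau2Estimate(float(t2), "REML", iterations=max_iter, converged=False)


def tau2_qprofile_ci(
    theta: np.ndarray, v: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Q-profile confidence interval for tau^2 (descriptive companion)."""
    theta, v = _check(theta, v)
    k = len(theta)
    lo_q = chi2.ppf(1 - (1 - level) / 2, k - 1)
    hi_q = chi2.ppf((1 - level) / 2, k - 1)

    def solve(target: float) -> float:
        if cochran_q(theta, v, 0.0) <= target:
            return 0.0
        hi = 1.0
        while cochran_q(theta, v, hi) > target:
            hi *= 2.0
            if hi > 1e6:
                return np.inf
        return float(brentq(lambda t2: cochran_q(theta, v, t2) - target, 0.0, hi))

    return solve(lo_q), solve(hi_q)


def pool(theta: np.ndarray, v: np.ndarray, tau2: float = 0.0,
         het_method: str = "FE", het_value: float | None = None) -> PooledResult:
    """Inverse-variance pooling with weights ``1/(v_j + tau2)``."""
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(theta) == 0:
        raise ValueError("cannot pool an empty set of effects")
    if np.any(v <= 0):
        raise ValueError("all within-study variances must be positive")
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return PooledResult(
        theta_hat=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        het_method=het_method,
        het_value=tau2 if het_value is None else het_value,
        weights=w,
        theta_j=theta,
        v_j=v,
        k_used=len(theta),
    )


def fit_rem(
    ds: MetaDataset,
    tau2_method: str = "DL",
    estimator: str = "conventional",
) -> PooledResult:
    """One-call conventional meta-analysis of a dataset.

    Degenerate (all-zero / all-event) studies are dropped first, following
    customary practice.  ``tau2_method`` may be ``"FE"`` for the
    fixed-effect analysis, or one of ``"DL"``, ``"MP"``, ``"REML"``.
    """
    kept, dropped = ds.drop_degenerate()
    theta, v, _ = dataset_effects(kept, estimator=estimator)
    if tau2_method == "FE":
        res = pool(theta, v, 0.0, het_method="FE")
    elif tau2_method in _TAU2_METHODS:
        if kept.k < 2:
            raise ValueError("random-effects analysis requires K >= 2 studies")
        est = {"DL": tau2_dl, "MP": tau2_mp, "REML": tau2_reml}[tau2_method](theta, v)
        res = pool(theta, v, est.tau2, het_method=tau2_method)
    else:
        raise ValueError(f"unknown tau2 method {tau2_method!r}")
    res.n_dropped = dropped
    return res
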