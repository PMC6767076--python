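"""Truncation probabilities and moments for the log-binomial mixed model.

With a log link, a study's true log-RR is ``theta_j = theta + b_j`` with
``b_j ~ N(0, tau^2)``, and the constraint ``pi_t = pi_c * exp(theta_j) < 1``
requires ``b_j < A = -log(pi_c) - theta``.  The probability of satisfying
the constraint is ``Phi(beta)`` with ``beta = A / tau``; when it is below
1 the model is improper and any repair biases the effect distribution:

* censoring ("point mass"): ``theta_j = min(theta + b_j, theta + A)``,
  placing mass ``1 - Phi(beta)`` at the boundary;
* truncation (rejection sampling): ``b_j`` follows a right-truncated
  normal, with the Barr-Sherrill closed-form moments.

Both repairs pull ``E(theta_j)`` below ``theta`` and shrink
``Var(theta_j)`` below ``tau^2``; these closed forms are what the
simulation module overlays on its empirical bias curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "TruncSpec",
    "trunc_probability",
    "all_studies_prob",
    "truncated_moments",
    "pointmass_moments",
    "median_pi_t",
]

#: below this mass almost nothing of the random-effect distribution is
#: admissible and the ratio phi/Phi is numerically meaningless
_MIN_MASS = 1e-12


@dataclass(frozen=True)
class TruncSpec:
    """Control probability, overall log-RR and between-study SD."""

    pi_c: float
    theta: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_c < 1.0:
            raise ValueError("pi_c must lie in (0, 1)")
        if self.tau <= 0.0:
            raise ValueError("tau must be positive")

    @property
    def a(self) -> float:
        """Upper bound on the random effect: ``-log(pi_c) - theta``."""
        return -np.log(self.pi_c) - self.theta

    @property
    def beta(self) -> float:
        return self.a / self.tau


def trunc_probability(spec: TruncSpec) -> float:
    """Probability that a single random effect satisfies the constraint."""
    return float(norm.cdf(spec.beta))


def all_studies_prob(spec: TruncSpec, k: int) -> float:
    """Probability that all K random effects satisfy the constraint."""
    if k < 0:
        raise ValueError("K must be nonnegative")
    return float(norm.cdf(spec.beta) ** k)


def truncated_moments(spec: TruncSpec) -> tuple[float, float]:
    """Mean and variance of ``theta_j`` under the truncation repair.

    For ``X ~ N(mu, tau^2)`` truncated from above at ``A`` and
    ``beta = (A - mu)/tau``:
    ``E(X) = mu - tau * phi(beta)/Phi(beta)`` and
    ``Var(X) = tau^2 [1 - beta phi(beta)/Phi(beta) - (phi(beta)/Phi(beta))^2]``.
    """
    beta = spec.beta
    big_phi = norm.cdf(beta)
    if big_phi < _MIN_MASS:
        raise ValueError(
            "admissible mass Phi(beta) underflows; the truncated distribution is "
            "degenerate for this (pi_c, theta, tau) -- reduce theta or pi_c")
    lam = norm.pdf(beta) / big_phi
    mean = spec.theta - spec.tau * lam
    var = spec.tau**2 * (1.0 - beta * lam - lam**2)
    return float(mean), float(var)


def pointmass_moments(spec: TruncSpec, c_star: float | None = None) -> tuple[float, float]:
    """Mean and variance of ``theta_j`` under the censoring repair.

    ``theta_j = min(X, c*)`` for ``X ~ N(theta, tau^2)``; by default the
    censoring point ``c*`` is the constraint boundary ``theta + A``
    (equivalently ``-log(pi_c)``).  With ``beta = (c* - theta)/tau``:

    ``E  = theta * Phi(beta) - tau * phi(beta) + c* (1 - Phi(beta))``
    ``E2 = (theta^2 + tau^2) Phi(beta) - tau (theta + c*) phi(beta)
           + c*^2 (1 - Phi(beta))``
    """
    mu, tau = spec.theta, spec.tau
    # c* beyond the boundary is mathematically fine (less censoring); the
    # modelling default is the boundary itself
    c = mu + spec.a if c_star is None else float(c_star)
    beta = (c - mu) / tau
    big_phi = norm.cdf(beta)
    phi = norm.pdf(beta)
    mean = mu * big_phi - tau * phi + c * (1.0 - big_phi)
    second = (mu**2 + tau**2) * big_phi - tau * (mu + c) * phi + c**2 * (1.0 - big_phi)
    return float(mean), float(second - mean**2)


def median_pi_t(pi_c: float, theta: float) -> float:
    """Median treatment probability ``pi_c * exp(theta)``.

    ``theta_j`` is symmetric about ``theta`` before any repair, so the
    median of ``pi_t = pi_c * exp(theta_j)`` is ``pi_c * e^theta``; values
    >= 1 are returned as-is (the caller decides how to interpret them).
    """
    if not 0.0 < pi_c < 1.0:
        raise ValueError("pi_c must lie in (0, 1)")
    return float(pi_c * np.exp(theta))
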