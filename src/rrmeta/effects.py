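"""Study-level log-risk-ratio estimators and variance estimators.

Two estimator conventions coexist in practice and both are implemented:

* ``"conventional"`` -- the sample log-RR ``log(p_t/p_c)`` with variance
  ``1/y_t - 1/n_t + 1/y_c - 1/n_c``; when the 2x2 table contains a zero
  cell, 0.5 is added to all four cells first.
* ``"pettigrew"`` -- the bias-corrected estimator that adds 1/2 to the
  events and the total of *each* arm in *every* study,
  ``log[(y_t + 1/2)/(n_t + 1/2)] - log[(y_c + 1/2)/(n_c + 1/2)]``,
  unbiased to O(n^-2), finite even for double-zero tables.

Under beta-binomial sampling with intra-cluster correlation ``rho`` the
within-study variance of the log-RR is inflated multiplicatively, by
``1 + (n - 1) rho`` per arm; ``var_bb_plugin`` is the plug-in (count-based)
version and ``var_bb_theoretical`` the population version.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetaDataset, StudyTable

__all__ = [
    "EffectEstimate",
    "log_rr_pettigrew",
    "log_rr_conventional",
    "var_binomial",
    "var_bb_plugin",
    "var_bb_theoretical",
    "study_effect",
    "dataset_effects",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study effect with the pieces needed for rho-dependent variances.

    The plug-in variance is linear in rho:
    ``v(rho) = a_t * (1 + (n_t - 1) rho) + a_c * (1 + (n_c - 1) rho)``,
    so we store the arm terms ``a_t``, ``a_c`` and the arm sizes once and
    evaluate at any rho without revisiting the counts.
    """

    theta_j: float
    a_t: float
    a_c: float
    n_t: int
    n_c: int
    correction: str

    def variance(self, rho: float = 0.0) -> float:
        if not 0.0 <= rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        return self.a_t * (1.0 + (self.n_t - 1) * rho) + self.a_c * (1.0 + (self.n_c - 1) * rho)

    @property
    def v_j(self) -> float:
        return self.variance(0.0)


def log_rr_pettigrew(s: StudyTable) -> float:
    """Bias-corrected log-RR; finite for every valid table."""
    return float(
        np.log((s.y_t + 0.5) / (s.n_t + 0.5)) - np.log((s.y_c + 0.5) / (s.n_c + 0.5))
    )


def _continuity_cells(s: StudyTable) -> tuple[float, float, float, float]:
    """Counts after the customary 0.5-to-all-cells correction for zero cells."""
    if s.has_zero_cell:
        return s.y_c + 0.5, s.n_c + 1.0, s.y_t + 0.5, s.n_t + 1.0
    return float(s.y_c), float(s.n_c), float(s.y_t), float(s.n_t)


def log_rr_conventional(s: StudyTable, continuity: bool = True) -> float:
    """Sample log-RR, optionally with the zero-cell continuity correction."""
    if continuity:
        y_c, n_c, y_t, n_t = _continuity_cells(s)
    else:
        y_c, n_c, y_t, n_t = float(s.y_c), float(s.n_c), float(s.y_t), float(s.n_t)
        if y_c == 0 or y_t == 0:
            raise ValueError(
                f"{s.study_id or 'study'}: zero events; conventional log-RR undefined "
                "without continuity correction")
    return float(np.log((y_t / n_t) / (y_c / n_c)))


def var_binomial(s: StudyTable, continuity: bool = True) -> float:
    """Customary variance of the sample log-RR under binomial sampling."""
    if continuity:
        y_c, n_c, y_t, n_t = _continuity_cells(s)
    else:
        y_c, n_c, y_t, n_t = float(s.y_c), float(s.n_c), float(s.y_t), float(s.n_t)
        if y_c == 0 or y_t == 0:
            raise ValueError(
                f"{s.study_id or 'study'}: zero events; variance undefined without correction")
    return float(1.0 / y_t - 1.0 / n_t + 1.0 / y_c - 1.0 / n_c)


def var_bb_plugin(s: StudyTable, rho: float) -> float:
    """Plug-in variance of the half-corrected log-RR under overdispersion.

    At ``rho = 0`` this is the half-corrected binomial variance; each arm
    term is inflated by ``1 + (n - 1) rho``.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    a_t = 1.0 / (s.y_t + 0.5) - 1.0 / (s.n_t + 0.5)
    a_c = 1.0 / (s.y_c + 0.5) - 1.0 / (s.n_c + 0.5)
    return float(a_t * (1.0 + (s.n_t - 1) * rho) + a_c * (1.0 + (s.n_c - 1) * rho))


def var_bb_theoretical(pi_t: float, pi_c: float, n_t: int, n_c: int, rho: float) -> float:
    """Delta-method variance of the log-RR for beta-binomial arms."""
    if not (0.0 < pi_t < 1.0 and 0.0 < pi_c < 1.0):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    return float(
        (1.0 - pi_t) / (n_t * pi_t) * (1.0 + (n_t - 1) * rho)
        + (1.0 - pi_c) / (n_c * pi_c) * (1.0 + (n_c - 1) * rho)
    )


def study_effect(s: StudyTable, estimator: str = "pettigrew") -> EffectEstimate:
    """Effect estimate plus variance components under the chosen convention."""
    if estimator == "pettigrew":
        theta = log_rr_pettigrew(s)
        a_t = 1.0 / (s.y_t + 0.5) - 1.0 / (s.n_t + 0.5)
        a_c = 1.0 / (s.y_c + 0.5) - 1.0 / (s.n_c + 0.5)
    elif estimator == "conventional":
        theta = log_rr_conventional(s, continuity=True)
        y_c, n_c, y_t, n_t = _continuity_cells(s)
        a_t = 1.0 / y_t - 1.0 / n_t
        a_c = 1.0 / y_c - 1.0 / n_c
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return EffectEstimate(theta, a_t, a_c, s.n_t, s.n_c, estimator)


def dataset_effects(
    ds: MetaDataset, estimator: str = "pettigrew", rho: float = 0.0
) -> tuple[np.ndarray, np.ndarray, list[EffectEstimate]]:
    """Arrays ``(theta_j, v_j(rho))`` plus the per-study effect objects."""
    effects = [study_effect(s, estimator) for s in ds]
    theta = np.array([e.theta_j for e in effects])
    v = np.array([e.variance(rho) for e in effects])
    return theta, v, effects
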