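"""Data generation and simulation under the log-binomial mixed model.

A replicate draws study effects ``theta_j ~ N(theta, tau^2)``, sets
``pi_jt = pi_c * exp(theta_j)``, and draws binomial counts in each arm
(equal arm sizes n/2, common ``pi_c``).  Because ``pi_jt`` can exceed 1,
one of two repairs is applied:

* ``"point_mass"`` -- set ``pi_jt = min(pi_jt, 1 - eps)``, i.e. censor the
  random effect at the boundary;
* ``"truncation"`` -- redraw the offending study's effect until admissible
  (per-study rejection sampling, a right-truncated normal).

All-zero / all-event studies are then discarded, as is customary.  The
simulation driver estimates ``tau^2`` by DL, MP and REML, pools with the
conventional REM, and reports bias and coverage per method, which can be
compared with the closed-form repair moments from
:mod:`rrmeta.truncation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MetaDataset, SimDesign, StudyTable
from .effects import dataset_effects
from .rem import pool, tau2_dl, tau2_mp, tau2_reml
from .truncation import TruncSpec, pointmass_moments, trunc_probability, truncated_moments

__all__ = [
    "EPS_BELOW_ONE",
    "SimReplicate",
    "SimSummary",
    "replicate_rng",
    "draw_study_effects",
    "generate_replicate",
    "run_simulation",
    "theoretical_bias_curves",
]

#: "at or slightly below 1": offset keeping Binomial(n, pi_t) non-degenerate
EPS_BELOW_ONE = 1e-12

_TAU2_FUNS = {"DL": tau2_dl, "MP": tau2_mp, "REML": tau2_reml}


@dataclass
class SimReplicate:
    dataset: MetaDataset
    true_theta_j: np.ndarray
    n_discarded: int


@dataclass
class SimSummary:
    """Per-grid-point simulation summary (means over replicates)."""

    design: SimDesign
    methods: tuple[str, ...]
    bias_het: dict[str, float]
    bias_theta: dict[str, float]
    coverage: dict[str, float]
    mcse_het: dict[str, float]
    mcse_theta: dict[str, float]
    n_failed: int = 0
    reps_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        d = self.design
        for m in self.methods:
            rows.append(
                {
                    "option": d.option, "k": d.k, "n": d.n, "theta": d.theta,
                    "pi_c": d.pi_c, "tau2": d.tau2, "rho": d.rho, "reps": self.reps_used,
                    "method": m,
                    "bias_het": self.bias_het[m], "mcse_het": self.mcse_het[m],
                    "bias_theta": self.bias_theta[m], "mcse_theta": self.mcse_theta[m],
                    "coverage": self.coverage[m], "n_failed": self.n_failed,
                }
            )
        return pd.DataFrame(rows)


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Counter-based RNG: every (seed, replicate) stream is independent."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def draw_study_effects(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """Realized study effects theta_j after the option's repair (log scale)."""
    bound = -np.log(design.pi_c)  # theta_j must stay below -log(pi_c)
    tau = np.sqrt(design.tau2)
    theta_j = rng.normal(design.theta, tau, size=design.k)
    if design.option == "point_mass":
        cap = bound + np.log1p(-EPS_BELOW_ONE)
        return np.minimum(theta_j, cap)
    # truncation: per-study redraw of inadmissible effects
    if tau > 0:
        accept_p = trunc_probability(TruncSpec(design.pi_c, design.theta, tau))
        if accept_p < 1e-8:
            raise ValueError(
                "acceptance probability ~ 0; rejection sampling would not terminate")
    for _ in range(10_000):
        bad = theta_j >= bound
        if not bad.any():
            return theta_j
        theta_j[bad] = rng.normal(design.theta, tau, size=bad.sum())
    raise RuntimeError("rejection sampling failed to terminate")


def generate_replicate(design: SimDesign, rng: np.random.Generator) -> SimReplicate:
    """One simulated meta-analysis (after the discard rule)."""
    if design.option not in ("point_mass", "truncation"):
        raise ValueError("generate_replicate handles the log-binomial options only")
    m = design.n_arm
    theta_j = draw_study_effects(design, rng)
    pi_t = np.minimum(design.pi_c * np.exp(theta_j), 1.0 - EPS_BELOW_ONE)
    y_c = rng.binomial(m, design.pi_c, size=design.k)
    y_t = rng.binomial(m, pi_t)
    studies, kept_effects = [], []
    for j in range(design.k):
        s = StudyTable(int(y_c[j]), m, int(y_t[j]), m, study_id=str(j + 1))
        if not s.is_degenerate:
            studies.append(s)
            kept_effects.append(theta_j[j])
    if not studies:  # pathological corner: keep one study, flag the rest
        studies = [StudyTable(int(y_c[0]), m, int(y_t[0]), m, "1")]
        kept_effects = [theta_j[0]]
    return SimReplicate(
        dataset=MetaDataset(tuple(studies)),
        true_theta_j=np.array(kept_effects),
        n_discarded=design.k - len(studies),
    )


def run_simulation(
    design: SimDesign,
    methods: tuple[str, ...] = ("DL", "MP", "REML"),
    estimator: str = "pettigrew",
) -> SimSummary:
    """Monte-Carlo study of tau^2 / theta estimation and CI coverage.

    Deterministic given ``design.seed``; per-replicate estimator failures
    are counted, not fatal.
    """
    unknown = set(methods) - set(_TAU2_FUNS)
    if unknown:
        raise ValueError(f"unknown tau2 methods: {sorted(unknown)}")
    tau2_hat = {m: [] for m in methods}
    theta_hat = {m: [] for m in methods}
    covered = {m: [] for m in methods}
    n_failed = 0
    for rep in range(design.reps):
        rng = replicate_rng(design.seed, rep)
        try:
            repl = generate_replicate(design, rng)
            if repl.dataset.k < 2:
                raise ValueError("fewer than 2 usable studies")
            theta, v, _ = dataset_effects(repl.dataset, estimator=estimator)
            for m in methods:
                t2 = _TAU2_FUNS[m](theta, v).tau2
                res = pool(theta, v, t2, het_method=m)
                tau2_hat[m].append(t2)
                theta_hat[m].append(res.theta_hat)
                covered[m].append(res.ci_low <= design.theta <= res.ci_high)
        except (ValueError, RuntimeError):
            n_failed += 1
    reps_used = design.reps - n_failed

    def _mean(xs):
        return float(np.mean(xs)) if xs else float("nan")

    def _mcse(xs):
        return float(np.std(xs, ddof=1) / np.sqrt(len(xs))) if len(xs) > 1 else float("nan")

    return SimSummary(
        design=design,
        methods=tuple(methods),
        bias_het={m: _mean(tau2_hat[m]) - design.tau2 for m in methods},
        bias_theta={m: _mean(theta_hat[m]) - design.theta for m in methods},
        coverage={m: _mean([float(c) for c in covered[m]]) for m in methods},
        mcse_het={m: _mcse(tau2_hat[m]) for m in methods},
        mcse_theta={m: _mcse(theta_hat[m]) for m in methods},
        n_failed=n_failed,
        reps_used=reps_used,
    )


def theoretical_bias_curves(
    thetas: np.ndarray, pi_cs: np.ndarray, tau2: float
) -> pd.DataFrame:
    """Closed-form repair bias ``E(theta_j) - theta`` and ``Var(theta_j)``.

    One row per (theta, pi_c, option); exact values from the censored- and
    truncated-normal moments, for overlaying on simulation output.
    """
    tau = float(np.sqrt(tau2))
    rows = []
    for pi_c in np.atleast_1d(pi_cs):
        for theta in np.atleast_1d(thetas):
            spec = TruncSpec(float(pi_c), float(theta), tau)
            for option, fn in (("point_mass", pointmass_moments),
                               ("truncation", truncated_moments)):
                mean, var = fn(spec)
                rows.append(
                    {"option": option, "theta": float(theta), "pi_c": float(pi_c),
                     "tau2": tau2, "bias_theta_j": mean - theta, "var_theta_j": var}
                )
    return pd.DataFrame(rows)
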