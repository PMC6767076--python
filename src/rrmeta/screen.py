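"""Studentized-residual and truncation-probability screening.

For each study ``j`` of meta-analysis ``m`` the screen computes the
half-corrected log-RR ``theta_mj``, its variance, the pooled estimate
``theta_m`` (fixed- or random-effects weights), the studentized residual

    ``r_mj = (theta_mj - theta_m) / s_mj``,
    ``s_mj^2 = 1/w_mj - 1/sum_j w_mj``,

and the estimated probability that the study's random effect violates the
``pi_t < 1`` constraint,

    ``p_trunc = 1 - Phi((-log(p_mjC) - theta_m) / tau_m)``,

with ``p_mjC = y_mjC / n_mjC`` the unbiased control-arm proportion.  Under
a correctly specified normal random-effects model the ``r_mj`` pooled over
many meta-analyses are approximately standard normal; a downward drift of
the residuals with increasing ``p_trunc`` is the audit signature of the
range restriction biasing pooled risk ratios upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import MetaDataset, SimDesign
from .effects import dataset_effects
from .logbin import generate_replicate, replicate_rng
from .rem import tau2_dl, tau2_mp, tau2_reml

__all__ = [
    "BIN_EDGES",
    "ScreenConfig",
    "studentized_residuals",
    "truncation_probability_hat",
    "screen_meta_analysis",
    "screen_collection",
    "bin_and_tabulate",
    "make_synthetic_collection",
]

#: half-open truncation-probability bins: <0.05, [0.05,0.15), ..., >=0.85
BIN_EDGES = np.array([0.0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 1.0 + 1e-9])

_BIN_LABELS = [
    "<0.05", "[0.05-0.15)", "[0.15-0.25)", "[0.25-0.35)", "[0.35-0.45)",
    "[0.45-0.55)", "[0.55-0.65)", "[0.65-0.75)", "[0.75-0.85)", ">=0.85",
]

_TAU2 = {"DL": tau2_dl, "MP": tau2_mp, "REML": tau2_reml}


@dataclass(frozen=True)
class ScreenConfig:
    """Filters applied before residual computation (all configurable)."""

    model: str = "REM"            # "FEM" or "REM"
    tau2_method: str = "DL"
    min_k: int = 3                # MAs with fewer studies are skipped
    min_arm_size: int = 5         # studies with n_c or n_t below are dropped
    require_positive_tau2: bool = True


def studentized_residuals(
    ds: MetaDataset, model: str = "REM", tau2_method: str = "DL"
) -> tuple[np.ndarray, float, float]:
    """Residuals plus the pooled estimate and tau2-hat used.

    Returns ``(r_j, theta_m, tau2_hat)``; for the FEM, ``tau2_hat`` is 0.
    A study whose weight dominates the pool can make ``s_mj^2 <= 0``; its
    residual is returned as NaN (flagged, not fatal).
    """
    if ds.k < 2:
        raise ValueError("residuals require K >= 2 studies")
    theta, v, _ = dataset_effects(ds, estimator="pettigrew")
    if model == "FEM":
        tau2 = 0.0
    elif model == "REM":
        tau2 = _TAU2[tau2_method](theta, v).tau2
    else:
        raise ValueError(f"unknown model {model!r}")
    w = 1.0 / (v + tau2)
    w_sum = np.sum(w)
    theta_m = float(np.sum(w * theta) / w_sum)
    s2 = 1.0 / w - 1.0 / w_sum
    with np.errstate(invalid="ignore"):
        r = np.where(s2 > 0, (theta - theta_m) / np.sqrt(np.abs(s2)), np.nan)
    return r, theta_m, float(tau2)


def truncation_probability_hat(p_c: float, theta_m: float, tau_m: float) -> float:
    """Estimated probability that the study's effect violates ``pi_t < 1``.

    ``tau_m = 0`` returns 0 by definition (no random effect to truncate);
    ``p_c = 0`` gives an infinite bound, hence probability 0.
    """
    if not 0.0 <= p_c <= 1.0:
        raise ValueError("p_c must lie in [0, 1]")
    if tau_m < 0:
        raise ValueError("tau_m must be nonnegative")
    if tau_m == 0.0 or p_c == 0.0:
        return 0.0
    return float(1.0 - norm.cdf((-np.log(p_c) - theta_m) / tau_m))


def screen_meta_analysis(ds: MetaDataset, config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Per-study screen records for one meta-analysis (may be empty).

    Applies the arm-size filter, then the K and tau2 filters, then
    computes residuals and truncation probabilities.
    """
    kept = tuple(
        s for s in ds.studies
        if s.n_c >= config.min_arm_size and s.n_t >= config.min_arm_size
        and not s.is_degenerate
    )
    if len(kept) < max(config.min_k, 2):
        return pd.DataFrame()
    sub = MetaDataset(kept, ds.ma_id)
    r, theta_m, tau2 = studentized_residuals(sub, config.model, config.tau2_method)
    if config.require_positive_tau2 and tau2 <= 0.0:
        return pd.DataFrame()
    tau_m = np.sqrt(tau2)
    theta, v, _ = dataset_effects(sub, estimator="pettigrew")
    p_trunc = np.array(
        [truncation_probability_hat(s.p_c, theta_m, tau_m) for s in sub]
    )
    return pd.DataFrame(
        {
            "ma_id": sub.ma_id,
            "study_id": [s.study_id for s in sub],
            "theta_mj": theta,
            "v_mj": v,
            "theta_m": theta_m,
            "tau2_m": tau2,
            "r_mj": r,
            "p_trunc": p_trunc,
            "bin": pd.Categorical.from_codes(
                np.digitize(p_trunc, BIN_EDGES[1:-1]), categories=_BIN_LABELS
            ),
        }
    )


def screen_collection(
    collection: Iterable[MetaDataset], config: ScreenConfig = ScreenConfig()
) -> pd.DataFrame:
    """Concatenated screen records for a collection of meta-analyses."""
    frames = [screen_meta_analysis(ds, config) for ds in collection]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def bin_and_tabulate(records: pd.DataFrame, split_by_sign: bool = True) -> pd.DataFrame:
    """Cross-tab of study counts by truncation-probability bin.

    Rows: pooled-effect sign groups (optional) plus a total; also returns
    per-bin residual quartiles for boxplot-style summaries.
    """
    if records.empty:
        raise ValueError("no screen records to tabulate")
    rec = records.copy()
    rec["bin"] = pd.Categorical(rec["bin"], categories=_BIN_LABELS)
    out = {}
    if split_by_sign:
        out["theta>=0"] = (
            rec.loc[rec["theta_m"] >= 0, "bin"].value_counts().reindex(_BIN_LABELS, fill_value=0)
        )
        out["theta<0"] = (
            rec.loc[rec["theta_m"] < 0, "bin"].value_counts().reindex(_BIN_LABELS, fill_value=0)
        )
    out["total"] = rec["bin"].value_counts().reindex(_BIN_LABELS, fill_value=0)
    counts = pd.DataFrame(out).T
    quartiles = (
        rec.groupby("bin", observed=False)["r_mj"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
    )
    return pd.concat({"counts": counts.T, "residuals": quartiles}, axis=1)


def make_synthetic_collection(
    n_mas: int,
    designs: Sequence[SimDesign] | SimDesign,
    seed: int = 0,
) -> list[MetaDataset]:
    """Synthetic stand-in for a literature-wide collection of meta-analyses.

    Each meta-analysis is generated by the log-binomial simulator; if a
    sequence of designs is given they are cycled through, so a mixture of
    regimes (benign and heavily truncated) can be screened together.
    Deterministic given ``seed``.
    """
    if isinstance(designs, SimDesign):
        designs = [designs]
    out = []
    for i in range(n_mas):
        d = designs[i % len(designs)]
        rng = replicate_rng(seed, i)
        repl = generate_replicate(d, rng)
        out.append(MetaDataset(repl.dataset.studies, ma_id=f"ma{i + 1:04d}"))
    return out
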