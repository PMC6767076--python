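"""Domain types and packaged example datasets.

A meta-analysis of a binary outcome is a collection of 2x2 tables: in study
``j``, ``y_c`` of ``n_c`` control patients and ``y_t`` of ``n_t`` treated
patients had the event.  The measure of effect throughout this package is
the risk ratio (RR), analysed on the log scale as
``log(p_t) - log(p_c)``.

Two classic datasets ship with the package:

``diuretics``
    Nine randomized trials of diuretics for prevention of pre-eclampsia in
    pregnancy (6942 patients in total; control-arm incidence ranging from
    1.9% to 50%).
``tca``
    Sixteen placebo-controlled trials of low-dosage tricyclic
    antidepressants, counting patients with at least one side effect
    (a harm outcome; RR > 1 expected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Z95",
    "StudyTable",
    "MetaDataset",
    "PooledResult",
    "BBFit",
    "SimDesign",
    "validate_dataset",
    "load_fixture",
    "read_csv",
    "read_collection_csv",
]

#: 97.5% standard-normal quantile used for every Wald interval, carried to
#: enough digits that 3-decimal confidence limits are reproducible.
Z95 = 1.959964


@dataclass(frozen=True)
class StudyTable:
    """One study's 2x2 table: events / arm sizes for control and treatment.

    Proportions are always derived from the counts (never stored) so that
    rounding in printed tables cannot drift into computations.
    """

    y_c: int
    n_c: int
    y_t: int
    n_t: int
    study_id: str = ""

    def __post_init__(self) -> None:
        for label, y, n in (("control", self.y_c, self.n_c),
                            ("treatment", self.y_t, self.n_t)):
            if int(n) != n or int(y) != y:
                raise ValueError(f"{self.study_id or 'study'}: non-integer count in {label} arm")
            if n < 1:
                raise ValueError(f"{self.study_id or 'study'}: {label} arm size must be positive")
            if y < 0:
                raise ValueError(f"{self.study_id or 'study'}: negative event count in {label} arm")
            if y > n:
                raise ValueError(
                    f"{self.study_id or 'study'}: {label} events ({y}) exceed arm size ({n})")

    @property
    def p_c(self) -> float:
        return self.y_c / self.n_c

    @property
    def p_t(self) -> float:
        return self.y_t / self.n_t

    @property
    def has_zero_cell(self) -> bool:
        """True if any of the four cells of the 2x2 table is zero."""
        return 0 in (self.y_c, self.y_t, self.n_c - self.y_c, self.n_t - self.y_t)

    @property
    def is_degenerate(self) -> bool:
        """All-zero or all-event study (``y_t + y_c`` equal to 0 or n).

        Such studies carry no information about the RR and are customarily
        discarded before pooling.
        """
        tot = self.y_c + self.y_t
        return tot == 0 or tot == self.n_c + self.n_t

    def swapped(self) -> "StudyTable":
        """Arms exchanged; the log-RR changes sign."""
        return StudyTable(self.y_t, self.n_t, self.y_c, self.n_c, self.study_id)


@dataclass(frozen=True)
class MetaDataset:
    """Ordered collection of studies forming one meta-analysis."""

    studies: tuple[StudyTable, ...]
    ma_id: str = ""

    def __post_init__(self) -> None:
        if len(self.studies) == 0:
            raise ValueError("a meta-analysis needs at least one study")

    @property
    def k(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)

    def __getitem__(self, i):
        return self.studies[i]

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays ``(y_c, n_c, y_t, n_t)`` in study order."""
        y_c = np.array([s.y_c for s in self.studies], dtype=float)
        n_c = np.array([s.n_c for s in self.studies], dtype=float)
        y_t = np.array([s.y_t for s in self.studies], dtype=float)
        n_t = np.array([s.n_t for s in self.studies], dtype=float)
        return y_c, n_c, y_t, n_t

    def drop_degenerate(self) -> tuple["MetaDataset", int]:
        """Remove all-zero / all-event studies; returns (dataset, n_dropped).

        Raises if every study is degenerate.
        """
        keep = tuple(s for s in self.studies if not s.is_degenerate)
        if not keep:
            raise ValueError(f"{self.ma_id or 'dataset'}: all studies are degenerate")
        return MetaDataset(keep, self.ma_id), self.k - len(keep)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "study_id": [s.study_id for s in self.studies],
                "y_c": [s.y_c for s in self.studies],
                "n_c": [s.n_c for s in self.studies],
                "y_t": [s.y_t for s in self.studies],
                "n_t": [s.n_t for s in self.studies],
            }
        )
        if self.ma_id:
            df.insert(0, "ma_id", self.ma_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def validate_dataset(rows: Iterable[Sequence], ma_id: str = "") -> MetaDataset:
    """Build a :class:`MetaDataset` from ``(study_id, y_c, n_c, y_t, n_t)`` rows.

    All malformed rows are reported together in one :class:`ValueError`,
    itemized per study, rather than failing at the first offender.
    """
    studies: list[StudyTable] = []
    problems: list[str] = []
    for i, row in enumerate(rows):
        try:
            sid, y_c, n_c, y_t, n_t = row
            studies.append(StudyTable(int(y_c), int(n_c), int(y_t), int(n_t), str(sid)))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i + 1}: {exc}")
    if problems:
        raise ValueError("invalid dataset:\n  " + "\n  ".join(problems))
    if not studies:
        raise ValueError("empty dataset: no study rows provided")
    return MetaDataset(tuple(studies), ma_id)


def read_csv(path, ma_id: str = "") -> MetaDataset:
    """Read one meta-analysis from CSV with columns study_id,y_c,n_c,y_t,n_t."""
    df = pd.read_csv(path)
    required = {"study_id", "y_c", "n_c", "y_t", "n_t"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CSV is missing columns: {sorted(missing)}")
    return validate_dataset(
        df[["study_id", "y_c", "n_c", "y_t", "n_t"]].itertuples(index=False, name=None),
        ma_id=ma_id or (str(df["ma_id"].iloc[0]) if "ma_id" in df.columns else ""),
    )


def read_collection_csv(path) -> list[MetaDataset]:
    """Read a screening collection: same schema plus a leading ``ma_id`` column."""
    df = pd.read_csv(path)
    if "ma_id" not in df.columns:
        raise ValueError("collection CSV requires an 'ma_id' column")
    out = []
    for ma_id, grp in df.groupby("ma_id", sort=False):
        out.append(
            validate_dataset(
                grp[["study_id", "y_c", "n_c", "y_t", "n_t"]].itertuples(index=False, name=None),
                ma_id=str(ma_id),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class PooledResult:
    """Inverse-variance pooled log-RR with its Wald interval.

    ``het_value``/``het_method`` record the heterogeneity parameter used in
    the weights: an additive between-study variance tau^2 in the
    conventional model, or a multiplicative intra-cluster correlation rho
    under the beta-binomial model.
    """

    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    het_method: str
    het_value: float
    weights: np.ndarray
    theta_j: np.ndarray
    v_j: np.ndarray
    k_used: int
    n_dropped: int = 0

    @property
    def rr(self) -> float:
        return float(np.exp(self.theta_hat))

    @property
    def rr_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def rr_high(self) -> float:
        return float(np.exp(self.ci_high))


@dataclass
class BBFit:
    """Maximum-likelihood fit of the two-arm beta-binomial model.

    Both arms share the intra-cluster correlation ``rho``; the groups
    differ only in the mean event probability (``pi_t`` vs ``pi_c``).
    ``cov`` is the inverse observed information in the fitted
    parametrization (``link`` records which one); ``log_rr`` /
    ``var_log_rr`` carry the delta-method treatment effect.
    """

    pi_t: float
    pi_c: float
    rho: float
    loglik: float
    cov: np.ndarray
    link: str
    converged: bool
    log_rr: float
    var_log_rr: float

    @property
    def rr(self) -> float:
        return float(np.exp(self.log_rr))

    @property
    def se_log_rr(self) -> float:
        return float(np.sqrt(self.var_log_rr))

    @property
    def ci_log_rr(self) -> tuple[float, float]:
        half = Z95 * self.se_log_rr
        return (self.log_rr - half, self.log_rr + half)


@dataclass
class SimDesign:
    """One grid point of a simulation study.

    ``n`` is the total study size split equally between arms; ``option``
    selects the data-generating mechanism: ``"point_mass"`` (out-of-range
    treatment probabilities censored just below 1), ``"truncation"``
    (offending study effects redrawn), or ``"bb"`` (beta-binomial arms).
    """

    k: int
    n: int
    theta: float
    pi_c: float
    tau2: float = 0.0
    rho: float = 0.0
    option: str = "point_mass"
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n % 2 != 0:
            raise ValueError("total study size n must be even (equal arms)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.option not in ("point_mass", "truncation", "bb"):
            raise ValueError(f"unknown option {self.option!r}")
        if self.option == "bb" and self.pi_c * np.exp(self.theta) >= 1.0:
            raise ValueError("beta-binomial generation requires pi_c * exp(theta) < 1")

    @property
    def n_arm(self) -> int:
        return self.n // 2


# ---------------------------------------------------------------------------
# Packaged example data
# ---------------------------------------------------------------------------

_DIURETICS_ROWS = [
    ("1", 14, 136, 14, 131),
    ("2", 17, 134, 21, 385),
    ("3", 24, 48, 14, 57),
    ("4", 18, 40, 6, 38),
    ("5", 35, 760, 12, 1011),
    ("6", 175, 1336, 138, 1370),
    ("7", 20, 524, 15, 506),
    ("8", 2, 103, 6, 108),
    ("9", 40, 102, 65, 153),
]

_TCA_ROWS = [
    ("1", 17, 28, 16, 24),
    ("2", 7, 10, 12, 12),
    ("3", 3, 12, 8, 13),
    ("4", 30, 62, 29, 60),
    ("5", 14, 53, 34, 60),
    ("6", 5, 21, 14, 20),
    ("7", 13, 46, 37, 45),
    ("8", 45, 60, 56, 60),
    ("9", 31, 82, 52, 95),
    ("10", 0, 10, 3, 16),
    ("11", 9, 47, 51, 110),
    ("12", 5, 20, 8, 20),
    ("13", 3, 16, 7, 15),
    ("14", 43, 72, 63, 72),
    ("15", 1, 29, 8, 28),
    ("16", 5, 23, 5, 17),
]

_FIXTURES = {"diuretics": _DIURETICS_ROWS, "tca": _TCA_ROWS}


def load_fixture(name: str) -> MetaDataset:
    """Return a packaged example dataset (``"diuretics"`` or ``"tca"``)."""
    try:
        rows = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}") from None
    return validate_dataset(rows, ma_id=name)
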