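"""Simulated biomarker cohorts with structural missingness.

A cohort row is one participant: a benign/malignant label, tumor thickness,
and the 12 microvessel biomarkers. The four branching-based biomarkers
(MDmean, MDmax, BAmean, BAmax) are structurally missing exactly when the
participant has no branch points (NB = 0).

Marginals are moment-matched to printed group summaries: Gaussian by
default, a shifted log-normal for the right-skewed measures (tau has
support >= 1), and a zero-inflated Poisson for NB parameterized by its mean
and P(NB = 0). Columns are drawn independently per participant — the spec
of a cohort is its set of marginals plus the missingness coupling, not a
joint distribution — so cross-biomarker order constraints (e.g. Dmax >=
Dmean) are not enforced on simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "Marginal",
    "GroupSpec",
    "CohortSpec",
    "generate_cohort",
    "melanoma_group_spec",
    "nevus_group_spec",
    "study_cohort_spec",
    "BIOMARKER_COLUMNS",
    "BRANCHING_BIOMARKERS",
]

BIOMARKER_COLUMNS = [
    "VD",
    "Dmean",
    "Dmax",
    "NV",
    "mvFD",
    "NB",
    "tau_mean",
    "tau_max",
    "MDmean",
    "MDmax",
    "BAmean",
    "BAmax",
]
BRANCHING_BIOMARKERS = ["MDmean", "MDmax", "BAmean", "BAmax"]


@dataclass
class Marginal:
    """Moment-matched marginal: family in {'normal', 'lognormal'} with optional shift.

    'lognormal' matches (mean, sd) of X - shift by a log-normal, so e.g.
    tortuosity uses shift=1 to respect its support [1, inf).
    """

    mean: float
    sd: float
    family: str = "normal"
    shift: float = 0.0
    integer: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("marginal SD must be >= 0")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown marginal family {self.family!r}")
        if self.family == "lognormal" and self.mean <= self.shift:
            raise ValueError("lognormal marginal needs mean > shift")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            x = np.full(n, self.mean)
        elif self.family == "normal":
            x = rng.normal(self.mean, self.sd, size=n)
        else:
            m, s = self.mean - self.shift, self.sd
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            x = self.shift + rng.lognormal(mu, np.sqrt(sigma2), size=n)
        if self.integer:
            x = np.rint(x)
        return x


def _zip_params(mean: float, p_zero: float) -> tuple[float, float]:
    """(pi, lam) of a zero-inflated Poisson with the given mean and P(X=0).

    Falls back to a plain Poisson when p_zero is at or below the Poisson floor
    exp(-lam) for that mean.
    """
    if mean < 0 or not 0.0 <= p_zero <= 1.0:
        raise ValueError("need mean >= 0 and P(zero) in [0, 1]")
    if mean == 0:
        return 1.0, 0.0
    if p_zero <= np.exp(-mean):
        return 0.0, mean

    def f(lam: float) -> float:
        return 1.0 - (mean / lam) * (1.0 - np.exp(-lam)) - p_zero

    lam = brentq(f, mean * (1 + 1e-9), 500.0)
    return 1.0 - mean / lam, lam


@dataclass
class GroupSpec:
    """One study arm: sample size, thickness moments, biomarker marginals, NB law."""

    n: int
    thickness_mean_mm: float
    thickness_sd_mm: float
    marginals: dict[str, Marginal]
    nb_mean: float
    p_nb_zero: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if self.thickness_sd_mm < 0:
            raise ValueError("thickness SD must be >= 0")
        if not 0.0 <= self.p_nb_zero <= 1.0:
            raise ValueError("P(NB=0) must lie in [0, 1]")
        missing = [c for c in BIOMARKER_COLUMNS if c != "NB" and c not in self.marginals]
        if missing:
            raise ValueError(f"missing marginals for {missing}")


@dataclass
class CohortSpec:
    malignant: GroupSpec
    benign: GroupSpec
    seed: int = 0
    gaussian_only: bool = False  # force Gaussian marginals for every biomarker

    groups: dict = field(init=False)

    def __post_init__(self) -> None:
        self.groups = {"malignant": self.malignant, "benign": self.benign}


def melanoma_group_spec(n: int = 21) -> GroupSpec:
    """Malignant arm, moment-matched to the study's printed group summaries."""
    return GroupSpec(
        n=n,
        thickness_mean_mm=3.81,
        thickness_sd_mm=2.63,
        marginals={
            "VD": Marginal(0.20, 0.11),
            "Dmean": Marginal(459.89, 174.46),
            "Dmax": Marginal(908.56, 359.09),
            "NV": Marginal(16.57, 11.84, family="lognormal", integer=True),
            "mvFD": Marginal(1.32, 0.11),
            "tau_mean": Marginal(1.14, 0.21, family="lognormal", shift=1.0),
            "tau_max": Marginal(1.91, 1.81, family="lognormal", shift=1.0),
            "MDmean": Marginal(0.40, 0.18),
            "MDmax": Marginal(0.70, 0.26),
            "BAmean": Marginal(99.53, 17.72),
            "BAmax": Marginal(141.25, 28.57),
        },
        nb_mean=8.90,
        p_nb_zero=0.0,
    )


def nevus_group_spec(n: int = 15) -> GroupSpec:
    """Benign arm; P(NB=0)=7/15 reproduces the observed branching missingness."""
    return GroupSpec(
        n=n,
        thickness_mean_mm=1.70,
        thickness_sd_mm=0.40,
        marginals={
            "VD": Marginal(0.12, 0.09),
            "Dmean": Marginal(381.83, 176.38),
            "Dmax": Marginal(624.32, 341.80),
            "NV": Marginal(6.73, 5.74, family="lognormal", integer=True),
            "mvFD": Marginal(1.14, 0.16),
            "tau_mean": Marginal(1.05, 0.03, family="lognormal", shift=1.0),
            "tau_max": Marginal(1.18, 0.21, family="lognormal", shift=1.0),
            "MDmean": Marginal(0.40, 0.18),
            "MDmax": Marginal(0.66, 0.22),
            "BAmean": Marginal(99.74, 32.92),
            "BAmax": Marginal(140.28, 35.24),
        },
        nb_mean=3.07,
        p_nb_zero=7.0 / 15.0,
    )


def study_cohort_spec(
    n_malignant: int = 21, n_benign: int = 15, seed: int = 0, gaussian_only: bool = False
) -> CohortSpec:
    return CohortSpec(
        malignant=melanoma_group_spec(n_malignant),
        benign=nevus_group_spec(n_benign),
        seed=seed,
        gaussian_only=gaussian_only,
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labeled cohort table from a :class:`CohortSpec`.

    Returns a DataFrame with columns id, label, thickness_mm, the 12
    biomarkers, and measurable_MD_BA. The branching biomarkers are NaN
    exactly where NB = 0 (measurable_MD_BA = 0).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    next_id = 0
    for label, grp in spec.groups.items():
        n = grp.n
        if n == 0:
            continue
        pi, lam = _zip_params(grp.nb_mean, grp.p_nb_zero)
        nb = np.where(rng.random(n) < pi, 0, rng.poisson(lam, size=n))
        row: dict[str, np.ndarray] = {}
        for name, marg in grp.marginals.items():
            if spec.gaussian_only and marg.family != "normal":
                marg = Marginal(marg.mean, marg.sd, integer=marg.integer)
            row[name] = marg.sample(n, rng)
        measurable = nb > 0
        for name in BRANCHING_BIOMARKERS:
            row[name] = np.where(measurable, row[name], np.nan)
        df = pd.DataFrame(
            {
                "id": np.arange(next_id, next_id + n),
                "label": label,
                "thickness_mm": rng.normal(grp.thickness_mean_mm, grp.thickness_sd_mm, size=n),
                **{c: (nb if c == "NB" else row[c]) for c in BIOMARKER_COLUMNS},
                "measurable_MD_BA": measurable.astype(int),
            }
        )
        next_id += n
        frames.append(df)
    if not frames:
        cols = ["id", "label", "thickness_mm", *BIOMARKER_COLUMNS, "measurable_MD_BA"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)
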