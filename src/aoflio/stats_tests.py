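"""Multivariate and agreement statistics for phasor-cluster comparisons.

Hotelling's T-squared generalizes the t-test to bivariate means; the paired
(dependent) form operates on per-location coordinate differences, so it is
the right test for comparing the same clusters across imaging sessions.  The
intraclass correlation coefficient quantifies test-retest agreement of scalar
summaries; the variant used here is the two-way random-effects,
absolute-agreement, single-measurement ICC, commonly written ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Hotelling2Result",
    "IccResult",
    "hotelling_paired",
    "hotelling_two_sample",
    "icc_agreement",
    "cluster_summary",
    "paired_ttest",
]


@dataclass(frozen=True)
class Hotelling2Result:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float

    def __post_init__(self) -> None:
        if self.t2 < -1e-12:
            raise ValueError("T-squared cannot be negative")


@dataclass(frozen=True)
class IccResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def hotelling_paired(x: np.ndarray, y: np.ndarray) -> Hotelling2Result:
    """Two-sample dependent (paired) Hotelling's T-squared for bivariate data.

    With differences D = X - Y, T^2 = n m' S_D^{-1} m where m is the mean
    difference and S_D the sample covariance of D; the F reference
    distribution is F(p, n - p) with p = 2 via
    F = T^2 (n - p) / (p (n - 1)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("x and y must be matching (n, 2) arrays")
    n, p = x.shape
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    d = x - y
    if np.all(d == 0.0):
        # identical samples: no evidence of any shift
        return Hotelling2Result(t2=0.0, f_stat=0.0, df1=p, df2=n - p,
                                p_value=1.0)
    m = d.mean(axis=0)
    cov = np.cov(d, rowvar=False, ddof=1)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or abs(det) < 1e-300:
        raise np.linalg.LinAlgError("singular difference covariance")
    t2 = float(n * m @ np.linalg.solve(cov, m))
    t2 = max(t2, 0.0)
    f_stat = t2 * (n - p) / (p * (n - 1))
    p_value = float(sps.f.sf(f_stat, p, n - p))
    return Hotelling2Result(t2=t2, f_stat=f_stat, df1=p, df2=n - p,
                            p_value=p_value)


def hotelling_two_sample(x: np.ndarray, y: np.ndarray) -> Hotelling2Result:
    """Independent two-sample Hotelling's T-squared with pooled covariance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != 2 or y.shape[1] != 2:
        raise ValueError("inputs must be (n, 2) arrays")
    n1, n2 = len(x), len(y)
    p = 2
    if n1 < 3 or n2 < 3:
        raise ValueError("each sample needs at least 3 observations")
    d = x.mean(axis=0) - y.mean(axis=0)
    s1 = np.cov(x, rowvar=False, ddof=1)
    s2 = np.cov(y, rowvar=False, ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if abs(np.linalg.det(pooled)) < 1e-300:
        raise np.linalg.LinAlgError("singular pooled covariance")
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(pooled, d))
    t2 = max(t2, 0.0)
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (p * (n1 + n2 - 2))
    p_value = float(sps.f.sf(f_stat, p, df2))
    return Hotelling2Result(t2=t2, f_stat=f_stat, df1=p, df2=df2,
                            p_value=p_value)


def icc_agreement(data: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``data`` is an n_subjects x n_sessions matrix with no missing cells.
    Computed from the standard two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x sessions matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom
    return IccResult(icc=float(icc), model="ICC(2,1)", n_subjects=n,
                     n_raters=k)


def cluster_summary(points: np.ndarray) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (ddof=1) of each phasor coordinate of a cluster."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n >= 2, 2) array of (g, s)")
    return {
        "mean": (float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        "sd": (float(pts[:, 0].std(ddof=1)), float(pts[:, 1].std(ddof=1))),
    }


def paired_ttest(a: np.ndarray, b: np.ndarray):
    """Thin pass-through to scipy's paired two-tailed t-test."""
    return sps.ttest_rel(np.asarray(a, float), np.asarray(b, float))
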