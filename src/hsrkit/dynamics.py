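"""Regulon-wide reporter dynamics: logistic induction fits, fold-change
normalization, PCA and the rate-versus-time kinetic tradeoff.

Each Hsf1 target gene's mean reporter course over heat shock is summarized by
a four-parameter logistic in time,

    f(t) = B + (M - B) / (1 + exp(-k (t - t50))),

chosen because the two statistics of interest — the time to half-maximal
induction and the maximal induction rate — are closed-form in it: the
half-max time is the inflection ``t50`` and the maximal slope is
``k (M - B) / 4``, attained there.

PCA treats genes as observations and time points as variables; columns are
mean-centered but *not* variance-scaled, so that expression magnitude can
dominate the first component on the raw matrix.  Normalizing each gene by
its basal (t = 0) level first isolates the induction dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize as lm_minimize
from scipy import stats

__all__ = [
    "GeneTimeCourse",
    "LogisticFit",
    "RegulonMatrix",
    "PCAResult",
    "TradeoffFit",
    "fit_logistic",
    "fit_logistic_arrays",
    "logistic",
    "time_to_half_max",
    "max_induction_rate",
    "fold_change_normalize",
    "run_pca",
    "tradeoff_fit",
]


def logistic(t, B, M, k, t50):
    """Four-parameter logistic induction curve."""
    return B + (M - B) / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t50)))


@dataclass(frozen=True)
class GeneTimeCourse:
    """Mean reporter level of one gene over the time course, with replicates."""

    gene: str
    times: np.ndarray
    means: np.ndarray
    replicates: Optional[np.ndarray] = None  # (n_reps, n_times)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.means, dtype=float)
        if t.shape != m.shape or t.ndim != 1:
            raise ValueError("times/means must be 1-d and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("reporter levels must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "means", m)
        if self.replicates is not None:
            r = np.asarray(self.replicates, dtype=float)
            if r.ndim != 2 or r.shape[1] != len(t):
                raise ValueError("replicates must be (n_reps, n_times)")
            object.__setattr__(self, "replicates", r)


@dataclass(frozen=True)
class LogisticFit:
    B: float
    M: float
    k: float
    t50: float
    rss: float
    degenerate: bool = False
    reason: str = ""

    @property
    def fold_change(self) -> float:
        if self.degenerate:
            return 1.0
        return self.M / self.B if self.B > 0 else float("nan")

    def predict(self, t) -> np.ndarray:
        return logistic(t, self.B, self.M, self.k, self.t50)


def fit_logistic_arrays(
    times: np.ndarray, values: np.ndarray, horizon: Optional[float] = None
) -> LogisticFit:
    """Least-squares logistic fit on plain arrays (shared by the dose-response
    time-course fits).  Degenerate inputs — constant series, or series the
    logistic cannot beat a flat line on (e.g. monotone decreasing) — come back
    flagged with NaN parameters rather than raising."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 time points for a 4-parameter fit")
    horizon = float(t[-1]) if horizon is None else horizon

    vmin, vmax = float(v.min()), float(v.max())
    rss_flat = float(np.sum((v - v.mean()) ** 2))
    if vmax - vmin <= 1e-12 * max(abs(vmax), 1.0):
        return LogisticFit(
            B=vmin, M=vmin, k=float("nan"), t50=float("nan"),
            rss=0.0, degenerate=True, reason="constant",
        )

    mid = 0.5 * (vmin + vmax)
    t50_init = float(t[np.argmin(np.abs(v - mid))])
    pars = Parameters()
    pars.add("B", value=vmin, min=0.0)
    pars.add("delta", value=max(vmax - vmin, 1e-12), min=0.0)  # enforces M >= B
    pars.add("M", expr="B + delta")
    pars.add("k", value=4.0 / (t[-1] - t[0]), min=1e-5, max=10.0)
    pars.add("t50", value=t50_init, min=0.0, max=2.0 * horizon)

    def residual(p):
        return logistic(t, p["B"], p["M"], p["k"], p["t50"]) - v

    try:
        out = lm_minimize(residual, pars, method="leastsq")
    except Exception:
        out = None
    if out is None or not out.success:
        return LogisticFit(
            B=float("nan"), M=float("nan"), k=float("nan"), t50=float("nan"),
            rss=float("nan"), degenerate=True, reason="non-convergence",
        )
    fit_rss = float(np.sum(np.asarray(out.residual) ** 2))
    B = float(out.params["B"].value)
    M = float(out.params["M"].value)
    k = float(out.params["k"].value)
    t50 = float(out.params["t50"].value)
    # no better than a flat line => no induction signal (covers decreasing series)
    if fit_rss > 0.95 * rss_flat or (M - B) <= 1e-9 * max(vmax, 1.0):
        return LogisticFit(
            B=B, M=M, k=float("nan"), t50=float("nan"),
            rss=fit_rss, degenerate=True, reason="no-induction",
        )
    return LogisticFit(B=B, M=M, k=k, t50=t50, rss=fit_rss)


def fit_logistic(tc: GeneTimeCourse) -> LogisticFit:
    """Logistic induction fit of one gene's mean time course."""
    return fit_logistic_arrays(tc.times, tc.means)


def time_to_half_max(fit: LogisticFit) -> float:
    """Time at which the fitted curve crosses B + (M - B)/2; exact = t50."""
    if fit.degenerate:
        return float("nan")
    return fit.t50


def max_induction_rate(fit: LogisticFit) -> float:
    """Maximal slope of the fitted logistic, k (M - B) / 4, attained at t50."""
    if fit.degenerate:
        return float("nan")
    return fit.k * (fit.M - fit.B) / 4.0


@dataclass(frozen=True)
class RegulonMatrix:
    """Genes x time-points matrix of mean reporter levels."""

    genes: tuple
    times: np.ndarray
    values: np.ndarray  # (n_genes, n_times)
    kind: str = "raw"   # 'raw' | 'fold_change'

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.shape != (len(self.genes), len(t)):
            raise ValueError("values shape must be (n_genes, n_times)")
        if np.any(~np.isfinite(v)):
            raise ValueError("matrix must have no missing cells")
        if self.kind not in ("raw", "fold_change"):
            raise ValueError("kind must be 'raw' or 'fold_change'")
        if self.kind == "raw" and np.any(v <= 0):
            raise ValueError("raw matrix must be strictly positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "genes", tuple(self.genes))

    @classmethod
    def from_timecourses(cls, courses: Sequence[GeneTimeCourse]) -> "RegulonMatrix":
        times = courses[0].times
        for tc in courses:
            if not np.array_equal(tc.times, times):
                raise ValueError("all gene time courses must share the same times")
        return cls(
            genes=tuple(tc.gene for tc in courses),
            times=times,
            values=np.vstack([tc.means for tc in courses]),
        )


def fold_change_normalize(m: RegulonMatrix) -> RegulonMatrix:
    """Divide each gene row by its basal (t = 0) level."""
    if m.kind != "raw":
        raise ValueError("fold_change_normalize expects a raw matrix")
    basal = m.values[:, 0]
    if np.any(basal <= 0):
        raise ValueError("zero or negative basal level; fold change undefined")
    return RegulonMatrix(
        genes=m.genes, times=m.times, values=m.values / basal[:, None],
        kind="fold_change",
    )


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray            # (n_genes, n_components)
    loadings: np.ndarray          # (n_components, n_times)
    variance_ratio: np.ndarray    # fractions, sum to 1

    def __post_init__(self) -> None:
        vr = np.asarray(self.variance_ratio, dtype=float)
        if np.any(vr < -1e-12) or np.any(vr > 1 + 1e-12):
            raise ValueError("variance fractions must lie in [0, 1]")
        if abs(vr.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")


def run_pca(m: RegulonMatrix) -> PCAResult:
    """PCA with genes as observations and time points as variables.

    Columns are mean-centered but not scaled.  Sign convention: each loading
    vector's largest-magnitude entry is positive, which makes scores
    deterministic across SVD implementations.
    """
    from sklearn.decomposition import PCA

    X = m.values
    if X.shape[0] < 3 or X.shape[1] < 3:
        raise ValueError("need at least 3 genes and 3 time points")
    if np.allclose(X - X.mean(axis=0), 0.0):
        raise ValueError("matrix has rank 0 after centering")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for j in range(loadings.shape[0]):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    vr = pca.explained_variance_ratio_
    vr = vr / vr.sum()
    return PCAResult(scores=scores, loadings=loadings, variance_ratio=vr)


@dataclass(frozen=True)
class TradeoffFit:
    """OLS of log10(max induction rate) on log10(time to half max), with a
    bootstrap 95% confidence band on slope and intercept."""

    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    n_genes: int

    def __post_init__(self) -> None:
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1]):
            raise ValueError("slope must lie inside its CI")
        if not (self.intercept_ci[0] <= self.intercept <= self.intercept_ci[1]):
            raise ValueError("intercept must lie inside its CI")


def tradeoff_fit(
    t_half: np.ndarray,
    max_rate: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> TradeoffFit:
    """Quantify the tradeoff between induction speed and induction rate."""
    th = np.asarray(t_half, dtype=float)
    mr = np.asarray(max_rate, dtype=float)
    keep = np.isfinite(th) & np.isfinite(mr) & (th > 0) & (mr > 0)
    th, mr = th[keep], mr[keep]
    if len(th) < 5:
        raise ValueError("need at least 5 non-degenerate genes")
    x, y = np.log10(th), np.log10(mr)
    slope, intercept = np.polyfit(x, y, 1)

    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) < 1e-12:
            boot[b] = (slope, intercept)
            continue
        boot[b] = np.polyfit(x[idx], y[idx], 1)
    s_lo, s_hi = np.percentile(boot[:, 0], [2.5, 97.5])
    i_lo, i_hi = np.percentile(boot[:, 1], [2.5, 97.5])
    # percentile bands are widened to include the point estimate if a skewed
    # bootstrap distribution would otherwise exclude it
    s_lo, s_hi = min(s_lo, slope), max(s_hi, slope)
    i_lo, i_hi = min(i_lo, intercept), max(i_hi, intercept)
    return TradeoffFit(
        slope=float(slope), intercept=float(intercept),
        slope_ci=(float(s_lo), float(s_hi)),
        intercept_ci=(float(i_lo), float(i_hi)),
        n_genes=int(n),
    )
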