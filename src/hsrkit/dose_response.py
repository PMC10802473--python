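"""Ethanol dose-response analysis.

Endpoint (4-hour) reporter levels across an ethanol concentration grid are
fit to a Hill function to extract the half-maximal activation concentration
(EC50); relative growth across the same grid is fit to the mirrored,
decreasing Hill form to extract the half-maximal growth-inhibition
concentration (IC50).  Per-concentration reporter time courses are fit to a
sigmoid in time at activating doses and to a quadratic polynomial at doses
too low to produce a sigmoidal rise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .dynamics import LogisticFit, fit_logistic_arrays

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "TimeCourseFit",
    "hill_curve",
    "fit_hill",
    "fit_concentration_time_course",
    "growth_dose_response",
    "SIGMOID_MIN_CONC",
]

# doses at/above this (% v/v) give sigmoidal reporter time courses; below,
# the response is a slow drift better served by a polynomial
SIGMOID_MIN_CONC = 6.0


@dataclass(frozen=True)
class DoseResponseCurve:
    """Response per ethanol concentration (mean over replicates)."""

    concentrations: np.ndarray  # % v/v, strictly increasing, >= 0
    response: np.ndarray
    direction: str              # 'increasing' (reporter) | 'decreasing' (growth)
    replicates: Optional[np.ndarray] = None  # (n_reps, n_conc)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations/response must be 1-d, equal length")
        if np.any(c < 0) or not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be non-negative, strictly increasing")
        if len(c) < 5:
            raise ValueError("need at least 5 concentrations for fitting")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError("direction must be 'increasing' or 'decreasing'")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class HillFit:
    floor: float
    ceiling: float
    C50: float    # % v/v at half-maximal response
    n: float      # Hill coefficient
    rss: float
    direction: str
    degenerate: bool = False

    def predict(self, c) -> np.ndarray:
        return hill_curve(c, self.floor, self.ceiling, self.C50, self.n, self.direction)


def hill_curve(c, floor, ceiling, C50, n, direction="increasing"):
    """Hill dose-response; 'decreasing' is the mirrored form (ceiling at c=0)."""
    c = np.asarray(c, dtype=float)
    occ = np.where(c > 0, c**n / (C50**n + c**n), 0.0)
    if direction == "increasing":
        return floor + (ceiling - floor) * occ
    return floor + (ceiling - floor) * (1.0 - occ)


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares Hill fit; by definition the fitted curve passes through
    (floor + ceiling)/2 at the fitted C50."""
    c, r = curve.concentrations, curve.response
    rmin, rmax = float(r.min()), float(r.max())
    if rmax - rmin <= 1e-12 * max(abs(rmax), 1.0):
        return HillFit(
            floor=rmin, ceiling=rmax, C50=float("nan"), n=float("nan"),
            rss=0.0, direction=curve.direction, degenerate=True,
        )
    mid = 0.5 * (rmin + rmax)
    c50_init = float(c[np.argmin(np.abs(r - mid))])
    c_pos = c[c > 0]
    c50_init = max(c50_init, float(c_pos.min()) if len(c_pos) else 1.0)

    pars = Parameters()
    pars.add("floor", value=rmin, min=0.0)
    pars.add("span", value=max(rmax - rmin, 1e-12), min=0.0)  # ceiling >= floor
    pars.add("ceiling", expr="floor + span")
    pars.add("C50", value=c50_init, min=1e-6, max=10.0 * float(c.max()))
    pars.add("n", value=4.0, min=0.5, max=20.0)

    def residual(p):
        return hill_curve(c, p["floor"], p["ceiling"], p["C50"], p["n"],
                          curve.direction) - r

    out = lm_minimize(residual, pars, method="leastsq")
    if not out.success:
        return HillFit(
            floor=float("nan"), ceiling=float("nan"), C50=float("nan"),
            n=float("nan"), rss=float("nan"), direction=curve.direction,
            degenerate=True,
        )
    return HillFit(
        floor=float(out.params["floor"].value),
        ceiling=float(out.params["ceiling"].value),
        C50=float(out.params["C50"].value),
        n=float(out.params["n"].value),
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
        direction=curve.direction,
    )


@dataclass(frozen=True)
class TimeCourseFit:
    """Per-concentration reporter time-course fit, recording which curve
    family was used."""

    concentration: float
    family: str                      # 'sigmoid' | 'polynomial'
    logistic: Optional[LogisticFit]  # set when family == 'sigmoid'
    poly_coeffs: Optional[np.ndarray]  # set when family == 'polynomial'
    rss: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "sigmoid":
            return self.logistic.predict(t)
        return np.polyval(self.poly_coeffs, t)


def fit_concentration_time_course(
    times: np.ndarray,
    values: np.ndarray,
    concentration: float,
    sigmoid_min_conc: float = SIGMOID_MIN_CONC,
) -> TimeCourseFit:
    """Fit one dose's reporter time course with the family appropriate to the
    dose: sigmoid at >= ``sigmoid_min_conc`` % v/v, quadratic below."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 time points")
    if concentration >= sigmoid_min_conc:
        lf = fit_logistic_arrays(t, v)
        rss = lf.rss if np.isfinite(lf.rss) else float("nan")
        return TimeCourseFit(
            concentration=float(concentration), family="sigmoid",
            logistic=lf, poly_coeffs=None, rss=rss,
        )
    coeffs = np.polyfit(t, v, 2)
    rss = float(np.sum((np.polyval(coeffs, t) - v) ** 2))
    return TimeCourseFit(
        concentration=float(concentration), family="polynomial",
        logistic=None, poly_coeffs=coeffs, rss=rss,
    )


def growth_dose_response(
    series_by_conc, shift_time_min: float = 240.0
) -> DoseResponseCurve:
    """Assemble a decreasing dose-response curve from growth assays.

    For each ethanol concentration, the log-phase maximal growth rate is
    extracted from every replicate OD600 series, averaged, and expressed
    relative to the 0% concentration.
    """
    from .cytometry_growth import max_growth_rate

    if 0.0 not in series_by_conc:
        raise ValueError("growth panel must include the 0% reference")
    conc = np.array(sorted(series_by_conc), dtype=float)
    rates = np.empty((len(conc),))
    reps_rel = []
    for i, c in enumerate(conc):
        per_rep = np.array(
            [max_growth_rate(s, shift_time_min).rate for s in series_by_conc[c]]
        )
        rates[i] = per_rep.mean()
        reps_rel.append(per_rep)
    ref = rates[conc == 0.0][0]
    if ref <= 0:
        raise ValueError("reference growth rate must be positive")
    n_reps = min(len(r) for r in reps_rel)
    replicates = np.vstack([r[:n_reps] for r in reps_rel]).T / ref
    return DoseResponseCurve(
        concentrations=conc,
        response=rates / ref,
        direction="decreasing",
        replicates=replicates,
    )
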