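"""Fitting the circuit model to reporter time courses.

Two regimes, matching how the model is confronted with data:

* **auxiliary mutants** (fes1/ubi4/gre3/pin3-like ΔHSE strains): a single
  parameter — the productive-release scale — is reduced from the wild-type
  calibration until the residual sum of squares against the observed HSE-YFP
  fold-change course is minimal;
* **ethanol baseline**: the wild-type ethanol response is captured by
  re-tuning only the client-production multiplier ``s_eth`` and the
  client–Hsp70 association ``k_bU``; the core-loop parameters are untouched.

Goodness of fit is the unweighted residual sum of squares.  Per-time
standard deviations are carried for diagnostics and an optional weighted
variant, but are unused by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .model_core import (
    ModelParameters,
    StressProtocol,
    Trajectory,
    basal_steady_state,
    simulate,
)

__all__ = [
    "ObservedTimeCourse",
    "FitResult",
    "rss",
    "fit_release_scale",
    "fit_ethanol_baseline",
    "FittingError",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ObservedTimeCourse:
    """A strain's measured mean fold-change course (flow-cytometry medians).

    ``truth`` optionally carries the generating parameters when the course is
    synthetic, so recovery tests can close the loop.
    """

    strain: str
    times: np.ndarray
    values: np.ndarray          # mean fold change, first entry 1
    sd: Optional[np.ndarray] = None
    n_reps: int = 3
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0.0:
            raise ValueError("first observation must be at t = 0")
        if abs(v[0] - 1.0) > 1e-9:
            raise ValueError("fold change at t = 0 must be 1")
        if np.any(v <= 0):
            raise ValueError("fold-change values must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != t.shape or np.any(sd < 0):
                raise ValueError("sd must match times and be non-negative")
            object.__setattr__(self, "sd", sd)


@dataclass(frozen=True)
class FitResult:
    release_scale: float
    rss: float
    profile_scales: np.ndarray
    profile_rss: np.ndarray
    fitted_values: np.ndarray   # model fold change at the observation times
    converged: bool
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("RSS must be >= 0")


def rss(observed: ObservedTimeCourse, simulated: Trajectory) -> float:
    """Unweighted residual sum of squares between observed fold change and
    the simulated reporter fold change at the observation times.

    Observation times must be a subset of the trajectory's sample times.
    """
    sim_fc = _fold_change_at(observed.times, simulated)
    return float(np.sum((observed.values - sim_fc) ** 2))


def _fold_change_at(times: np.ndarray, traj: Trajectory) -> np.ndarray:
    idx = np.searchsorted(traj.times, times)
    ok = (idx < len(traj.times)) & np.isclose(
        traj.times[np.minimum(idx, len(traj.times) - 1)], times, atol=1e-9
    )
    if not ok.all():
        missing = np.asarray(times)[~ok]
        raise ValueError(f"observation times not in trajectory samples: {missing}")
    return traj.yfp_fold_change[idx]


def _golden_section(f, a: float, b: float, xtol: float) -> tuple[float, float]:
    """Minimize a unimodal scalar function on [a, b] by golden-section search."""
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > xtol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (c, fc) if fc < fd else (d, fd)


def fit_release_scale(
    observed: ObservedTimeCourse,
    base: ModelParameters,
    protocol: StressProtocol,
    bounds: tuple[float, float] = (0.01, 1.0),
    n_grid: int = 40,
    xtol: float = 1e-3,
) -> FitResult:
    """Single-parameter fit of an auxiliary-feedback mutant.

    Scans ``release_scale`` on a log-spaced grid over ``bounds``, then refines
    the best bracket by golden-section search.  The scale multiplies the
    wild-type productive-release rate ``k_rel``; the search is bounded above
    by 1 because auxiliary mutants can only lose release capacity.
    """
    cache: dict[float, Trajectory] = {}
    last_ss: list = [None]

    def sim_at(scale: float) -> Trajectory:
        if scale not in cache:
            params = base.replace(k_rel=base.k_rel * scale)
            # warm-start the steady-state search from the previous scale's
            # fixed point; adjacent scales have nearby basal states
            ss = basal_steady_state(params, guess=last_ss[0])
            last_ss[0] = ss
            cache[scale] = simulate(params, protocol, initial_state=ss)
        return cache[scale]

    def obj(scale: float) -> float:
        try:
            return rss(observed, sim_at(scale))
        except Exception as exc:  # solver failure at an extreme scale
            raise FittingError(f"simulation failed at scale {scale}: {exc}") from exc

    grid = np.geomspace(bounds[0], bounds[1], n_grid)
    grid_rss = np.array([obj(s) for s in grid])
    i = int(np.argmin(grid_rss))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    best_scale, best_rss = _golden_section(obj, float(lo), float(hi), xtol)
    if grid_rss[i] < best_rss:
        best_scale, best_rss = float(grid[i]), float(grid_rss[i])
    at_boundary = i in (0, n_grid - 1)
    fitted = _fold_change_at(observed.times, sim_at(best_scale))
    return FitResult(
        release_scale=float(best_scale),
        rss=float(best_rss),
        profile_scales=grid,
        profile_rss=grid_rss,
        fitted_values=fitted,
        converged=True,
        at_boundary=at_boundary,
    )


def fit_ethanol_baseline(
    observed_wt: ObservedTimeCourse,
    base: ModelParameters,
    protocol: StressProtocol,
    max_fev_per_start: int = 60,
) -> ModelParameters:
    """Re-calibrate the wild-type model for ethanol stress.

    Only two parameters move: the stress client-production multiplier
    ``s_eth`` and the client–Hsp70 association ``k_bU``.  Both are optimized
    as multiplicative factors in log space (scale-free, positivity built in)
    by Nelder–Mead local searches from a 3x3 grid of starting factors; the
    best start is then polished.  All other parameters are returned bit-equal
    to ``base``.
    """
    if protocol.stress_type != "ethanol":
        raise ValueError("fit_ethanol_baseline requires an ethanol protocol")

    last_ss: list = [None]

    def params_for(logm: np.ndarray) -> Optional[ModelParameters]:
        s_eth = base.s_eth * math.exp(logm[0])
        k_bU = base.k_bU * math.exp(logm[1])
        if s_eth < 1.0:
            return None
        return base.replace(s_eth=s_eth, k_bU=k_bU)

    def obj(logm: np.ndarray) -> float:
        p = params_for(logm)
        if p is None:
            return 1e12
        try:
            ss = basal_steady_state(p, guess=last_ss[0])
            last_ss[0] = ss
            return rss(observed_wt, simulate(p, protocol, initial_state=ss))
        except Exception:
            return 1e12

    starts = [
        np.array([ls, lb])
        for ls in (math.log(1 / 3), 0.0, math.log(3))
        for lb in (math.log(1 / 3), 0.0, math.log(3))
    ]
    best = None
    for x0 in starts:
        res = minimize(
            obj, x0, method="Nelder-Mead",
            options={"maxfev": max_fev_per_start, "xatol": 1e-3, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        raise FittingError("ethanol baseline fit failed from all starts")
    res = minimize(
        obj, best.x, method="Nelder-Mead",
        options={"maxfev": 200, "xatol": 1e-4, "fatol": 1e-12},
    )
    final = res if res.fun <= best.fun else best
    params = params_for(final.x)
    if params is None:
        raise FittingError("ethanol baseline fit converged to invalid parameters")
    return params
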