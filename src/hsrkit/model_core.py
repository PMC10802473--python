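"""Deterministic ODE model of the Hsf1–Hsp70 heat shock response circuit.

The circuit couples two feedback mechanisms:

* the **core expression loop** — free Hsf1 drives Hsp70 synthesis, and free
  Hsp70 binds and represses Hsf1;
* an **auxiliary feedback** on chaperone cycling — the "productive release"
  rate ``k_rel`` at which Hsp70 is released from a folded client and returned
  to the available pool.  Strains lacking Hsf1-dependent induction of release
  factors (Fes1-like mutants) are modeled by scaling this single parameter
  down.

Stress raises the influx of unfolded clients, which titrate Hsp70 away from
Hsf1.  Client accumulation additionally weakens the Hsp70–Hsf1 association
rate through a Hill-type "affinity switch" standing in for the titration of
the J-domain protein Sis1 away from Hsf1.  Pathway output is read out by an
HSE-driven YFP reporter with explicit maturation.

Species (arbitrary units): free clients ``U``, free Hsp70 ``Hf``,
Hsp70–client complex ``HU``, Hsp70–Hsf1 complex ``HF``, free Hsf1 ``Ff``,
immature YFP ``Y`` and mature YFP ``Ym``.  Total Hsf1 is conserved:
``Ff + HF = F_tot``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SPECIES",
    "ModelParameters",
    "StrainGenotype",
    "StressProtocol",
    "SystemState",
    "Trajectory",
    "SteadyStateError",
    "IntegrationError",
    "hill",
    "make_parameters",
    "stress_multiplier",
    "derivatives",
    "basal_steady_state",
    "simulate",
]

SPECIES = ("U", "Hf", "HU", "HF", "Ff", "Y", "Ym")

_NEG_TOL = -1e-9


class SteadyStateError(RuntimeError):
    """Raised when the pre-stress steady state cannot be located."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces invalid states."""


def hill(x: float, K: float, n: float) -> float:
    """Activating Hill function x^n / (K^n + x^n), safe at x = 0."""
    if np.ndim(x) == 0 and x <= 0.0:
        return 0.0
    xn = np.asarray(x, dtype=float) ** n
    return xn / (K**n + xn)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the circuit.  Units: a.u. for amounts, minutes for time.

    ``k_rel`` is the auxiliary-feedback parameter: productive (client-consuming)
    release of Hsp70 from clients.  ``k_offU`` is plain, non-productive
    dissociation and is small by default so the Fes1-tunable path dominates.
    """

    k_U0: float      # basal client production (a.u./min)
    s_heat: float    # fold-increase of client production under heat
    s_eth: float     # fold-increase of client production under ethanol
    k_bU: float      # Hsp70-client association (1/(a.u. min))
    k_rel: float     # productive client release (1/min) -- auxiliary feedback
    k_offU: float    # non-productive client release (1/min)
    k_bF0: float     # maximal Hsp70-Hsf1 association (1/(a.u. min))
    k_uF: float      # Hsp70-Hsf1 dissociation (1/min)
    K_sis: float     # client level at half-maximal affinity switch (a.u.)
    h_sis: float     # affinity-switch Hill coefficient
    beta0: float     # basal Hsp70 synthesis (a.u./min)
    beta1: float     # maximal Hsf1-dependent Hsp70 synthesis (a.u./min)
    K_hsf: float     # Hill constant for Hsf1-driven Hsp70 synthesis (a.u.)
    n_hsf: float     # Hill coefficient for Hsp70 synthesis
    alpha_y: float   # maximal HSE-YFP transcription rate (a.u./min)
    K_y: float       # Hill constant of the reporter promoter (a.u.)
    n_y: float       # Hill coefficient of the reporter promoter
    m_mat: float     # YFP maturation rate (1/min)
    gamma: float     # dilution/degradation applied to all species (1/min)
    F_tot: float     # total Hsf1 (a.u., conserved)

    def __post_init__(self) -> None:
        for name in (
            "k_U0", "s_heat", "s_eth", "k_bU", "k_rel", "k_offU", "k_bF0",
            "k_uF", "K_sis", "h_sis", "beta0", "beta1", "K_hsf", "n_hsf",
            "alpha_y", "K_y", "n_y", "m_mat", "gamma", "F_tot",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.F_tot <= 0:
            raise ValueError("F_tot must be > 0")
        for name in ("h_sis", "n_hsf", "n_y"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("s_heat", "s_eth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (stress raises client influx)")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (validation re-runs)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class StrainGenotype:
    """A strain to simulate, expressed as an override of the base parameters.

    ``kind``:
      * ``WT`` — wild type;
      * ``HSP70_DFBL`` — core feedback broken: no Hsf1-dependent Hsp70
        induction, basal expression preserved;
      * ``AUX_DHSE`` — auxiliary-feedback mutant (fes1/ubi4/gre3/pin3-like):
        productive release scaled down by ``release_scale``.
    """

    name: str
    kind: str
    release_scale: Optional[float] = None

    KINDS = ("WT", "HSP70_DFBL", "AUX_DHSE")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(
                f"unknown genotype kind {self.kind!r}; expected one of {self.KINDS}"
            )
        if self.kind == "AUX_DHSE":
            rs = self.release_scale
            if rs is None or not (0 < rs <= 1):
                raise ValueError("AUX_DHSE requires release_scale in (0, 1]")
        elif self.kind == "HSP70_DFBL":
            if self.release_scale is not None:
                raise ValueError("HSP70_DFBL carries no release_scale")
        else:  # WT
            if self.release_scale not in (None, 1, 1.0):
                raise ValueError("WT requires release_scale = 1 (or unset)")


@dataclass(frozen=True)
class StressProtocol:
    """Stimulus schedule: stress type, onset time, magnitude, sampling times.

    ``magnitude`` is descriptive metadata (temperature in °C for heat, percent
    v/v for ethanol); the kinetic effect of stress enters through the
    ``s_heat`` / ``s_eth`` parameters.  Onset is inclusive and instantaneous:
    client influx is multiplied from ``t >= t_on``.
    """

    stress_type: str
    t_on: float = 0.0
    magnitude: float = 0.0
    sample_times: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0, 240.0]
        )
    )

    def __post_init__(self) -> None:
        if self.stress_type not in ("none", "heat", "ethanol"):
            raise ValueError(f"unknown stress_type {self.stress_type!r}")
        t = np.asarray(self.sample_times, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("sample_times must be a 1-d array with >= 2 entries")
        if t[0] != 0.0:
            raise ValueError("first sample time must be 0 (pre-stress reference)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.t_on < 0:
            raise ValueError("t_on must be >= 0")
        object.__setattr__(self, "sample_times", t)


@dataclass(frozen=True)
class SystemState:
    """One point in state space (also used for derivative vectors)."""

    U: float
    Hf: float
    HU: float
    HF: float
    Ff: float
    Y: float
    Ym: float

    def to_array(self) -> np.ndarray:
        return np.array([self.U, self.Hf, self.HU, self.HF, self.Ff, self.Y, self.Ym])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(v) for v in y))

    @property
    def total_hsp70(self) -> float:
        return self.Hf + self.HU + self.HF

    @property
    def total_hsf1(self) -> float:
        return self.Ff + self.HF


@dataclass(frozen=True)
class Trajectory:
    """Simulation output sampled at the protocol times.

    Derived series:
      * ``yfp_fold_change`` — mature reporter relative to t = 0 (exactly 1 there);
      * ``free_hsf1_fraction`` — Ff / F_tot, the activity proxy;
      * ``available_hsp70`` — free Hsp70, the proxy for nuclear-available
        chaperone;
      * ``hse_transcription_rate`` — instantaneous reporter synthesis rate
        alpha_y * Hill(Ff), used to diagnose adaptation.
    """

    times: np.ndarray
    states: np.ndarray  # (n_times, 7) in SPECIES order
    params: ModelParameters
    protocol: StressProtocol

    def __post_init__(self) -> None:
        if len(self.times) != self.states.shape[0] or self.states.shape[1] != 7:
            raise ValueError("times/states shape mismatch")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def yfp_fold_change(self) -> np.ndarray:
        ym = self.species("Ym")
        if ym[0] <= 0:
            raise ValueError("Ym(0) must be positive for fold change")
        return ym / ym[0]

    @property
    def free_hsf1_fraction(self) -> np.ndarray:
        return self.species("Ff") / self.params.F_tot

    @property
    def available_hsp70(self) -> np.ndarray:
        return self.species("Hf")

    @property
    def hse_transcription_rate(self) -> np.ndarray:
        p = self.params
        return p.alpha_y * hill(self.species("Ff"), p.K_y, p.n_y)

    def to_tidy_frame(self):
        """Long-format table: time_min, species, value."""
        import pandas as pd

        recs = []
        for j, sp in enumerate(SPECIES):
            for t, v in zip(self.times, self.states[:, j]):
                recs.append({"time_min": t, "species": sp, "value": v})
        for t, v in zip(self.times, self.yfp_fold_change):
            recs.append({"time_min": t, "species": "yfp_fold_change", "value": v})
        return pd.DataFrame.from_records(recs)

    def to_wide_frame(self):
        """Wide-format table: one column per species plus derived series."""
        import pandas as pd

        d = {"time_min": self.times}
        for j, sp in enumerate(SPECIES):
            d[sp] = self.states[:, j]
        d["yfp_fold_change"] = self.yfp_fold_change
        d["free_hsf1_fraction"] = self.free_hsf1_fraction
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Right-hand side


def _rhs(t: float, y: np.ndarray, p: ModelParameters, s: float) -> np.ndarray:
    U, Hf, HU, HF, Ff, Y, Ym = y
    # affinity switch: clients titrate Sis1 away from Hsf1, weakening binding
    k_bF = p.k_bF0 / (1.0 + (max(U, 0.0) / p.K_sis) ** p.h_sis)
    bindU = p.k_bU * Hf * U
    bindF = k_bF * Hf * Ff
    hsp_syn = p.beta0 + p.beta1 * hill(Ff, p.K_hsf, p.n_hsf)
    dU = p.k_U0 * s - bindU + p.k_offU * HU - p.gamma * U
    dHU = bindU - (p.k_rel + p.k_offU + p.gamma) * HU
    dHf = (
        hsp_syn
        + (p.k_rel + p.k_offU) * HU
        - bindU
        - bindF
        + p.k_uF * HF
        - p.gamma * Hf
    )
    dHF = bindF - (p.k_uF + p.gamma) * HF
    # Hsf1 is conserved: dilution of the HF complex returns Hsf1 to the free
    # pool, so dFf = -dHF exactly.
    dFf = -bindF + (p.k_uF + p.gamma) * HF
    dY = p.alpha_y * hill(Ff, p.K_y, p.n_y) - (p.m_mat + p.gamma) * Y
    dYm = p.m_mat * Y - p.gamma * Ym
    return np.array([dU, dHf, dHU, dHF, dFf, dY, dYm])


def derivatives(state: SystemState, params: ModelParameters, s: float) -> SystemState:
    """Instantaneous rates at ``state`` under stress multiplier ``s``."""
    return SystemState.from_array(_rhs(0.0, state.to_array(), params, s))


# ---------------------------------------------------------------------------
# Operations


def make_parameters(genotype: StrainGenotype, base: ModelParameters) -> ModelParameters:
    """Translate a genotype into model parameters.

    * ``WT``: identity.
    * ``AUX_DHSE``: ``k_rel`` multiplied by ``release_scale``.
    * ``HSP70_DFBL``: Hsf1-dependent Hsp70 synthesis removed (``beta1 = 0``)
      with ``beta0`` raised so the pre-stress steady-state *total* Hsp70
      matches wild type.  Because only the synthesis term changes, setting
      ``beta0' = beta0 + beta1 * Hill(Ff_basal)`` makes the wild-type basal
      state an exact fixed point of the mutant system.
    """
    if genotype.kind == "WT":
        return base
    if genotype.kind == "AUX_DHSE":
        return base.replace(k_rel=base.k_rel * genotype.release_scale)
    if genotype.kind == "HSP70_DFBL":
        ss = basal_steady_state(base)
        beta0_new = base.beta0 + base.beta1 * hill(ss.Ff, base.K_hsf, base.n_hsf)
        return base.replace(beta0=float(beta0_new), beta1=0.0)
    raise ValueError(f"unknown genotype kind {genotype.kind!r}")


def stress_multiplier(protocol: StressProtocol, params: ModelParameters, t: float) -> float:
    """Client-production multiplier at time ``t`` (onset inclusive)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if protocol.stress_type == "none" or t < protocol.t_on:
        return 1.0
    if protocol.stress_type == "heat":
        return params.s_heat
    return params.s_eth


def _initial_guess(p: ModelParameters) -> np.ndarray:
    h_guess = (p.beta0 + 0.2 * p.beta1) / p.gamma
    return np.array(
        [0.1, max(h_guess, 0.1), 0.1, 0.8 * p.F_tot, 0.2 * p.F_tot, 0.1, 0.1]
    )


def basal_steady_state(
    params: ModelParameters,
    guess: Optional[SystemState] = None,
    relax_minutes: float = 6000.0,
    tol: float = 1e-8,
) -> SystemState:
    """Pre-stress fixed point (s = 1), located by relaxation plus root polish.

    The polish runs on the reduced 6-species system with ``Ff = F_tot - HF``
    eliminated, because the conserved Hsf1 direction makes the full Jacobian
    singular.  Raises :class:`SteadyStateError` with the final residual if the
    derivative max-norm does not drop below ``tol``.
    """
    p = params

    def reduced(x: np.ndarray) -> np.ndarray:
        U, Hf, HU, HF, Y, Ym = x
        Ff = p.F_tot - HF
        y = np.array([U, Hf, HU, HF, Ff, Y, Ym])
        d = _rhs(0.0, y, p, 1.0)
        return np.array([d[0], d[1], d[2], d[3], d[5], d[6]])

    def polish(y: np.ndarray) -> Optional[np.ndarray]:
        x0 = np.array([y[0], y[1], y[2], y[3], y[5], y[6]])
        sol = root(reduced, x0, method="hybr", tol=1e-13)
        U, Hf, HU, HF, Y, Ym = sol.x
        full = np.array([U, Hf, HU, HF, p.F_tot - HF, Y, Ym])
        if np.max(np.abs(_rhs(0.0, full, p, 1.0))) < tol and np.min(full) > _NEG_TOL:
            return np.clip(full, 0.0, None)
        return None

    if guess is not None:
        polished = polish(guess.to_array())
        if polished is not None and polished[6] > 0:
            return SystemState.from_array(polished)

    y0 = _initial_guess(p)
    sol = solve_ivp(
        _rhs, (0.0, relax_minutes), y0, args=(p, 1.0),
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise SteadyStateError(f"relaxation integration failed: {sol.message}")
    y_relaxed = sol.y[:, -1]
    polished = polish(y_relaxed)
    if polished is None:
        resid = float(np.max(np.abs(_rhs(0.0, y_relaxed, p, 1.0))))
        raise SteadyStateError(
            f"steady state did not converge; final derivative max-norm {resid:.3e}"
        )
    if polished[6] <= 0:
        raise SteadyStateError("basal mature YFP is zero; fold change undefined")
    return SystemState.from_array(polished)


def simulate(
    params: ModelParameters,
    protocol: StressProtocol,
    initial_state: Optional[SystemState] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the circuit from its basal steady state through the protocol.

    Uses an adaptive stiff-capable scheme (LSODA), split at the stress onset
    so the discontinuous influx multiplier never crosses a solver step.
    """
    times = protocol.sample_times
    y0 = (initial_state or basal_steady_state(params)).to_array()
    t_end = float(times[-1])
    t_on = min(protocol.t_on, t_end) if protocol.stress_type != "none" else t_end

    states = np.empty((len(times), 7))
    filled = np.zeros(len(times), dtype=bool)
    # samples exactly at a segment boundary belong to the earlier segment
    # (the state is continuous; only the derivative jumps)
    if times[0] == 0.0:
        states[0] = y0
        filled[0] = True

    segments = []
    if t_on > 0:
        segments.append((0.0, t_on, 1.0))
    if t_on < t_end:
        s_stress = stress_multiplier(protocol, params, max(t_on, 0.0))
        segments.append((t_on, t_end, s_stress))

    y_cur = y0
    for t_a, t_b, s in segments:
        mask = (~filled) & (times > t_a) & (times <= t_b)
        t_eval = times[mask]
        sol = solve_ivp(
            _rhs, (t_a, t_b), y_cur, args=(params, s),
            method="LSODA", rtol=rtol, atol=atol,
            t_eval=np.unique(np.concatenate([t_eval, [t_b]])),
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{t_a}, {t_b}]: {sol.message}")
        lookup = {float(t): sol.y[:, j] for j, t in enumerate(sol.t)}
        for i in np.nonzero(mask)[0]:
            states[i] = lookup[float(times[i])]
            filled[i] = True
        y_cur = sol.y[:, -1]

    if not filled.all():
        raise IntegrationError("internal error: unsampled protocol times")
    if states.min() < _NEG_TOL:
        raise IntegrationError(
            f"negative species beyond tolerance: min = {states.min():.3e}"
        )
    states = np.clip(states, 0.0, None)
    return Trajectory(times=times, states=states, params=params, protocol=protocol)
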