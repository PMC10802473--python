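"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of a 42-strain Hsf1-target
reporter library and its companion assays: basal reporter levels spanning
several orders of magnitude, induction fold changes from barely detectable
to ~10x with rapid genes inducing more strongly (and high-basal genes more
weakly), an ethanol dose-response with calibrated EC50/IC50, per-cell
cytometry events with a dead-cell artifact, and two-phase OD600 growth
curves with a 30->37 C shift at 4 h.

Every generator is a pure function of its spec and seed — identical calls
return bit-identical data — and every bundle carries its generating ground
truth so the analysis modules can be closed-loop tested.

All ground-truth constants come from the versioned default calibration;
nothing is hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import synthetic_defaults
from .cytometry_growth import FlowSample, GrowthSeries
from .dose_response import DoseResponseCurve, hill_curve
from .dynamics import GeneTimeCourse, logistic
from .fitting import ObservedTimeCourse
from .model_core import (
    ModelParameters,
    StrainGenotype,
    StressProtocol,
    make_parameters,
    simulate,
)

__all__ = [
    "RegulonSpec",
    "NoiseSpec",
    "RegulonLibrary",
    "EthanolPanel",
    "gen_regulon_library",
    "gen_mutant_panel",
    "gen_ethanol_panel",
    "gen_flow_sample",
    "gen_growth_curves",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Regulon library


@dataclass(frozen=True)
class RegulonSpec:
    """Statistical shape of the synthetic reporter library.

    Marginals are sampled by rank (stratified quantile midpoints), so the
    configured basal and fold-change ranges are covered deterministically;
    the correlations are imposed on the ranks through a Gaussian copula.
    """

    n_genes: int = 42
    times: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0, 240.0]
        )
    )
    basal_min: float = 10.0
    basal_decades: float = 4.0
    fold_change_min: float = 1.05
    fold_change_max: float = 10.0
    t50_min: float = 20.0
    t50_max: float = 180.0
    rate_scale: float = 3.0
    rate_jitter_sigma: float = 0.15
    rho_fc_t50: float = -0.7
    rho_basal_fc: float = -0.6
    replicate_cv: float = 0.05
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_genes < 5:
            raise ValueError("n_genes must be >= 5")
        if not (self.basal_min > 0 and self.basal_decades > 0):
            raise ValueError("invalid basal range")
        if not (1.0 <= self.fold_change_min < self.fold_change_max):
            raise ValueError("invalid fold-change range")
        if not (0 < self.t50_min < self.t50_max):
            raise ValueError("invalid t50 range")
        for rho in (self.rho_fc_t50, self.rho_basal_fc):
            if not (-1 < rho < 1):
                raise ValueError("rank correlations must lie in (-1, 1)")
        if self.replicate_cv < 0 or self.n_replicates < 1:
            raise ValueError("invalid replicate spec")
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    @classmethod
    def default(cls) -> "RegulonSpec":
        cfg = synthetic_defaults("regulon")
        return cls(
            n_genes=cfg["n_genes"],
            times=np.asarray(cfg["times_min"], dtype=float),
            basal_min=cfg["basal_min"],
            basal_decades=cfg["basal_decades"],
            fold_change_min=cfg["fold_change_min"],
            fold_change_max=cfg["fold_change_max"],
            t50_min=cfg["t50_min"],
            t50_max=cfg["t50_max"],
            rate_scale=cfg["rate_scale"],
            rate_jitter_sigma=cfg["rate_jitter_sigma"],
            rho_fc_t50=cfg["rho_fc_t50"],
            rho_basal_fc=cfg["rho_basal_fc"],
            replicate_cv=cfg["replicate_cv"],
            n_replicates=cfg["n_replicates"],
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise settings shared by the generators."""

    replicate_cv: float = 0.05       # multiplicative CV per replicate point
    cell_sigma: float = 0.12         # per-cell residual lognormal sigma
    dead_fraction: float = 0.0
    dead_fluor_atten: float = 0.05
    dead_ssc_atten: float = 0.3
    ssc_sigma: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replicate_cv < 0 or self.cell_sigma < 0 or self.ssc_sigma < 0:
            raise ValueError("noise CVs must be >= 0")
        if not (0 <= self.dead_fraction < 1):
            raise ValueError("dead_fraction must lie in [0, 1)")

    @classmethod
    def default(cls) -> "NoiseSpec":
        flow = synthetic_defaults("flow")
        return cls(
            cell_sigma=flow["ratio_sigma"],
            dead_fraction=flow["dead_fraction"],
            dead_fluor_atten=flow["dead_fluor_atten"],
            dead_ssc_atten=flow["dead_ssc_atten"],
            ssc_sigma=flow["ssc_sigma"],
        )


@dataclass(frozen=True)
class RegulonLibrary:
    courses: tuple  # GeneTimeCourse per gene
    truth: pd.DataFrame  # gene, basal, fold_change, k, t50


def _rank_quantiles(z: np.ndarray) -> np.ndarray:
    """Map values to quantile midpoints (rank + 0.5)/n, preserving order."""
    ranks = np.argsort(np.argsort(z))
    return (ranks + 0.5) / len(z)


def gen_regulon_library(spec: Optional[RegulonSpec] = None, seed: int = 0) -> RegulonLibrary:
    """Generate the synthetic Hsf1-target reporter library.

    Per gene: basal level log-uniform (by stratified ranks) over the
    configured decades; fold change and half-max time rank-coupled so that
    rapidly induced genes induce more strongly and high-basal genes induce
    weakly; mean trace logistic; replicates multiplicative-lognormal around
    the true mean; reported means are replicate averages.
    """
    spec = spec or RegulonSpec.default()
    rng = np.random.default_rng(seed)
    n = spec.n_genes

    z_fc = rng.standard_normal(n)
    a, c = spec.rho_basal_fc, spec.rho_fc_t50
    z_basal = a * z_fc + np.sqrt(1 - a**2) * rng.standard_normal(n)
    z_t50 = c * z_fc + np.sqrt(1 - c**2) * rng.standard_normal(n)

    u_basal = _rank_quantiles(z_basal)
    u_fc = _rank_quantiles(z_fc)
    u_t50 = _rank_quantiles(z_t50)

    basal = spec.basal_min * 10.0 ** (u_basal * spec.basal_decades)
    fc = spec.fold_change_min * (spec.fold_change_max / spec.fold_change_min) ** u_fc
    t50 = spec.t50_min + u_t50 * (spec.t50_max - spec.t50_min)
    k = np.clip(
        spec.rate_scale / t50 * np.exp(rng.normal(0.0, spec.rate_jitter_sigma, n)),
        0.01, 0.5,
    )

    courses = []
    for g in range(n):
        mean_true = logistic(spec.times, basal[g], basal[g] * fc[g], k[g], t50[g])
        reps = mean_true * _lognormal_factors(
            rng, spec.replicate_cv, (spec.n_replicates, len(spec.times))
        )
        courses.append(
            GeneTimeCourse(
                gene=f"gene{g + 1:02d}",
                times=spec.times,
                means=reps.mean(axis=0),
                replicates=reps,
            )
        )
    truth = pd.DataFrame(
        {
            "gene": [tc.gene for tc in courses],
            "basal": basal,
            "fold_change": fc,
            "k": k,
            "t50": t50,
        }
    )
    return RegulonLibrary(courses=tuple(courses), truth=truth)


# ---------------------------------------------------------------------------
# Mutant reporter panels (model-driven)


def gen_mutant_panel(
    genotypes: Sequence[StrainGenotype],
    protocol: StressProtocol,
    noise: NoiseSpec,
    base: ModelParameters,
    seed: int = 0,
) -> list[ObservedTimeCourse]:
    """Simulate HSE-YFP fold-change courses for a genotype panel and dress
    them as observed data (3 replicates, multiplicative noise, per-replicate
    renormalization to its own t = 0 value, as flow-derived fold changes are)."""
    rng = np.random.default_rng(seed)
    n_reps = 3
    out = []
    for gt in genotypes:
        params = make_parameters(gt, base)
        traj = simulate(params, protocol)
        fc = traj.yfp_fold_change
        reps = fc * _lognormal_factors(rng, noise.replicate_cv, (n_reps, len(fc)))
        reps = reps / reps[:, :1]
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1)
        out.append(
            ObservedTimeCourse(
                strain=gt.name,
                times=protocol.sample_times,
                values=mean,
                sd=sd,
                n_reps=n_reps,
                truth={
                    "kind": gt.kind,
                    "release_scale": gt.release_scale if gt.kind == "AUX_DHSE" else 1.0,
                    "params": params,
                    "noiseless_fold_change": fc,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ethanol dose-response panel


@dataclass(frozen=True)
class EthanolPanel:
    """Synthetic ethanol screen: per-dose reporter time courses, the 4-h
    endpoint dose-response curve, and per-dose growth curves."""

    concentrations: np.ndarray
    times: np.ndarray
    yfp_courses: dict          # conc -> (n_reps, n_times) fold-change array
    endpoint_curve: DoseResponseCurve
    growth_series: dict        # conc -> list[GrowthSeries]
    truth: dict


def gen_ethanol_panel(
    concentrations: Optional[Sequence[float]] = None,
    times: Optional[Sequence[float]] = None,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
) -> EthanolPanel:
    """Generate the ethanol dose-response dataset at the default calibration.

    Four-hour reporter levels follow a Hill curve with the calibrated true
    EC50; growth inhibition follows a decreasing Hill with the calibrated
    IC50, realized as two-phase logistic OD600 curves whose post-shift rate
    is scaled by the inhibition curve.  Reporter time courses are sigmoidal
    in time at activating doses and a slow quadratic drift below them.
    """
    cfg = synthetic_defaults("ethanol_panel")
    gcfg = synthetic_defaults("growth")
    conc = np.asarray(
        cfg["concentrations_pct"] if concentrations is None else concentrations,
        dtype=float,
    )
    t = np.asarray(cfg["times_min"] if times is None else times, dtype=float)
    noise = noise or NoiseSpec(replicate_cv=cfg["replicate_cv"])
    if 0.0 not in conc:
        raise ValueError("concentration grid must include 0")
    if not (conc.min() < cfg["ec50_yfp_pct"] < conc.max()):
        raise ValueError("concentration grid must span the EC50 region")
    rng = np.random.default_rng(seed)
    n_reps = int(cfg["n_replicates"])
    horizon = float(t[-1])

    ec50, n_yfp = cfg["ec50_yfp_pct"], cfg["hill_n_yfp"]
    floor_f, ceil_f = cfg["yfp_floor_fold"], cfg["yfp_ceiling_fold"]
    endpoint_true = hill_curve(conc, floor_f, ceil_f, ec50, n_yfp, "increasing")

    yfp_courses = {}
    endpoint_reps = np.empty((n_reps, len(conc)))
    for j, (ci, ei) in enumerate(zip(conc, endpoint_true)):
        if ci >= cfg["sigmoid_min_conc_pct"]:
            t50c = float(np.clip(160.0 - 12.0 * ci, 40.0, 160.0))
            kc = 4.0 / t50c
            sig = 1.0 / (1.0 + np.exp(-kc * (t - t50c)))
            shape = (sig - sig[0]) / (sig[-1] - sig[0])
        else:
            shape = (t / horizon) ** 2
        mean_course = 1.0 + (ei - 1.0) * shape
        reps = mean_course * _lognormal_factors(
            rng, noise.replicate_cv, (n_reps, len(t))
        )
        yfp_courses[float(ci)] = reps
        endpoint_reps[:, j] = reps[:, -1]

    endpoint_curve = DoseResponseCurve(
        concentrations=conc,
        response=endpoint_reps.mean(axis=0),
        direction="increasing",
        replicates=endpoint_reps,
    )

    ic50, n_gr = cfg["ic50_growth_pct"], cfg["hill_n_growth"]
    floor_g = cfg["growth_floor_rel"]
    rel_growth = hill_curve(conc, floor_g, 1.0, ic50, n_gr, "decreasing")
    growth_series = {}
    for ci, gi in zip(conc, rel_growth):
        growth_series[float(ci)] = _two_phase_curves(
            rng,
            n_reps=int(gcfg["n_replicates"]),
            od0=gcfg["od0"],
            K=gcfg["carrying_capacity"],
            r1=gcfg["rate_phase1"],
            r2=gcfg["rate_phase2"] * gi,
            shift=gcfg["shift_min"],
            total=gcfg["total_min"],
            dt=gcfg["sampling_min"],
            cv=gcfg["replicate_cv"],
            strain=f"WT@{ci}%",
        )

    truth = {
        "ec50_yfp_pct": ec50,
        "hill_n_yfp": n_yfp,
        "yfp_floor_fold": floor_f,
        "yfp_ceiling_fold": ceil_f,
        "endpoint_true": endpoint_true,
        "ic50_growth_pct": ic50,
        "hill_n_growth": n_gr,
        "growth_floor_rel": floor_g,
        "rel_growth_true": rel_growth,
        "shift_min": gcfg["shift_min"],
    }
    return EthanolPanel(
        concentrations=conc,
        times=t,
        yfp_courses=yfp_courses,
        endpoint_curve=endpoint_curve,
        growth_series=growth_series,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Flow cytometry events


def gen_flow_sample(
    mean_level: float,
    noise: Optional[NoiseSpec] = None,
    n_events: int = 10_000,
    seed: int = 0,
    label: str = "sample",
) -> FlowSample:
    """Per-cell events for one sample.

    Live cells: side scatter lognormal around a common size scale, and
    fluorescence proportional to side scatter (size) times the target level
    with residual lognormal noise — so the fluorescence/ssc ratio is a tight
    estimator of ``mean_level``.  Dead cells (configured fraction) keep some
    scatter but lose most fluorescence, producing the low-ratio artifact the
    ssc normalization is meant to reject.
    """
    noise = noise or NoiseSpec.default()
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    rng = np.random.default_rng(seed)
    n_dead = int(round(noise.dead_fraction * n_events))
    n_live = n_events - n_dead

    ssc_scale = 100.0
    ssc = ssc_scale * rng.lognormal(0.0, noise.ssc_sigma, n_events)
    ratio_noise = rng.lognormal(0.0, noise.cell_sigma, n_events)
    fluor = mean_level * ssc * ratio_noise
    if n_dead:
        dead = np.zeros(n_events, dtype=bool)
        dead[rng.choice(n_events, size=n_dead, replace=False)] = True
        fluor[dead] *= noise.dead_fluor_atten
        ssc[dead] *= noise.dead_ssc_atten
    return FlowSample(label=label, fluorescence=fluor, side_scatter=ssc)


# ---------------------------------------------------------------------------
# Growth curves


def _two_phase_logistic(
    t: np.ndarray, od0: float, K: float, r1: float, r2: float, shift: float
) -> np.ndarray:
    """Closed-form logistic growth with a rate change at the shift time."""
    A1 = (K - od0) / od0
    od = K / (1.0 + A1 * np.exp(-r1 * t))
    od_s = K / (1.0 + A1 * np.exp(-r1 * shift))
    A2 = (K - od_s) / od_s
    late = K / (1.0 + A2 * np.exp(-r2 * (t - shift)))
    return np.where(t <= shift, od, late)


def _two_phase_curves(
    rng, n_reps, od0, K, r1, r2, shift, total, dt, cv, strain
) -> list[GrowthSeries]:
    t = np.arange(0.0, total + 0.5 * dt, dt)
    mean_od = _two_phase_logistic(t, od0, K, r1, r2, shift)
    out = []
    for r in range(n_reps):
        od = mean_od * _lognormal_factors(rng, cv, len(t))
        out.append(GrowthSeries(times=t, od600=od, replicate=f"r{r + 1}", strain=strain))
    return out


def gen_growth_curves(
    strains: Mapping[str, float],
    seed: int = 0,
    replicate_cv: Optional[float] = None,
) -> list[GrowthSeries]:
    """Two-phase logistic OD600 curves for a strain panel.

    ``strains`` maps strain name to its post-shift growth-rate scale
    (1 = no deficit; 0.5 = half the wild-type 37 C rate).  Sampling follows
    the calibrated assay layout: 20-min spacing over 24 h with the
    temperature shift at 4 h, two replicates per strain.
    """
    cfg = synthetic_defaults("growth")
    rng = np.random.default_rng(seed)
    cv = cfg["replicate_cv"] if replicate_cv is None else replicate_cv
    out = []
    for name, scale in strains.items():
        if not (0 <= scale <= 1.5):
            raise ValueError(f"implausible rate scale {scale} for strain {name!r}")
        out.extend(
            _two_phase_curves(
                rng,
                n_reps=int(cfg["n_replicates"]),
                od0=cfg["od0"],
                K=cfg["carrying_capacity"],
                r1=cfg["rate_phase1"],
                r2=cfg["rate_phase2"] * scale,
                shift=cfg["shift_min"],
                total=cfg["total_min"],
                dt=cfg["sampling_min"],
                cv=cv,
                strain=name,
            )
        )
    return out
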