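"""Versioned default calibration: one YAML file holds every tunable constant.

The wild-type ODE parameter set, the default heat/ethanol protocols and the
ground-truth constants of the synthetic-data generators are all read from
``data/default_calibration.yaml`` so that tests, the CLI and the generators
share a single source of defaults.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Any, Optional

import numpy as np
import yaml

from .model_core import ModelParameters, StressProtocol

__all__ = [
    "load_default_calibration",
    "default_parameters",
    "default_heat_protocol",
    "default_ethanol_protocol",
    "synthetic_defaults",
]


@functools.lru_cache(maxsize=1)
def load_default_calibration() -> dict[str, Any]:
    """Parsed contents of the shipped calibration file."""
    text = resources.files("hsrkit.data").joinpath("default_calibration.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters() -> ModelParameters:
    """Wild-type baseline parameter set."""
    return ModelParameters(**load_default_calibration()["model"])


def _protocol(kind: str, sample_times: Optional[np.ndarray] = None) -> StressProtocol:
    cfg = load_default_calibration()["protocols"][kind]
    times = np.asarray(
        cfg["sample_times_min"] if sample_times is None else sample_times, dtype=float
    )
    magnitude = cfg.get("magnitude_c", cfg.get("magnitude_pct", 0.0))
    return StressProtocol(
        stress_type=kind, t_on=cfg["t_on_min"], magnitude=magnitude, sample_times=times
    )


def default_heat_protocol(sample_times: Optional[np.ndarray] = None) -> StressProtocol:
    """39 C heat shock from t = 0, sampled at 10 points over 240 min."""
    return _protocol("heat", sample_times)


def default_ethanol_protocol(sample_times: Optional[np.ndarray] = None) -> StressProtocol:
    """8.5% v/v ethanol from t = 0, sampled at 10 points over 240 min."""
    return _protocol("ethanol", sample_times)


def synthetic_defaults(section: str) -> dict[str, Any]:
    """Generator ground-truth constants: section in
    {'regulon', 'ethanol_panel', 'flow', 'growth'}."""
    return dict(load_default_calibration()["synthetic"][section])
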