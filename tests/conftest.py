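import numpy as np
import pytest

from hsrkit import calibration as cal
from hsrkit.model_core import _rhs, basal_steady_state, simulate


@pytest.fixture(scope="session")
def base_params():
    return cal.default_parameters()


@pytest.fixture(scope="session")
def heat_protocol():
    return cal.default_heat_protocol()


@pytest.fixture(scope="session")
def ethanol_protocol():
    return cal.default_ethanol_protocol()


@pytest.fixture(scope="session")
def basal_state(base_params):
    return basal_steady_state(base_params)


@pytest.fixture(scope="session")
def wt_traj(base_params, heat_protocol):
    return simulate(base_params, heat_protocol)


@pytest.fixture(scope="session")
def traj_cache(base_params, heat_protocol):
    """Factory caching heat-shock trajectories by release scale."""
    cache = {}

    def get(scale: float = 1.0, params=None):
        key = (scale, id(params))
        if key not in cache:
            p = params or base_params
            cache[key] = simulate(p.replace(k_rel=p.k_rel * scale), heat_protocol)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rk4_integrate():
    """Fixed-step classical RK4 oracle for the circuit ODE."""

    def integrate(params, protocol, dt=0.01):
        y = basal_steady_state(params).to_array().copy()
        times = protocol.sample_times
        s = {"none": 1.0, "heat": params.s_heat, "ethanol": params.s_eth}[
            protocol.stress_type
        ]
        out = [y.copy()]
        t = 0.0
        idx = 1
        nsteps = int(round(times[-1] / dt))
        for _ in range(nsteps):
            k1 = _rhs(t, y, params, s)
            k2 = _rhs(t + dt / 2, y + dt / 2 * k1, params, s)
            k3 = _rhs(t + dt / 2, y + dt / 2 * k2, params, s)
            k4 = _rhs(t + dt, y + dt * k3, params, s)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            if idx < len(times) and abs(t - times[idx]) < dt / 2:
                out.append(y.copy())
                idx += 1
        return np.array(out)

    return integrate
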