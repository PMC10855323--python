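import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellmech import PLRParams
from cellmech.simulate import CurveSpec, simulate_curve

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def elastic_curve():
    """Noise-free purely elastic curve, E = 2800 Pa (session-cached)."""
    spec = CurveSpec(params=PLRParams(E1=2800.0), seed=11)
    return simulate_curve(spec)


@pytest.fixture(scope="session")
def visco_curve():
    """Noise-free PLR curve, E1 = 5 kPa, alpha = 0.2 (session-cached)."""
    spec = CurveSpec(params=PLRParams(E1=5000.0, alpha=0.2), seed=12)
    return simulate_curve(spec)


@pytest.fixture(scope="session")
def noisy_curve():
    """PLR curve with 20 pN RMS force noise."""
    spec = CurveSpec(params=PLRParams(E1=3000.0, alpha=0.1),
                     noise_rms_nN=0.02, seed=13)
    return simulate_curve(spec)


def random_history(seed, n=120, duration=0.02, dmax_nm=300.0):
    """Random piecewise-smooth indentation history (not force-balanced).

    Monotone power-law-ish loading to a random turnaround, then unloading
    with a different exponent; delta(0) = 0.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n)
    tm_index = int(n * rng.uniform(0.35, 0.65))
    tm = t[tm_index]
    p_up = rng.uniform(0.8, 1.6)
    p_dn = rng.uniform(0.8, 1.6)
    dmax = dmax_nm * rng.uniform(0.5, 1.5)
    delta = np.empty(n)
    delta[: tm_index + 1] = dmax * (t[: tm_index + 1] / tm) ** p_up
    tail = (t[tm_index:] - tm) / (t[-1] - tm)
    delta[tm_index:] = dmax * np.clip(1.0 - tail ** p_dn, 0.0, None)
    return t, delta, tm_index
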