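import numpy as np
import pytest

from strokesim import Connectome, KuramotoParams, generate_synthetic_connectome


@pytest.fixture(scope="session")
def small_conn() -> Connectome:
    """Default synthetic connectome at study size."""
    return generate_synthetic_connectome(18, density=0.3, seed=1)


@pytest.fixture(scope="session")
def sym_conn() -> Connectome:
    return generate_synthetic_connectome(10, density=0.5, symmetric=True, seed=4)


@pytest.fixture()
def short_kp() -> KuramotoParams:
    return KuramotoParams(duration=10.0, transient=2.0, seed=0)


def naive_euler_phases(weights: np.ndarray, params: KuramotoParams,
                       theta0: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Straightforward sin/cos Euler-Maruyama reference integrator.

    Independent of the package's phasor-rotation kernel; returns the
    (n_steps, N) unwrapped trajectory including the transient.
    """
    n = theta0.shape[0]
    th = theta0.copy()
    out = np.empty((params.n_steps, n))
    amp = np.sqrt(2.0 * params.D * params.dt)
    for t in range(params.n_steps):
        coup = (np.cos(th) * (weights @ np.sin(th))
                - np.sin(th) * (weights @ np.cos(th)))
        th = th + 2 * np.pi * params.f * params.dt \
            + params.K / n * params.dt * coup + amp * noise[t]
        out[t] = th
    return out
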