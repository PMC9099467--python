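import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hsmcr as h

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return h.default_library()


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Default study conditions without noise (exact bilinear product)."""
    return h.simulate_dataset(config=h.SimulationConfig(noise_fraction=0.0))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default study conditions: 0-72 h at 0.5 h, 1% uniform noise."""
    return h.simulate_dataset(config=h.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def uptake_model():
    return h.get_model("uptake")


@pytest.fixture(scope="session")
def uptake_response_model():
    return h.get_model("uptake_response")


def brute_force_bounded_ls(A, b, nonneg_mask, tol=1e-12):
    """Independent oracle: enumerate active sets of the sign-constrained LS.

    For every subset of the non-negativity-flagged coefficients, clamp that
    subset to zero, solve the unconstrained least squares on the rest, keep
    the feasible candidates and return the one with the smallest residual.
    Exact for full-rank designs; exponential in the component count, so only
    usable on toy problems — which is the point of an oracle.
    """
    from itertools import combinations

    A = np.asarray(A, float)
    b = np.asarray(b, float)
    k = A.shape[1]
    flagged = [i for i in range(k) if nonneg_mask[i]]
    best_x, best_r = None, np.inf
    for m in range(len(flagged) + 1):
        for clamped in combinations(flagged, m):
            free = [i for i in range(k) if i not in clamped]
            x = np.zeros(k)
            if free:
                x[free] = np.linalg.lstsq(A[:, free], b, rcond=None)[0]
            if any(x[i] < -tol for i in flagged):
                continue
            r = float(np.sum((A @ x - b) ** 2))
            if r < best_r - 1e-15:
                best_r, best_x = r, x
    return best_x, best_r
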