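import numpy as np
import pytest
from scipy.integrate import solve_ivp

from levinsfert import CommunityParams, FecundityProfile, preset_profile


@pytest.fixture(scope="session")
def params():
    """Standard community rates used throughout the experiments."""
    return CommunityParams(q=0.3, m=0.2)


@pytest.fixture(scope="session")
def f0():
    return preset_profile("f0")


@pytest.fixture(scope="session")
def f1():
    return preset_profile("f1")


@pytest.fixture(scope="session")
def f2():
    return preset_profile("f2")


def scalar_rhs(p, f, q, m, eps=0.0):
    """Independent term-by-term evaluation of the occupancy dynamics.

    Deliberately written as explicit scalar loops over the three
    summations so it shares no code path with the vectorized
    implementation it oracles.
    """
    n = len(p)
    dp = np.empty(n)
    for i in range(n):
        colonize = q * f[i] * p[i] * (1.0 - sum(p[j] for j in range(i + 1)))
        displaced = q * sum(f[j] * p[j] for j in range(i)) * p[i]
        dp[i] = colonize - displaced - m * p[i] + eps
    return dp


def ode_equilibrium(f, q, m, t_end=1e6, p0=1e-3):
    """Brute-force stationary state by long integration.

    The right-hand side is formulated with lower-triangular matrix
    products rather than running sums, keeping it an independent route
    from the implementation it oracles while staying fast at n = 80.
    """
    f = np.asarray(f, dtype=float)
    n = f.size
    lower_eq = np.tril(np.ones((n, n)))  # j <= i
    lower_lt = lower_eq - np.eye(n)  # j < i

    def rhs(t, p):
        return (q * f * p * (1.0 - lower_eq @ p)
                - q * (lower_lt @ (f * p)) * p - m * p)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.full(n, p0),
        method="LSODA",
        rtol=1e-10,
        atol=1e-14,
        t_eval=[t_end],
    )
    assert sol.success
    return np.clip(sol.y[:, -1], 0.0, None)


def random_small_instance(rng):
    """Random community of at most 6 species with positive rates."""
    n = int(rng.integers(1, 7))
    f = rng.uniform(0.2, 4.0, n)
    q = float(rng.uniform(0.1, 1.0))
    m = float(rng.uniform(0.05, 1.0))
    return FecundityProfile(values=f), CommunityParams(q=q, m=m)
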