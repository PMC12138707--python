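import numpy as np
import pytest
from scipy.integrate import solve_ivp

from synkin import FWParams

# Reference jerk-time / rate-constant sets for the three perchlorate
# concentrations (mM) at which the two-step model fits well.
PERCHLORATE_CONDITIONS = {
    "60": {"k1": 0.01, "k2": 0.11, "t1": 6.38, "tmax": 11.86, "t2": 17.34},
    "80": {"k1": 0.03, "k2": 0.11, "t1": 3.47, "tmax": 8.68, "t2": 13.90},
    "120": {"k1": 0.03, "k2": 0.13, "t1": 2.57, "tmax": 7.13, "t2": 11.68},
}

A0_MM = 2.0

# 3x3x3 grid spanning the reference rate-constant ranges
GRID_K1 = (0.01, 0.02, 0.03)
GRID_K2 = (0.11, 0.12, 0.13)
GRID_A0 = (1.0, 2.0, 3.0)


def ode_monomer(params: FWParams, times: np.ndarray) -> np.ndarray:
    """Independent oracle: adaptive high-order integration of
    dA/dt = -k1*A - k2*A*(A0 - A)."""
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, a: [-params.k1 * a[0] - params.k2 * a[0] * (params.a0 - a[0])],
        (0.0, float(times[-1]) if times[-1] > 0 else 1.0),
        [params.a0],
        t_eval=times,
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
    )
    assert sol.success
    return sol.y[0]


@pytest.fixture
def ref_params() -> FWParams:
    row = PERCHLORATE_CONDITIONS["120"]
    return FWParams(k1=row["k1"], k2=row["k2"], a0=A0_MM)
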