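import numpy as np
import pytest

from tightbind.core import KineticParams
from tightbind.reset import ResetConfig


@pytest.fixture(scope="session")
def pendos_params() -> KineticParams:
    """Inhibitor-substrate kinetics used throughout the reset experiments."""
    return KineticParams(Km=0.47, kcat=0.03)


@pytest.fixture(scope="session")
def reset_config(pendos_params) -> ResetConfig:
    """The auto-reset experiment: 0.25 nM enzyme, 16 nM inhibitor,
    0.47 uM reporter, enzyme decay 0.020/min starting at 25 min."""
    return ResetConfig(
        P_T0=0.25,
        N_T0=16.0,
        pC_T=470.0,
        params_N=pendos_params,
        eff_C=0.52,
        kdeg=0.020,
        deg_onset=1500.0,
    )


def bisect_complex(N_T: float, P_T: float, Km: float, iters: int = 200) -> float:
    """Independent bisection solve of the tight-binding quadratic
    x^2 - (N_T+P_T+Km) x + N_T P_T = 0 on [0, min(N_T, P_T)]."""
    s = N_T + P_T + Km

    def f(x: float) -> float:
        return x * x - s * x + N_T * P_T

    lo, hi = 0.0, min(N_T, P_T)
    if f(hi) == 0.0:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def rk4_integrate(rhs, y0: float, t_end: float, dt: float) -> float:
    """Fixed-step scalar RK4, the reference integrator for depletion ODEs."""
    t, y = 0.0, float(y0)
    n = int(np.ceil(t_end / dt))
    h = t_end / n
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y
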