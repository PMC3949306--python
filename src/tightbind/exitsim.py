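"""Phosphatase desequestration dynamics at M-phase exit.

At the end of M phase the kinase producing the phospho-inhibitor (pEndos)
shuts off, leaving a large pool of inhibitor (~1 uM) sequestering
essentially all of the phosphatase (~250 nM, Km ~ 1 nM).  Because the
inhibitor is also a slow substrate, the phosphatase chews through the pool
and frees itself.  This module integrates that process under the total
quasi-steady-state approximation (tQSSA), cross-checks it against the
explicit mass-action equations, and provides the validity diagnostics and
the decomposition of dephosphorylating flux between two phosphatases.

Scenarios (all concentrations nM, times s):
  * single-phosphatase: the sequestered enzyme alone consumes the inhibitor;
  * two-phosphatase: a second, conventional enzyme "PPX" (high Km, high
    kcat) helps;
  * dead-end: the sequestered enzyme only binds (Kd) and PPX alone consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import KineticParams, bound_complex

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "ValidityDiagnostics",
    "simulate_tqssa",
    "simulate_mass_action",
    "half_desequestration_time",
    "fractional_velocities",
    "tqssa_validity",
    "single_phosphatase_scenario",
    "two_phosphatase_scenario",
    "dead_end_scenario",
    "BEYOND_HORIZON",
]

BEYOND_HORIZON = math.inf
RTOL = 1e-8
ATOL = 1e-12
DEFAULT_KON = 0.057  # 1/(nM s), measured association rate for the inhibitor


@dataclass(frozen=True)
class ScenarioConfig:
    """Species totals and per-enzyme kinetics for an exit simulation.

    mode_P "substrate": the primary enzyme P consumes the ligand with
    (Km, kcat) from params_P.  mode_P "dead_end": P only binds, with
    dissociation constant params_P.Kd, and kcat is forced to zero.
    """

    N_T0: float
    P_T: float
    params_P: KineticParams
    X_T: float = 0.0
    params_X: KineticParams | None = None
    mode_P: str = "substrate"
    kon_P: float = DEFAULT_KON
    kon_X: float = DEFAULT_KON
    horizon: float | None = None

    def __post_init__(self) -> None:
        if self.mode_P not in ("substrate", "dead_end"):
            raise ValueError(f"unknown mode_P {self.mode_P!r}")
        if self.mode_P == "dead_end" and self.params_P.Kd is None:
            raise ValueError("dead_end mode requires params_P.Kd")
        if self.X_T > 0 and self.params_X is None:
            raise ValueError("X_T > 0 requires params_X")
        if self.N_T0 < 0 or self.P_T < 0 or self.X_T < 0:
            raise ValueError("totals must be >= 0")

    @property
    def binding_Km_P(self) -> float:
        return self.params_P.Kd if self.mode_P == "dead_end" else self.params_P.Km

    @property
    def kcat_P(self) -> float:
        return 0.0 if self.mode_P == "dead_end" else self.params_P.kcat

    @property
    def koff_P(self) -> float:
        """Dissociation rate consistent with the binding constant.

        Substrate mode uses the Briggs-Haldane relation Km = (koff+kcat)/kon,
        so koff = kon*Km - kcat; dead-end mode uses koff = kon*Kd.
        """
        if self.mode_P == "dead_end":
            return self.kon_P * self.params_P.Kd
        koff = self.kon_P * self.params_P.Km - self.params_P.kcat
        if koff <= 0:
            raise ValueError(
                "kon*Km <= kcat: no nonnegative koff satisfies Briggs-Haldane; "
                "supply a larger kon"
            )
        return koff

    @property
    def koff_X(self) -> float:
        koff = self.kon_X * self.params_X.Km - self.params_X.kcat
        if koff <= 0:
            raise ValueError("kon_X*Km_X <= kcat_X: no nonnegative koff_X")
        return koff


def single_phosphatase_scenario(
    N_T0: float = 1000.0,
    P_T: float = 250.0,
    Km: float = 1.0,
    kcat: float = 0.05,
) -> ScenarioConfig:
    """The sequestered phosphatase alone dephosphorylates its inhibitor."""
    return ScenarioConfig(
        N_T0=N_T0, P_T=P_T, params_P=KineticParams(Km=Km, kcat=kcat), horizon=600.0
    )


def two_phosphatase_scenario(
    N_T0: float = 1000.0,
    P_T: float = 250.0,
    Km_P: float = 1.0,
    kcat_P: float = 0.05,
    X_T: float = 250.0,
    Km_X: float = 85e3,
    kcat_X: float = 22.5,
) -> ScenarioConfig:
    """A conventional second phosphatase PPX assists the sequestered one."""
    return ScenarioConfig(
        N_T0=N_T0,
        P_T=P_T,
        params_P=KineticParams(Km=Km_P, kcat=kcat_P),
        X_T=X_T,
        params_X=KineticParams(Km=Km_X, kcat=kcat_X),
        horizon=600.0,
    )


def dead_end_scenario(
    N_T0: float = 1000.0,
    P_T: float = 250.0,
    Kd_P: float = 0.12,
    X_T: float = 250.0,
    Km_X: float = 85e3,
    kcat_X: float = 22.5,
) -> ScenarioConfig:
    """The sequestered enzyme only binds; PPX alone consumes the inhibitor."""
    return ScenarioConfig(
        N_T0=N_T0,
        P_T=P_T,
        params_P=KineticParams(Km=Kd_P, Kd=Kd_P),
        X_T=X_T,
        params_X=KineticParams(Km=Km_X, kcat=kcat_X),
        mode_P="dead_end",
        horizon=20000.0,
    )


@dataclass
class Trajectory:
    """Time-indexed concentrations and derived fractions."""

    t: np.ndarray
    N_T: np.ndarray
    N: np.ndarray
    P: np.ndarray
    X: np.ndarray
    phospho_fraction: np.ndarray
    free_P_fraction: np.ndarray
    config: ScenarioConfig = field(repr=False)
    method: str = "tqssa"
    _free_P_at: object = field(default=None, repr=False)

    def free_P_fraction_at(self, t: float) -> float:
        """Dense (interpolant-based) free-enzyme fraction at arbitrary t."""
        return float(self._free_P_at(t))


def _free_tqssa(N_T: float, cfg: ScenarioConfig) -> tuple[float, float, float]:
    """Free (N, P, X) from the one- or two-enzyme tQSSA algebra."""
    KmP = cfg.binding_Km_P
    if cfg.X_T == 0.0:
        NP = bound_complex(N_T, cfg.P_T, KmP)
        N = N_T - NP
        return N, cfg.P_T - NP, 0.0
    KmX = cfg.params_X.Km

    def g(N: float) -> float:
        return N * (1.0 + cfg.P_T / (KmP + N) + cfg.X_T / (KmX + N)) - N_T

    if N_T == 0.0:
        N = 0.0
    else:
        N = brentq(g, 0.0, N_T, xtol=1e-13, rtol=8.9e-16)
    P = cfg.P_T / (1.0 + N / KmP)
    X = cfg.X_T / (1.0 + N / KmX)
    return N, P, X


def simulate_tqssa(
    config: ScenarioConfig, horizon: float | None = None, n_points: int = 1001
) -> Trajectory:
    """Integrate d[N]_T/dt = -(kcatP [P]/KmP + kcatX [X]/KmX) [N] (tQSSA)."""
    diag = tqssa_validity(config)
    if not diag.valid:
        import warnings

        warnings.warn(
            f"tQSSA validity parameter epsilon = {diag.epsilon:.2e} is not << 1",
            stacklevel=2,
        )
    horizon = float(horizon if horizon is not None else (config.horizon or 600.0))
    cfg = config
    KmP, kcatP = cfg.binding_Km_P, cfg.kcat_P
    kcatX = cfg.params_X.kcat if cfg.params_X else 0.0
    KmX = cfg.params_X.Km if cfg.params_X else 1.0

    def rhs(t: float, y: np.ndarray) -> list[float]:
        N_T = max(y[0], 0.0)
        N, P, X = _free_tqssa(N_T, cfg)
        return [-(kcatP * P / KmP + kcatX * X / KmX) * N]

    sol = solve_ivp(
        rhs, (0.0, horizon), [cfg.N_T0], method="LSODA",
        rtol=RTOL, atol=ATOL, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"tQSSA integration failed: {sol.message}")
    t = np.linspace(0.0, horizon, n_points)
    N_T = np.maximum(sol.sol(t)[0], 0.0)
    free = np.array([_free_tqssa(n, cfg) for n in N_T])
    N, P, X = free[:, 0], free[:, 1], free[:, 2]

    def free_P_at(tq: float) -> float:
        n = max(float(sol.sol(tq)[0]), 0.0)
        return _free_tqssa(n, cfg)[1] / cfg.P_T

    return Trajectory(
        t=t,
        N_T=N_T,
        N=N,
        P=P,
        X=X,
        phospho_fraction=N_T / cfg.N_T0 if cfg.N_T0 > 0 else np.zeros_like(N_T),
        free_P_fraction=P / cfg.P_T,
        config=cfg,
        method="tqssa",
        _free_P_at=free_P_at,
    )


def simulate_mass_action(
    config: ScenarioConfig, horizon: float | None = None, n_points: int = 1001
) -> Trajectory:
    """Explicit mass-action integration including the transient complexes.

    State (N, P, NP, X, NX) with association kon, dissociation koff from
    the Briggs-Haldane relation (see ScenarioConfig.koff_P) and catalytic
    release at kcat.  Starts fully unbound, so it differs from the tQSSA
    during the initial binding transient 0 <= t <= t_c only.
    """
    horizon = float(horizon if horizon is not None else (config.horizon or 600.0))
    cfg = config
    konP, koffP, kcatP = cfg.kon_P, cfg.koff_P, cfg.kcat_P
    has_X = cfg.X_T > 0
    if has_X:
        konX, koffX, kcatX = cfg.kon_X, cfg.koff_X, cfg.params_X.kcat

    def rhs(t: float, y: np.ndarray) -> list[float]:
        N, P, NP, X, NX = y
        bindP = konP * N * P
        dNP = bindP - (koffP + kcatP) * NP
        dN = -bindP + koffP * NP
        dP = -bindP + (koffP + kcatP) * NP
        if has_X:
            bindX = konX * N * X
            dNX = bindX - (koffX + kcatX) * NX
            dN += -bindX + koffX * NX
            dX = -bindX + (koffX + kcatX) * NX
        else:
            dNX, dX = 0.0, 0.0
        return [dN, dP, dNP, dX, dNX]

    y0 = [cfg.N_T0, cfg.P_T, 0.0, cfg.X_T, 0.0]
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method="LSODA",
        rtol=RTOL, atol=ATOL, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"mass-action integration failed: {sol.message}")
    t = np.linspace(0.0, horizon, n_points)
    N, P, NP, X, NX = sol.sol(t)
    if np.any(np.array([N, P, NP, X, NX]) < -1e-6):
        raise RuntimeError("negative concentration in mass-action solution")
    N_T = N + NP + NX

    def free_P_at(tq: float) -> float:
        return float(sol.sol(tq)[1]) / cfg.P_T

    return Trajectory(
        t=t,
        N_T=N_T,
        N=N,
        P=P,
        X=X,
        phospho_fraction=N_T / cfg.N_T0 if cfg.N_T0 > 0 else np.zeros_like(N_T),
        free_P_fraction=P / cfg.P_T,
        config=cfg,
        method="mass_action",
        _free_P_at=free_P_at,
    )


def half_desequestration_time(traj: Trajectory) -> float:
    """First time the free-enzyme fraction crosses 0.5, in seconds.

    Located on the integrator's dense output by bracketing and root
    refinement; returns BEYOND_HORIZON (inf) if the trajectory never
    crosses within its horizon, and 0 if it starts at or above 0.5.
    """
    f = traj.free_P_fraction
    if f[0] >= 0.5:
        return 0.0
    idx = np.nonzero(f >= 0.5)[0]
    if idx.size == 0:
        return BEYOND_HORIZON
    i = idx[0]
    return float(
        brentq(
            lambda t: traj.free_P_fraction_at(t) - 0.5,
            traj.t[i - 1],
            traj.t[i],
            xtol=1e-9,
        )
    )


def fractional_velocities(
    N_T0_grid, config: ScenarioConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Share of dephosphorylating flux carried by each of two phosphatases.

    For each total ligand concentration, solves the two-enzyme algebra for
    the free concentrations and returns f_P = v_P/(v_P+v_X) and its
    complement, where v_P = kcatP [P][N]/KmP and v_X = kcatX [X][N]/KmX.
    The sequestered enzyme dominates until the ligand pool exceeds its own
    capacity to soak it up.
    """
    if config.X_T <= 0 or config.params_X is None:
        raise ValueError("fractional_velocities requires both enzymes present")
    N_T0_grid = np.asarray(N_T0_grid, dtype=float)
    f_P = np.empty_like(N_T0_grid)
    KmP, kcatP = config.binding_Km_P, config.kcat_P
    KmX, kcatX = config.params_X.Km, config.params_X.kcat
    for i, n0 in enumerate(N_T0_grid):
        N, P, X = _free_tqssa(n0, config)
        vP = kcatP * P * N / KmP
        vX = kcatX * X * N / KmX
        if vP + vX == 0.0:
            raise ValueError(f"both velocities vanish at N_T0 = {n0:g} nM")
        f_P[i] = vP / (vP + vX)
    return f_P, 1.0 - f_P


@dataclass(frozen=True)
class ValidityDiagnostics:
    """tQSSA applicability diagnostics.

    epsilon: kcat [P]_T / (kon ([N]_T(0) + [P]_T + Km)^2), dimensionless;
    the approximation is trusted when epsilon << 1.  epsilon_per_nM is the
    variant reading without the [P]_T factor in the numerator (units
    1/nM).  t_c = 1/(kon ([N]_T(0) + Km)) is the duration of the initial
    binding transient during which the tQSSA and mass-action solutions
    legitimately differ.
    """

    epsilon: float
    epsilon_per_nM: float
    t_c: float
    valid: bool


def tqssa_validity(
    config: ScenarioConfig, threshold: float = 1e-2
) -> ValidityDiagnostics:
    """Evaluate the tQSSA validity parameter and transient timescale."""
    kon = config.kon_P
    Km = config.binding_Km_P
    s = config.N_T0 + config.P_T + Km
    eps = config.kcat_P * config.P_T / (kon * s * s)
    eps_alt = config.kcat_P / (kon * s * s)
    t_c = 1.0 / (kon * (config.N_T0 + Km))
    return ValidityDiagnostics(
        epsilon=eps, epsilon_per_nM=eps_alt, t_c=t_c, valid=eps < threshold
    )
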