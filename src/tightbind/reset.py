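"""The "automatic reset" of a sequestered phosphatase.

A tight-binding inhibitor that is also a slow substrate silences the enzyme
only transiently: the enzyme consumes its own inhibitor and then resumes
work on its ordinary (high-Km, high-kcat) reporter substrate.  This module
models that experiment: a reporter dephosphorylation time course with and
without the inhibitor, the lag the inhibitor imposes, and the dose-response
analysis (IC50 and its conversion to a true Kd) that distinguishes a
consumable inhibitor from a dead-end one.

Enzyme activity additionally decays during the long incubations; this is
modeled as first-order loss at rate k_deg, optionally postponed by an onset
delay for inhibitor-containing samples (inhibitor binding appears to
stabilise the enzyme).

Units: concentrations nM, time s.  By convention k_deg is quoted per
minute and the reporter efficiency kcat/Km per (uM s); both are converted
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import KineticParams, bound_complex, tqssa_free_pair
from .fitting import FitError, FitResult, irls_fit

__all__ = [
    "ResetConfig",
    "ResetTrajectory",
    "DoseResponseDataset",
    "control_release_curve",
    "simulate_reset",
    "lag_time",
    "fit_reset",
    "fit_dose_response",
    "ic50_to_kd",
    "BEYOND_HORIZON",
]

BEYOND_HORIZON = math.inf
RTOL = 1e-8
ATOL = 1e-12


@dataclass(frozen=True)
class ResetConfig:
    """Reset-experiment configuration.

    P_T0: initial total enzyme (nM); N_T0: total inhibitor/substrate (nM);
    pC_T: reporter substrate (nM, assumed unbound and undepleted since far
    below its Km); params_N: inhibitor kinetics (Km nM, kcat 1/s);
    eff_C: reporter catalytic efficiency kcat/Km in 1/(uM s);
    kdeg: enzyme decay in 1/min; deg_onset: decay start time (s);
    inhibitor_mode "substrate" consumes the inhibitor, "dead_end" only
    binds it (requires Kd_dead, nM).
    """

    P_T0: float
    N_T0: float
    pC_T: float
    params_N: KineticParams
    eff_C: float
    kdeg: float = 0.0
    deg_onset: float = 0.0
    inhibitor_mode: str = "substrate"
    Kd_dead: float | None = None

    def __post_init__(self) -> None:
        if self.inhibitor_mode not in ("substrate", "dead_end"):
            raise ValueError(f"unknown inhibitor_mode {self.inhibitor_mode!r}")
        if self.inhibitor_mode == "dead_end" and self.Kd_dead is None:
            raise ValueError("dead_end mode requires Kd_dead")
        for name in ("P_T0", "pC_T", "eff_C"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.N_T0 < 0 or self.kdeg < 0 or self.deg_onset < 0:
            raise ValueError("N_T0, kdeg and deg_onset must be >= 0")

    @property
    def eff_nM(self) -> float:
        """Reporter efficiency in 1/(nM s)."""
        return self.eff_C * 1e-3

    @property
    def kdeg_s(self) -> float:
        """Enzyme decay rate in 1/s."""
        return self.kdeg / 60.0

    @property
    def binding_Km(self) -> float:
        """Effective binding constant for the inhibitor complex (nM)."""
        return self.Kd_dead if self.inhibitor_mode == "dead_end" else self.params_N.Km

    @property
    def kcat_N(self) -> float:
        """Inhibitor turnover; zero for a dead-end inhibitor."""
        return 0.0 if self.inhibitor_mode == "dead_end" else self.params_N.kcat

    def total_enzyme(self, t):
        """[P]_T(t) under first-order decay postponed to deg_onset."""
        t = np.asarray(t, dtype=float)
        decay = np.exp(-self.kdeg_s * np.maximum(t - self.deg_onset, 0.0))
        return self.P_T0 * decay


@dataclass
class ResetTrajectory:
    """Time course of the reset experiment on a user grid, with dense access."""

    t: np.ndarray
    N_T: np.ndarray
    P_T: np.ndarray
    free_P: np.ndarray
    released: np.ndarray  # reporter product (nM)
    rate: np.ndarray  # instantaneous reporter dephosphorylation rate (nM/s)
    config: ResetConfig = field(repr=False)
    _dense: object = field(default=None, repr=False)

    def rate_at(self, t: float) -> float:
        """Model-based instantaneous reporter rate at arbitrary t."""
        cfg = self.config
        if self._dense is None:
            N_T = cfg.N_T0
        else:
            N_T = max(float(self._dense(t)[0]), 0.0)
        P_tot = float(cfg.total_enzyme(t))
        _, P = tqssa_free_pair(N_T, P_tot, cfg.binding_Km)
        return cfg.eff_nM * cfg.pC_T * P


def control_release_curve(config: ResetConfig, t) -> np.ndarray:
    """Closed-form reporter release (nM) for the no-inhibitor control.

    released(t) = (kcat/Km) [pC]_T [P]_T(0) (1 - e^{-kdeg t}) / kdeg,
    with the kdeg -> 0 limit rate0 * t.  The control's decay onset is 0.
    """
    if config.N_T0 != 0:
        raise ValueError("control_release_curve requires N_T0 = 0")
    t = np.asarray(t, dtype=float)
    rate0 = config.eff_nM * config.pC_T * config.P_T0
    k = config.kdeg_s
    if k == 0.0:
        return rate0 * t
    return rate0 * -np.expm1(-k * t) / k


def simulate_reset(config: ResetConfig, t_grid) -> ResetTrajectory:
    """Integrate inhibitor depletion and reporter release on t_grid.

    The tQSSA gives free enzyme [P] from (N_T(t), P_T(t)); the inhibitor
    depletes as d[N]_T/dt = -kcat_N [P] [N] / Km while the reporter product
    accumulates as d[32P]/dt = eff * [pC]_T * [P].  Reporter binding is
    neglected (pC_T far below its own Km).  In dead_end mode the inhibitor
    is not consumed and Km is replaced by Kd_dead.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    cfg = config
    Km, kcat = cfg.binding_Km, cfg.kcat_N

    def rhs(t: float, y: np.ndarray) -> list[float]:
        N_T = max(y[0], 0.0)
        P_tot = float(cfg.total_enzyme(t))
        N, P = tqssa_free_pair(N_T, P_tot, Km)
        return [-kcat * P * N / Km, cfg.eff_nM * cfg.pC_T * P]

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs,
        (t0, t_grid[-1]),
        [cfg.N_T0, 0.0],
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"reset integration failed: {sol.message}")
    y = sol.sol(t_grid)
    N_T = np.maximum(y[0], 0.0)
    released = y[1]
    P_tot = cfg.total_enzyme(t_grid)
    free_P = np.array([tqssa_free_pair(n, p, Km)[1] for n, p in zip(N_T, P_tot)])
    rate = cfg.eff_nM * cfg.pC_T * free_P
    return ResetTrajectory(
        t=t_grid,
        N_T=N_T,
        P_T=P_tot,
        free_P=free_P,
        released=released,
        rate=rate,
        config=cfg,
        _dense=sol.sol,
    )


def lag_time(traj: ResetTrajectory, control: ResetTrajectory) -> float:
    """Delay imposed by the inhibitor, in seconds.

    First time at which the inhibited sample's instantaneous reporter rate
    reaches 50% of the control's rate at the same time, located by root
    finding on the model rates.  Returns BEYOND_HORIZON (inf) if the
    threshold is never reached within the common grid.
    """
    t_lo, t_hi = max(traj.t[0], control.t[0]), min(traj.t[-1], control.t[-1])
    if t_hi <= t_lo:
        raise ValueError("trajectories share no time interval")

    def deficit(t: float) -> float:
        return traj.rate_at(t) / control.rate_at(t) - 0.5

    if deficit(max(t_lo, 1e-9)) >= 0.0:
        return 0.0
    grid = np.linspace(max(t_lo, 1e-9), t_hi, 2049)
    vals = np.array([deficit(t) for t in grid])
    idx = np.nonzero(vals >= 0.0)[0]
    if idx.size == 0:
        return BEYOND_HORIZON
    i = idx[0]
    return float(brentq(deficit, grid[i - 1], grid[i], xtol=1e-6))


def fit_reset(
    control_data: pd.DataFrame,
    inhibited_data: pd.DataFrame,
    config: ResetConfig,
    weighting: str = "model",
) -> tuple[FitResult, FitResult]:
    """Two-stage fit of the reset experiment.

    Stage 1 fits (eff_C, kdeg) to the control time course with the closed
    form; stage 2 fixes those and fits the inhibitor's (Km, kcat) to the
    inhibited course by forward simulation.  Both data frames need columns
    t_s and released_nM.  The supplied config provides the known totals and
    starting guesses; its deg_onset applies to the inhibited stage only
    (the control uses onset 0).
    """
    tc = control_data["t_s"].to_numpy(float)
    yc = control_data["released_nM"].to_numpy(float)
    mask = tc > 0
    ctrl_cfg = replace(
        config, N_T0=0.0, deg_onset=0.0, inhibitor_mode="substrate", Kd_dead=None
    )

    def control_model(theta: np.ndarray) -> np.ndarray:
        eff, kdeg = theta
        c = replace(ctrl_cfg, eff_C=eff, kdeg=kdeg)
        return control_release_curve(c, tc[mask])

    p0 = (config.eff_C, max(config.kdeg, 1e-4))
    fit_ctrl = irls_fit(control_model, yc[mask], p0, ("eff_C", "kdeg"), weighting=weighting)

    ti = inhibited_data["t_s"].to_numpy(float)
    yi = inhibited_data["released_nM"].to_numpy(float)
    maski = ti > 0
    t_eval = np.unique(ti[maski])
    base = replace(
        config, eff_C=fit_ctrl.estimates["eff_C"], kdeg=fit_ctrl.estimates["kdeg"]
    )

    def inhibited_model(theta: np.ndarray) -> np.ndarray:
        Km, kcat = theta
        c = replace(base, params_N=KineticParams(Km=Km, kcat=kcat))
        traj = simulate_reset(c, t_eval)
        lookup = dict(zip(t_eval, traj.released))
        return np.array([lookup[t] for t in ti[maski]])

    p0 = (config.params_N.Km, config.params_N.kcat)
    fit_inh = irls_fit(inhibited_model, yi[maski], p0, ("Km", "kcat"), weighting=weighting)
    fit_inh.notes.append(
        "control parameters fixed at stage-1 estimates: "
        f"eff_C={base.eff_C:.4g}/(uM s), kdeg={base.kdeg:.4g}/min"
    )
    return fit_ctrl, fit_inh


@dataclass
class DoseResponseDataset:
    """Fractional enzyme activity vs inhibitor dose at fixed conditions.

    ``data`` columns: inhibitor_conc (nM), activity_fraction.  P_T: enzyme
    (nM); S: reporter substrate concentration (nM); Km_S: reporter Km (nM).
    """

    data: pd.DataFrame
    P_T: float
    S: float
    Km_S: float
    incubation_time: float | None = None

    def __post_init__(self) -> None:
        a = self.data["activity_fraction"]
        if (a < 0).any() or (a > 1.2).any():
            raise ValueError("activity_fraction must lie in [0, 1.2]")


def _morrison_activity(I_T: np.ndarray, P_T: float, Kd_app: float, A0: float) -> np.ndarray:
    bound = np.array([bound_complex(i, P_T, Kd_app) for i in I_T])
    return A0 * (1.0 - bound / P_T)


def fit_dose_response(data: DoseResponseDataset, model: str = "auto") -> FitResult:
    """Fit an inhibition dose-response curve and report its IC50 (nM).

    For tight-binding inhibitors (IC50 comparable to the enzyme
    concentration) the free-enzyme fraction from the tight-binding
    quadratic is the correct curve shape and yields
    IC50 = Kd_app + P_T/2; for weak inhibitors a logistic (Hill) form is
    used.  ``model``: "morrison", "logistic" or "auto" (tight-binding
    shape whenever the logistic midpoint lands within 20x the enzyme
    concentration).
    """
    I = data.data["inhibitor_conc"].to_numpy(float)
    a = data.data["activity_fraction"].to_numpy(float)
    if np.unique(I).size < 6:
        raise FitError("need at least 6 dose levels")
    P_T = data.P_T

    pos = I > 0
    mid0 = float(np.exp(np.interp(0.5, a[pos][np.argsort(a[pos])],
                                  np.log(I[pos])[np.argsort(a[pos])])))

    def fit_logistic() -> FitResult:
        def m(theta: np.ndarray) -> np.ndarray:
            ic50, h, A0 = theta
            return A0 / (1.0 + (I / ic50) ** h)

        res = irls_fit(m, a, (mid0, 1.0, max(a.max(), 0.5)), ("IC50", "hill", "A0"))
        res.notes.append("logistic (Hill) dose-response model")
        return res

    def fit_morrison() -> FitResult:
        def m(theta: np.ndarray) -> np.ndarray:
            Kd_app, A0 = theta
            return _morrison_activity(I, P_T, Kd_app, A0)

        kd0 = max(mid0 - P_T / 2.0, mid0 * 1e-3)
        res = irls_fit(m, a, (kd0, max(a.max(), 0.5)), ("Kd_app", "A0"))
        ic50 = res.estimates["Kd_app"] + P_T / 2.0
        res.estimates["IC50"] = ic50
        res.stderrs["IC50"] = res.stderrs["Kd_app"]
        res.notes.append("tight-binding (free-enzyme fraction) dose-response model")
        return res

    if model == "logistic":
        res = fit_logistic()
    elif model == "morrison":
        res = fit_morrison()
    elif model == "auto":
        res = fit_logistic()
        if res.estimates["IC50"] < 20.0 * P_T:
            res = fit_morrison()
    else:
        raise ValueError(f"unknown model {model!r}")

    ic50 = res.estimates["IC50"]
    if not (I[pos].min() <= ic50 <= I.max()):
        res.notes.append(
            f"extrapolation warning: fitted IC50 = {ic50:.3g} nM lies outside "
            f"the measured dose range [{I[pos].min():.3g}, {I.max():.3g}] nM"
        )
    return res


def ic50_to_kd(IC50: float, P_T: float, S: float, Km_S: float) -> float:
    """Convert a tight-binding competitive IC50 to a true Kd (nM).

    Kd = (IC50 - P_T/2) / (1 + S/Km_S): the P_T/2 term removes the
    stoichiometric titration of the enzyme and the denominator removes the
    competition from the assay substrate.  Below the titration limit
    IC50 <= P_T/2 the Kd is unresolvable.
    """
    if IC50 <= P_T / 2.0:
        raise ValueError(
            f"IC50 = {IC50:g} nM is at or below the stoichiometric titration "
            f"limit P_T/2 = {P_T / 2.0:g} nM; Kd unresolvable"
        )
    return (IC50 - P_T / 2.0) / (1.0 + S / Km_S)
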