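"""Seeded generators for the three assay designs, with known ground truth.

Each generator forward-simulates the corresponding model and applies
multiplicative Gaussian noise — value * (1 + cv * z), truncated at zero —
which is the simplest error model consistent with identically distributed
fractional errors; a lognormal variant is available.  Defaults mirror the
experimental designs: enzyme at 0.25-1 nM, ligand grids spanning ~1-1100 nM,
3-4 technical replicates, incubations short enough to keep conversion below
20%.  Generators are pure functions of (truth, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .competition import CompetitionDataset, predict_release
from .core import KineticParams, morrison_velocity
from .reset import ResetConfig, ResetTrajectory, control_release_curve, simulate_reset

__all__ = [
    "NoiseModel",
    "gen_velocity_dataset",
    "gen_competition_dataset",
    "gen_reset_timecourses",
    "DEFAULT_VELOCITY_GRID",
    "DEFAULT_OA_GRID",
]

# ligand titration used in the direct velocity assays (nM)
DEFAULT_VELOCITY_GRID = (1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 110.0, 1100.0)
# okadaic-acid dose grid (nM): half-decade steps spanning KdO up to the
# competition midpoint scale KdO*(1 + N_T0/Km) for sub-nM Km
DEFAULT_OA_GRID = (0.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0, 30000.0)


@dataclass(frozen=True)
class NoiseModel:
    """Identically distributed fractional measurement noise."""

    cv: float = 0.10
    replicates: int = 3
    seed: int = 0
    lognormal: bool = False

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0.0:
            return np.asarray(values, dtype=float).copy()
        if self.lognormal:
            sigma = np.sqrt(np.log1p(self.cv**2))
            factor = rng.lognormal(-sigma**2 / 2.0, sigma, size=np.shape(values))
        else:
            factor = 1.0 + self.cv * rng.standard_normal(np.shape(values))
        return np.maximum(values * factor, 0.0)


def gen_velocity_dataset(
    truth: KineticParams,
    P_T: float = 0.5,
    N_T_grid=DEFAULT_VELOCITY_GRID,
    noise: NoiseModel = NoiseModel(),
    experiment_id: str = "synthetic",
    incubation_s: float | None = None,
):
    """Initial-velocity titration table from a known (Km, kcat) truth."""
    from .velocity import VelocityDataset

    rng = np.random.default_rng(noise.seed)
    rows = []
    for n in N_T_grid:
        v_true = morrison_velocity(n, P_T, truth)
        v_obs = noise.apply(np.full(noise.replicates, v_true), rng)
        for r, v in enumerate(v_obs, start=1):
            rows.append((experiment_id, r, float(n), float(v)))
    data = pd.DataFrame(rows, columns=["experiment_id", "replicate_id", "N_T", "v"])
    ds = VelocityDataset(
        data=data,
        P_T=P_T,
        truth={"Km": truth.Km, "kcat": truth.kcat, "cv": noise.cv, "seed": noise.seed},
    )
    if incubation_s is not None:
        ds.flag_conversion(incubation_s)
    return ds


def gen_competition_dataset(
    truth: KineticParams,
    N_T0: float = 50.0,
    P_T: float = 0.25,
    t_end: float = 600.0,
    O_T_grid=DEFAULT_OA_GRID,
    KdO: float = 30.0,
    noise: NoiseModel = NoiseModel(),
    experiment_id: str = "synthetic",
) -> CompetitionDataset:
    """Competitor dose-response table (released fraction at fixed time)."""
    rng = np.random.default_rng(noise.seed)
    rows = []
    for o in O_T_grid:
        f_true = predict_release(N_T0, P_T, o, KdO, truth, t_end)
        f_obs = noise.apply(np.full(noise.replicates, f_true), rng)
        for r, f in enumerate(f_obs, start=1):
            rows.append((experiment_id, r, float(o), float(f)))
    data = pd.DataFrame(
        rows, columns=["experiment_id", "replicate_id", "O_T", "released_fraction"]
    )
    ds = CompetitionDataset(
        data=data,
        N_T0=N_T0,
        P_T=P_T,
        t_end=t_end,
        KdO=KdO,
        truth={"Km": truth.Km, "kcat": truth.kcat, "cv": noise.cv, "seed": noise.seed},
    )
    max_true = predict_release(N_T0, P_T, 0.0, KdO, truth, t_end)
    if max_true >= 0.2:
        ds.flags.append(
            f"uninhibited release {max_true:.2f} exceeds the 20% design cap; "
            "shorten t_end or lower P_T"
        )
    return ds


def gen_reset_timecourses(
    truth: ResetConfig,
    t_grid=None,
    noise: NoiseModel = NoiseModel(cv=0.05),
) -> tuple[pd.DataFrame, pd.DataFrame, ResetTrajectory]:
    """Paired control / inhibited reporter time courses.

    Returns (control_df, inhibited_df, inhibited_trajectory) where the data
    frames carry noisy released_nM at each grid time (columns: condition_id,
    t_s, released_nM, replicate_id).  Default grid: every 10 min to 120 min.
    """
    from dataclasses import replace

    if t_grid is None:
        t_grid = np.arange(0.0, 121.0, 10.0) * 60.0
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(noise.seed)

    ctrl_cfg = replace(truth, N_T0=0.0, deg_onset=0.0, inhibitor_mode="substrate",
                       Kd_dead=None)
    ctrl_true = control_release_curve(ctrl_cfg, t_grid)
    traj = simulate_reset(truth, t_grid if t_grid[0] > 0 else t_grid[1:])
    inh_true = np.interp(t_grid, traj.t, traj.released, left=0.0)

    def table(cond: str, values: np.ndarray) -> pd.DataFrame:
        rows = []
        for t, y in zip(t_grid, values):
            obs = noise.apply(np.full(noise.replicates, y), rng)
            for r, v in enumerate(obs, start=1):
                rows.append((cond, float(t), float(v), r))
        return pd.DataFrame(rows, columns=["condition_id", "t_s", "released_nM",
                                           "replicate_id"])

    return table("control", ctrl_true), table("inhibited", inh_true), traj
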