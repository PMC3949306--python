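"""Config loading, trajectory output and plotting.

All numeric keys in configs and CSV columns carry explicit unit suffixes
(``_nM``, ``_uM``, ``_s``, ``_min``, ``_per_s``, ``_per_min``); values are
converted to the canonical internal units (nM, s) at load time.  Unknown
keys are rejected rather than ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .core import KineticParams
from .exitsim import ScenarioConfig, Trajectory

__all__ = ["load_scenario_yaml", "scenario_from_dict", "write_trajectory_csv", "plot_fractions"]

_UNIT_FACTORS = {
    "_nM": 1.0,
    "_uM": 1e3,  # -> nM
    "_per_s": 1.0,
    "_per_min": 1.0 / 60.0,  # -> 1/s
    "_per_nM_s": 1.0,
    "_s": 1.0,
    "_min": 60.0,  # -> s
}

_SCENARIO_KEYS = {
    "N_T0": ("N_T0", True),
    "P_T": ("P_T", True),
    "Km_P": ("Km_P", False),
    "kcat_P": ("kcat_P", False),
    "Kd_P": ("Kd_P", False),
    "X_T": ("X_T", False),
    "Km_X": ("Km_X", False),
    "kcat_X": ("kcat_X", False),
    "kon": ("kon", False),
    "kon_X": ("kon_X", False),
    "horizon": ("horizon", False),
}


def _strip_units(raw: dict) -> dict:
    """Convert unit-suffixed keys to canonical bare keys in nM / s."""
    out: dict = {}
    for key, value in raw.items():
        if key == "mode_P":
            out[key] = value
            continue
        for suffix, factor in sorted(_UNIT_FACTORS.items(), key=lambda kv: -len(kv[0])):
            if key.endswith(suffix):
                out[key[: -len(suffix)]] = float(value) * factor
                break
        else:
            raise ValueError(
                f"config key {key!r} lacks a recognised unit suffix "
                f"(one of {sorted(_UNIT_FACTORS)})"
            )
    return out


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a unit-suffixed mapping."""
    mode = raw.pop("mode_P", "substrate") if isinstance(raw, dict) else "substrate"
    vals = _strip_units(raw)
    unknown = set(vals) - set(_SCENARIO_KEYS)
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    for name, (_, required) in _SCENARIO_KEYS.items():
        if required and name not in vals:
            raise ValueError(f"scenario config missing required key {name}")
    if mode == "dead_end":
        if "Kd_P" not in vals:
            raise ValueError("dead_end scenario requires Kd_P")
        params_P = KineticParams(Km=vals["Kd_P"], Kd=vals["Kd_P"])
    else:
        params_P = KineticParams(Km=vals["Km_P"], kcat=vals["kcat_P"])
    params_X = None
    if vals.get("X_T", 0.0) > 0:
        params_X = KineticParams(Km=vals["Km_X"], kcat=vals["kcat_X"])
    kwargs = {}
    if "kon" in vals:
        kwargs["kon_P"] = vals["kon"]
    if "kon_X" in vals:
        kwargs["kon_X"] = vals["kon_X"]
    return ScenarioConfig(
        N_T0=vals["N_T0"],
        P_T=vals["P_T"],
        params_P=params_P,
        X_T=vals.get("X_T", 0.0),
        params_X=params_X,
        mode_P=mode,
        horizon=vals.get("horizon"),
        **kwargs,
    )


def load_scenario_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return scenario_from_dict(dict(raw))


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "t_s": traj.t,
            "N_T_nM": traj.N_T,
            "free_N_nM": traj.N,
            "free_P_nM": traj.P,
            "free_X_nM": traj.X,
            "phospho_fraction": traj.phospho_fraction,
            "free_P_fraction": traj.free_P_fraction,
        }
    ).to_csv(path, index=False)


def plot_fractions(traj: Trajectory, path) -> None:
    """Phospho-fraction and free-enzyme fraction vs time, one panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(traj.t, traj.phospho_fraction, color="purple", label="phospho-ligand fraction")
    ax.plot(traj.t, traj.free_P_fraction, color="darkorange", label="free enzyme fraction")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
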