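"""Weighted nonlinear regression shared by all fitters.

The error model throughout is *equal fractional errors*: measurement noise
scales with the size of the measured quantity, so weighted least squares
uses weights proportional to 1/y^2.  Two weighting variants are supported:

``model`` (default)
    Iteratively reweighted least squares (IRLS): weights 1/max(y_model,
    floor)^2 frozen from the previous iterate, refit until the parameters
    stabilise.  Matches a multiplicative (lognormal-like) error assumption.
``observed``
    Fixed weights 1/max(y_obs, floor)^2; a single weighted solve.

Parameters are fitted on the log scale, which guarantees positivity
without hard bounds; standard errors are mapped back to the natural scale
by the delta method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "FitError", "irls_fit", "inverse_variance_pool"]

EPS_FLOOR = 1e-12  # nM/s; guards zero-velocity points in the weights
MAX_OUTER_ITER = 500
PARAM_RTOL = 1e-8


class FitError(RuntimeError):
    """Raised on non-convergence or degenerate data; carries diagnostics."""

    def __init__(self, message: str, last_iterate: dict | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class FitResult:
    """Point estimates with standard errors from a weighted regression."""

    estimates: dict[str, float]
    stderrs: dict[str, float]
    covariance: np.ndarray | None
    weighting: str
    n_points: int
    converged: bool
    n_outer_iter: int = 0
    residual_rms: float = float("nan")
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.estimates[name], self.stderrs[name]

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "stderrs": self.stderrs,
            "covariance": None
            if self.covariance is None
            else np.asarray(self.covariance).tolist(),
            "weighting": self.weighting,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_outer_iter": self.n_outer_iter,
            "residual_rms": self.residual_rms,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def irls_fit(
    model_fn: Callable[[np.ndarray], np.ndarray],
    y_obs: np.ndarray,
    p0: Sequence[float],
    param_names: Sequence[str],
    weighting: str = "model",
) -> FitResult:
    """Fit positive parameters to positive data under fractional-error weights.

    ``model_fn`` maps a natural-scale parameter vector to predicted
    observations aligned with ``y_obs``.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    if y_obs.size == 0:
        raise FitError("empty dataset")
    if np.all(y_obs <= 0):
        raise FitError("degenerate data: all observations are zero or negative")
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 <= 0):
        raise FitError(f"initial guesses must be positive, got {dict(zip(param_names, p0))}")
    if weighting not in ("model", "observed"):
        raise ValueError(f"unknown weighting {weighting!r}")

    def solve(log_p: np.ndarray, weights: np.ndarray):
        def resid(lp: np.ndarray) -> np.ndarray:
            return (y_obs - model_fn(np.exp(lp))) / weights

        return least_squares(resid, log_p, method="lm", xtol=1e-12, ftol=1e-12)

    log_p = np.log(p0)
    if weighting == "observed":
        weights = np.maximum(y_obs, EPS_FLOOR)
        sol = solve(log_p, weights)
        n_outer = 1
        converged = sol.success
    else:
        weights = np.maximum(model_fn(np.exp(log_p)), EPS_FLOOR)
        converged = False
        n_outer = 0
        for n_outer in range(1, MAX_OUTER_ITER + 1):
            sol = solve(log_p, weights)
            new_log_p = sol.x
            if np.all(
                np.abs(new_log_p - log_p) <= PARAM_RTOL * np.maximum(np.abs(log_p), 1.0)
            ):
                log_p = new_log_p
                converged = True
                break
            log_p = new_log_p
            weights = np.maximum(model_fn(np.exp(log_p)), EPS_FLOOR)
        sol = solve(log_p, weights)

    if not converged or not sol.success:
        raise FitError(
            f"regression did not converge after {n_outer} reweighting iterations",
            last_iterate=dict(zip(param_names, np.exp(sol.x))),
        )

    theta = np.exp(sol.x)
    n, k = y_obs.size, theta.size
    dof = max(n - k, 1)
    rss = float(2.0 * sol.cost)
    s2 = rss / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov_log = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov_log = s2 * np.linalg.pinv(JtJ)
    # delta method: theta = exp(phi)
    scale = np.outer(theta, theta)
    cov = cov_log * scale
    stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return FitResult(
        estimates=dict(zip(param_names, map(float, theta))),
        stderrs=dict(zip(param_names, map(float, stderr))),
        covariance=cov,
        weighting=weighting,
        n_points=int(n),
        converged=True,
        n_outer_iter=n_outer,
        residual_rms=math.sqrt(rss / n),
    )


def inverse_variance_pool(fits: Sequence[FitResult]) -> FitResult:
    """Pool parameter estimates across experiments by inverse-variance weighting.

    Weighted mean with w_i = 1/SE_i^2 per parameter and pooled
    SE = (sum w_i)^(-1/2).  A single fit is returned unchanged with a note.
    """
    if len(fits) == 0:
        raise FitError("nothing to pool")
    if len(fits) == 1:
        out = fits[0]
        out.notes.append("single experiment: pooled result is the fit itself")
        return out
    if any(not f.converged for f in fits):
        raise FitError("can only pool converged fits")
    names = list(fits[0].estimates)
    if any(list(f.estimates) != names for f in fits):
        raise FitError("fits estimate different parameter sets")
    estimates: dict[str, float] = {}
    stderrs: dict[str, float] = {}
    for name in names:
        w = np.array([1.0 / f.stderrs[name] ** 2 for f in fits])
        x = np.array([f.estimates[name] for f in fits])
        estimates[name] = float(np.sum(w * x) / np.sum(w))
        stderrs[name] = float(1.0 / math.sqrt(np.sum(w)))
    return FitResult(
        estimates=estimates,
        stderrs=stderrs,
        covariance=None,
        weighting="inverse-variance pool",
        n_points=sum(f.n_points for f in fits),
        converged=True,
        notes=[f"pooled over {len(fits)} experiments"],
    )
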