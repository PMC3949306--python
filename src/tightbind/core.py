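"""Closed-form tight-binding algebra.

Quasi-steady-state treatment of an enzyme P acting on (or sequestered by) a
ligand N when the enzyme concentration is *not* negligible relative to the
Michaelis constant, so the classic substitutions [N] ~ [N]_T and
[P] ~ [P]_T are invalid.  Combining mass conservation with the QSS condition
for the complex NP gives the quadratic

    [NP]^2 - ([N]_T + [P]_T + Km) [NP] + [N]_T [P]_T = 0,

whose smaller root is the physical complex concentration (Morrison form).
All concentrations are in nM, all times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KineticParams",
    "SpeciesTotals",
    "bound_complex",
    "morrison_velocity",
    "free_concentrations_competitive",
    "tqssa_free_pair",
]

_KD_RTOL = 1e-6


@dataclass(frozen=True)
class KineticParams:
    """Rate and binding constants for one enzyme-ligand pair.

    Parameters
    ----------
    Km : float
        Michaelis constant in nM.
    kcat : float, optional
        Turnover number in 1/s.  Absent for a dead-end (non-hydrolyzed)
        ligand.
    kon : float, optional
        Association rate in 1/(nM s).
    koff : float, optional
        Dissociation rate in 1/s.
    Kd : float, optional
        Equilibrium dissociation constant in nM.  When ``kon``, ``koff``
        and ``Kd`` are all given, ``Kd == koff/kon`` is enforced to a
        relative tolerance of 1e-6.
    """

    Km: float
    kcat: float | None = None
    kon: float | None = None
    koff: float | None = None
    Kd: float | None = None

    def __post_init__(self) -> None:
        for name in ("Km", "kcat", "kon", "koff", "Kd"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.kon is not None and self.koff is not None and self.Kd is not None:
            implied = self.koff / self.kon
            if abs(implied - self.Kd) > _KD_RTOL * self.Kd:
                raise ValueError(
                    f"inconsistent constants: koff/kon = {implied:g} nM "
                    f"but Kd = {self.Kd:g} nM"
                )


@dataclass(frozen=True)
class SpeciesTotals:
    """Total (free + bound) concentrations of all species, in nM.

    N_T is the phospho-ligand (substrate and/or inhibitor), P_T the primary
    enzyme, O_T a dead-end active-site competitor, X_T a secondary enzyme,
    pC_T a reporter substrate.
    """

    N_T: float
    P_T: float
    O_T: float = 0.0
    X_T: float = 0.0
    pC_T: float = 0.0

    def __post_init__(self) -> None:
        for name in ("N_T", "P_T", "O_T", "X_T", "pC_T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0 or not math.isfinite(value):
            raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


def bound_complex(N_T: float, P_T: float, Km: float) -> float:
    """Equilibrium/QSS concentration of the enzyme-ligand complex, in nM.

    Returns the smaller root of the tight-binding quadratic, computed via
    the conjugate form 2ab/(s + sqrt(s^2 - 4ab)) which is stable when
    4*N_T*P_T << s^2 (the naive "minus" root suffers catastrophic
    cancellation there).
    """
    _check_nonneg(N_T=N_T, P_T=P_T)
    if not Km > 0:
        raise ValueError(f"Km must be strictly positive, got {Km!r}")
    if N_T == 0.0 or P_T == 0.0:
        return 0.0
    s = N_T + P_T + Km
    disc = s * s - 4.0 * N_T * P_T
    # disc = (N_T - P_T)^2 + Km*(2*N_T + 2*P_T + Km) > 0 always
    return 2.0 * N_T * P_T / (s + math.sqrt(disc))


def morrison_velocity(N_T: float, P_T: float, params: KineticParams) -> float:
    """Tight-binding initial velocity v = kcat * [NP], in nM/s.

    Reduces to classic Michaelis-Menten v = kcat*P_T*N_T/(Km+N_T) in the
    dilute-enzyme limit P_T << Km + N_T.
    """
    if params.kcat is None:
        raise ValueError("params.kcat is required for a velocity")
    return params.kcat * bound_complex(N_T, P_T, params.Km)


def free_concentrations_competitive(
    totals: SpeciesTotals, Km: float, KdO: float
) -> tuple[float, float, float]:
    """Free (N, O, P) when a dead-end competitor O shares the active site.

    Solves the coupled QSS relations

        [N] = [N]_T / (1 + [P]/Km)
        [O] = [O]_T / (1 + [P]/KdO)
        [P] = [P]_T / (1 + [O]/KdO + [N]/Km)

    under the approximation [N] ~ [N]_T, valid when the ligand is in large
    excess over the enzyme (enforced: N_T >= 100*P_T).  Eliminating [O]
    leaves a quadratic in [P],

        a P^2 + (a*KdO + O_T - P_T) P - P_T*KdO = 0,   a = 1 + N_T/Km,

    whose positive root is returned together with consistent [N] and [O].
    """
    if not (Km > 0 and KdO > 0):
        raise ValueError("Km and KdO must be strictly positive")
    N_T, P_T, O_T = totals.N_T, totals.P_T, totals.O_T
    if P_T > 0 and N_T < 100.0 * P_T:
        raise ValueError(
            "free_concentrations_competitive requires N_T >= 100*P_T "
            f"(ligand excess); got N_T/P_T = {N_T / P_T:g}"
        )
    return _free_competitive_unchecked(N_T, P_T, O_T, Km, KdO)


def _free_competitive_unchecked(
    N_T: float, P_T: float, O_T: float, Km: float, KdO: float
) -> tuple[float, float, float]:
    """Same algebra as free_concentrations_competitive, no regime guard."""
    if P_T == 0.0:
        return N_T, O_T, 0.0
    a = 1.0 + N_T / Km
    b = a * KdO + O_T - P_T
    c = -P_T * KdO
    # positive root, stable for either sign of b
    disc = math.sqrt(b * b - 4.0 * a * c)
    if b >= 0:
        P = -2.0 * c / (b + disc)
    else:
        P = (-b + disc) / (2.0 * a)
    P = min(max(P, 0.0), P_T)
    O = O_T / (1.0 + P / KdO)
    return N_T, O, P


def tqssa_free_pair(N_T: float, P_T: float, Km: float) -> tuple[float, float]:
    """Free (N, P) from the total-QSSA pair, without assuming N_T >> P_T.

    [N] = [N]_T/(1 + [P]/Km) and [P] = [P]_T/(1 + [N]/Km) solved
    simultaneously; equivalent to the tight-binding quadratic via
    N = N_T - [NP], P = P_T - [NP].  The nearly-consumed species is
    recovered from the QSS relation N*P = Km*NP rather than by
    subtraction, which would cancel catastrophically when it is almost
    fully bound.
    """
    NP = bound_complex(N_T, P_T, Km)
    if NP == 0.0:
        return N_T, P_T
    if N_T >= P_T:
        N = N_T - NP
        P = Km * NP / N
    else:
        P = P_T - NP
        N = Km * NP / P
    return N, P
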