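"""Tight-binding algebra: quadratic roots, competitive displacement, tQSSA pair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tightbind.core import (
    KineticParams,
    SpeciesTotals,
    bound_complex,
    free_concentrations_competitive,
    morrison_velocity,
    tqssa_free_pair,
)

from .conftest import bisect_complex

log_conc = st.floats(min_value=-3.0, max_value=6.0)


class TestKineticParams:
    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError, match="Km"):
            KineticParams(Km=0.0)
        with pytest.raises(ValueError, match="kcat"):
            KineticParams(Km=1.0, kcat=-0.1)

    def test_rejects_inconsistent_rate_constants(self):
        with pytest.raises(ValueError, match="inconsistent"):
            KineticParams(Km=1.0, kon=0.057, koff=0.0068, Kd=0.5)

    def test_accepts_consistent_rate_constants(self):
        p = KineticParams(Km=1.0, kon=0.057, koff=0.0068, Kd=0.0068 / 0.057)
        assert p.Kd == pytest.approx(0.119298, rel=1e-4)

    def test_km_kd_independent(self):
        # a tight inhibitor may carry Kd < Km without complaint
        KineticParams(Km=1.0, Kd=0.12)


class TestBoundComplex:
    @pytest.mark.parametrize(
        "N_T, P_T, Km, expected",
        [
            (0.0, 0.5, 1.0, 0.0),
            (1.0, 0.0, 1.0, 0.0),
            (1.0, 0.5, 1.0, 0.2192235936),  # bisection oracle value
        ],
    )
    def test_known_values(self, N_T, P_T, Km, expected):
        assert bound_complex(N_T, P_T, Km) == pytest.approx(expected, abs=1e-9)

    def test_saturation_limit(self):
        # enzyme fully occupied as substrate becomes saturating
        assert bound_complex(1100.0, 0.5, 1.0) == pytest.approx(0.49973, rel=1e-3)
        assert bound_complex(1e9, 0.5, 1.0) == pytest.approx(0.5, rel=1e-6)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            bound_complex(-1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            bound_complex(1.0, 0.5, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ln=log_conc, lp=log_conc, lk=log_conc)
    def test_matches_bisection_oracle_on_log_grid(self, ln, lp, lk):
        N_T, P_T, Km = 10.0**ln, 10.0**lp, 10.0**lk
        got = bound_complex(N_T, P_T, Km)
        want = bisect_complex(N_T, P_T, Km)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-300)
        assert 0.0 <= got <= min(N_T, P_T)


class TestMorrisonVelocity:
    def test_zero_substrate_gives_zero(self):
        p = KineticParams(Km=1.0, kcat=0.03)
        assert morrison_velocity(0.0, 0.5, p) == 0.0

    def test_derived_value(self):
        p = KineticParams(Km=1.0, kcat=0.03)
        assert morrison_velocity(1.0, 0.5, p) == pytest.approx(0.006576707, rel=1e-6)

    def test_saturation_approaches_vmax(self):
        # near-constant rate at saturating substrate: v -> kcat * P_T
        p = KineticParams(Km=1.0, kcat=0.03)
        v = morrison_velocity(1100.0, 0.5, p)
        assert v == pytest.approx(0.01499, rel=1e-3)
        assert v < 0.03 * 0.5

    def test_strictly_increasing_in_substrate(self):
        p = KineticParams(Km=1.0, kcat=0.03)
        grid = np.geomspace(0.01, 1e4, 50)
        v = [morrison_velocity(n, 0.5, p) for n in grid]
        assert np.all(np.diff(v) > 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ln=st.floats(min_value=-1, max_value=4), lk=st.floats(min_value=-1, max_value=3))
    def test_dilute_enzyme_limit_is_michaelis_menten(self, ln, lk):
        N_T, Km = 10.0**ln, 10.0**lk
        P_T = 0.009 * (Km + N_T)  # below the 1% threshold P_T < 0.01 (Km+N_T)
        p = KineticParams(Km=Km, kcat=0.03)
        classic = 0.03 * P_T * N_T / (Km + N_T)
        assert morrison_velocity(N_T, P_T, p) == pytest.approx(classic, rel=0.01)


def fixed_point_competitive(N_T, P_T, O_T, Km, KdO, iters=2000):
    """Oracle: fixed-point iteration of the three coupled QSS relations
    under the ligand-excess approximation N ~ N_T."""
    O, P = O_T, 0.0
    for _ in range(iters):
        P = P_T / (1.0 + O / KdO + N_T / Km)
        O = O_T / (1.0 + P / KdO)
    return P


class TestFreeConcentrationsCompetitive:
    def test_no_competitor_reduces_to_simple_partition(self):
        N, O, P = free_concentrations_competitive(
            SpeciesTotals(N_T=50.0, P_T=0.25), Km=1.0, KdO=30.0
        )
        assert P == pytest.approx(0.25 / 51.0, rel=1e-9)  # P_T/(1+N_T/Km)
        assert O == 0.0

    def test_competitor_saturation_frees_no_enzyme(self):
        _, _, P = free_concentrations_competitive(
            SpeciesTotals(N_T=50.0, P_T=0.25, O_T=1e9), Km=1.0, KdO=30.0
        )
        assert P == pytest.approx(0.0, abs=1e-6)

    def test_matches_fixed_point_oracle(self):
        _, _, P = free_concentrations_competitive(
            SpeciesTotals(N_T=50.0, P_T=0.25, O_T=30.0), Km=1.0, KdO=30.0
        )
        want = fixed_point_competitive(50.0, 0.25, 30.0, 1.0, 30.0)
        assert P == pytest.approx(want, abs=1e-10)

    def test_free_enzyme_decreases_with_either_ligand(self):
        def P_of(N_T, O_T):
            return free_concentrations_competitive(
                SpeciesTotals(N_T=N_T, P_T=0.25, O_T=O_T), Km=1.0, KdO=30.0
            )[2]

        P_doses = [P_of(50.0, o) for o in (0, 10, 100, 1000, 10000)]
        assert np.all(np.diff(P_doses) < 0)
        P_lig = [P_of(n, 30.0) for n in (30, 50, 100, 500)]
        assert np.all(np.diff(P_lig) < 0)

    def test_ligand_excess_precondition_enforced(self):
        with pytest.raises(ValueError, match="N_T/P_T"):
            free_concentrations_competitive(
                SpeciesTotals(N_T=10.0, P_T=0.25), Km=1.0, KdO=30.0
            )


class TestTqssaFreePair:
    def test_sequestration_regime(self):
        N, P = tqssa_free_pair(1000.0, 250.0, 1.0)
        assert N == pytest.approx(750.0, rel=1e-2)
        assert P == pytest.approx(1.0 * 250.0 / N, rel=1e-2)  # Km*P_T/N

    def test_no_ligand(self):
        assert tqssa_free_pair(0.0, 250.0, 1.0) == (0.0, 250.0)

    def test_excess_enzyme_regime(self):
        N, P = tqssa_free_pair(125.0, 250.0, 1.0)
        assert P == pytest.approx(125.0, rel=0.01)  # about half desequestered

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ln=log_conc, lp=log_conc, lk=log_conc)
    def test_consistent_with_bound_complex_and_self_consistent(self, ln, lp, lk):
        N_T, P_T, Km = 10.0**ln, 10.0**lp, 10.0**lk
        N, P = tqssa_free_pair(N_T, P_T, Km)
        NP = bound_complex(N_T, P_T, Km)
        assert N == pytest.approx(N_T - NP, rel=1e-9, abs=1e-12)
        # both defining relations hold with the same complex
        assert N * (1.0 + P / Km) == pytest.approx(N_T, rel=1e-7, abs=1e-9)
        assert P * (1.0 + N / Km) == pytest.approx(P_T, rel=1e-7, abs=1e-9)

    def test_agrees_with_competitive_solver_in_excess_regime(self):
        # with no competitor the competitive solver's only approximation is
        # N ~ N_T, whose relative error is bounded by P_T/N_T: within 0.1%
        # at thousand-fold ligand excess, within 1% at the hundred-fold
        # precondition boundary.  tqssa_free_pair is the exact
        # equilibrium-binding (kcat=0) reference here.
        for N_T, P_T, Km in [(2000, 1.0, 0.47), (5000, 2.0, 10.0)]:
            _, _, P_approx = free_concentrations_competitive(
                SpeciesTotals(N_T=N_T, P_T=P_T), Km=Km, KdO=30.0
            )
            _, P_exact = tqssa_free_pair(N_T, P_T, Km)
            assert P_approx == pytest.approx(P_exact, rel=1e-3)
        for N_T, P_T, Km in [(50, 0.25, 1.0), (200, 2.0, 10.0)]:
            _, _, P_approx = free_concentrations_competitive(
                SpeciesTotals(N_T=N_T, P_T=P_T), Km=Km, KdO=30.0
            )
            _, P_exact = tqssa_free_pair(N_T, P_T, Km)
            assert P_approx == pytest.approx(P_exact, rel=P_T / N_T)
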