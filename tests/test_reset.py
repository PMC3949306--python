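"""Auto-reset model: control closed form, inhibited dynamics, lag, IC50."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tightbind.core import KineticParams, bound_complex
from tightbind.reset import (
    BEYOND_HORIZON,
    DoseResponseDataset,
    ResetConfig,
    control_release_curve,
    fit_dose_response,
    fit_reset,
    ic50_to_kd,
    lag_time,
    simulate_reset,
)
from tightbind.synth import NoiseModel, gen_reset_timecourses

T_GRID = np.linspace(1.0, 7200.0, 400)


def control_config(cfg: ResetConfig) -> ResetConfig:
    return replace(cfg, N_T0=0.0, deg_onset=0.0, inhibitor_mode="substrate", Kd_dead=None)


class TestControlReleaseCurve:
    def test_zero_at_time_zero(self, reset_config):
        assert control_release_curve(control_config(reset_config), 0.0) == 0.0

    def test_hand_evaluated_closed_form(self, reset_config):
        # rate0 = 0.52e-3 * 470 * 0.25 = 0.0611 nM/s; decay factor 543.8 s
        got = control_release_curve(control_config(reset_config), 600.0)
        assert got == pytest.approx(33.23, abs=0.02)

    def test_no_decay_limit_is_linear_and_bounds_from_above(self, reset_config):
        cfg = replace(control_config(reset_config), kdeg=0.0)
        got = control_release_curve(cfg, 600.0)
        assert got == pytest.approx(0.0611 * 600.0, rel=1e-3)
        assert got > control_release_curve(control_config(reset_config), 600.0)

    def test_requires_no_inhibitor(self, reset_config):
        with pytest.raises(ValueError, match="N_T0"):
            control_release_curve(reset_config, 600.0)


class TestSimulateReset:
    def test_without_inhibitor_matches_closed_form(self, reset_config):
        cfg = control_config(reset_config)
        traj = simulate_reset(cfg, T_GRID)
        want = control_release_curve(cfg, T_GRID)
        np.testing.assert_allclose(traj.released, want, rtol=1e-7)

    def test_inhibited_course_shows_lag_then_recovery(self, reset_config):
        traj = simulate_reset(reset_config, T_GRID)
        ctrl = simulate_reset(control_config(reset_config), T_GRID)
        lag = lag_time(traj, ctrl)
        assert 30.0 * 60 <= lag <= 40.0 * 60  # roughly 35 min
        # early rates suppressed, late rates approach (here exceed, because
        # decay starts later in the inhibited sample) the control's
        assert traj.rate[0] < 0.05 * ctrl.rate[0]
        assert traj.rate[-1] > 0.8 * ctrl.rate[-1]

    def test_dead_end_inhibitor_suppresses_throughout(self, reset_config):
        dead = replace(reset_config, inhibitor_mode="dead_end", Kd_dead=0.12)
        traj_dead = simulate_reset(dead, T_GRID)
        traj_sub = simulate_reset(reset_config, T_GRID)
        ctrl = simulate_reset(control_config(reset_config), T_GRID)
        # visual ordering of the three curves at every time point
        assert np.all(traj_dead.released <= traj_sub.released + 1e-9)
        assert np.all(traj_sub.released <= ctrl.released + 1e-9)
        assert lag_time(traj_dead, ctrl) == BEYOND_HORIZON

    def test_mass_balance_and_monotonicity(self, reset_config):
        traj = simulate_reset(reset_config, T_GRID)
        assert np.all(np.diff(traj.N_T) <= 1e-9)  # inhibitor only consumed
        assert traj.released[-1] <= reset_config.pC_T
        assert np.all(traj.released >= 0)

    def test_identical_trajectories_have_zero_lag(self, reset_config):
        ctrl = simulate_reset(control_config(reset_config), T_GRID)
        assert lag_time(ctrl, ctrl) == 0.0


class TestFitReset:
    def test_noiseless_two_stage_exact_recovery(self, reset_config):
        ctrl, inh, _ = gen_reset_timecourses(
            reset_config, noise=NoiseModel(cv=0.0, replicates=1, seed=0)
        )
        fit_ctrl, fit_inh = fit_reset(ctrl, inh, reset_config)
        assert fit_ctrl.estimates["eff_C"] == pytest.approx(0.52, rel=1e-6)
        assert fit_ctrl.estimates["kdeg"] == pytest.approx(0.020, rel=1e-6)
        assert fit_inh.estimates["Km"] == pytest.approx(0.47, rel=1e-4)
        assert fit_inh.estimates["kcat"] == pytest.approx(0.03, rel=1e-4)

    def test_noisy_recovery_within_experimental_error_scale(self, reset_config):
        ctrl, inh, _ = gen_reset_timecourses(
            reset_config, noise=NoiseModel(cv=0.05, replicates=3, seed=4)
        )
        # start from deliberately wrong guesses
        start = replace(reset_config, params_N=KineticParams(Km=1.0, kcat=0.01))
        _, fit_inh = fit_reset(ctrl, inh, start)
        assert abs(fit_inh.estimates["Km"] - 0.47) <= 0.14


class TestDoseResponse:
    @staticmethod
    def tight_dataset(Kd=0.12, P_T=0.125, S=5000.0, Km_S=85e3):
        Kd_app = Kd * (1 + S / Km_S)
        doses = np.array([0.0, 0.01, 0.03, 0.1, 0.2, 0.3, 0.5, 1.0, 3.0])
        act = np.array([1.0 - bound_complex(d, P_T, Kd_app) / P_T for d in doses])
        df = pd.DataFrame({"inhibitor_conc": doses, "activity_fraction": act})
        return DoseResponseDataset(data=df, P_T=P_T, S=S, Km_S=Km_S)

    def test_symmetric_logistic_recovers_midpoint_dose(self):
        doses = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 1e4])
        act = 1.0 / (1.0 + doses / 100.0)
        df = pd.DataFrame({"inhibitor_conc": doses, "activity_fraction": act})
        ds = DoseResponseDataset(data=df, P_T=1e-3, S=0.0, Km_S=1.0)
        fit = fit_dose_response(ds, model="logistic")
        assert fit.estimates["IC50"] == pytest.approx(100.0, rel=1e-4)

    def test_tight_binding_curve_yields_sub_nanomolar_ic50(self):
        fit = fit_dose_response(self.tight_dataset())
        # Kd 0.12 nM at these assay conditions gives IC50 ~ 0.19 nM
        assert fit.estimates["IC50"] == pytest.approx(0.19, abs=0.015)
        assert any("tight-binding" in n for n in fit.notes)

    def test_upper_plateau_recovered_from_zero_dose_points(self):
        fit = fit_dose_response(self.tight_dataset())
        assert fit.estimates["A0"] == pytest.approx(1.0, rel=1e-3)

    def test_ic50_round_trips_to_kd(self):
        fit = fit_dose_response(self.tight_dataset())
        kd = ic50_to_kd(fit.estimates["IC50"], 0.125, 5000.0, 85e3)
        assert kd == pytest.approx(0.12, rel=1e-2)


class TestIc50ToKd:
    def test_hand_evaluated_conversion(self):
        # 197 pM IC50 at 0.125 nM enzyme, 5 uM substrate, Km 85 uM
        kd = ic50_to_kd(0.197, 0.125, 5000.0, 85e3)
        assert kd == pytest.approx(0.127, abs=5e-4)

    def test_classic_limit_no_substrate_no_enzyme(self):
        assert ic50_to_kd(10.0, 1e-9, 0.0, 1.0) == pytest.approx(10.0, rel=1e-6)

    def test_titration_limit_unresolvable(self):
        with pytest.raises(ValueError, match="titration"):
            ic50_to_kd(0.0625, 0.125, 5000.0, 85e3)


class TestResetConfig:
    def test_dead_end_requires_kd(self, pendos_params):
        with pytest.raises(ValueError, match="Kd_dead"):
            ResetConfig(
                P_T0=0.25, N_T0=16.0, pC_T=470.0, params_N=pendos_params,
                eff_C=0.52, inhibitor_mode="dead_end",
            )
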