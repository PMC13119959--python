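"""Euler stepping, batch simulation, and trajectory bookkeeping."""

import math

import numpy as np
import pytest

from biobattery import (
    AnolyteState,
    ElectroParams,
    MicrobialParams,
    Mode,
    TerminationReason,
    TerminationSpec,
    euler_step,
    simulate_batch,
    summary_metrics,
)
from biobattery.engine import Trajectory


class TestEulerStep:
    def test_empty_state_fixed_point(self, mp, ep):
        s0 = AnolyteState(X=0, S=0, P_red=0, P_ox=0)
        for mode in Mode:
            s1 = euler_step(s0, 0.01, mp, ep, mode, j_charge=0.0)
            assert (s1.X, s1.S, s1.P_red, s1.P_ox) == (0, 0, 0, 0)
            assert s1.t == pytest.approx(0.01)

    def test_total_phenazine_conservation_one_step(self, ep):
        """With k_deg = 0 the Euler update adds exactly production*dt to P_tot."""
        mp = MicrobialParams(k_deg=1e-300)  # degradation off (field must be > 0)
        s0 = AnolyteState(X=0.5, S=10.0, P_red=0.003, P_ox=0.001)
        from biobattery import growth_rate, production_rate

        r = production_rate(growth_rate(s0, mp), s0.X, mp)
        s1 = euler_step(s0, 0.01, mp, ep, Mode.DISCHARGE)
        assert s1.P_tot - s0.P_tot == pytest.approx(r * 0.01, rel=1e-12)

    def test_recharge_moves_imposed_charge(self, ep):
        """One recharge step at the default charging current moves 3.73e-4 mmol/L."""
        mp = MicrobialParams(k_deg=1e-300)
        s0 = AnolyteState(X=0.1, S=5.0, P_red=0.0, P_ox=0.05)
        s1 = euler_step(s0, 0.01, mp, ep, Mode.RECHARGE, j_charge=0.02)
        assert s1.P_red == pytest.approx(0.00037311499196766336, rel=1e-10)
        assert s0.P_ox - s1.P_ox == pytest.approx(s1.P_red - s0.P_red, rel=1e-10)
        # biomass and substrate frozen during recharge
        assert (s1.X, s1.S) == (s0.X, s0.S)

    def test_recharge_flux_yields_to_empty_oxidized_pool(self, mp, ep):
        s0 = AnolyteState(X=0.1, S=5.0, P_red=0.0, P_ox=1e-6)
        s1 = euler_step(s0, 0.01, mp, ep, Mode.RECHARGE, j_charge=0.02)
        assert s1.P_ox >= 0.0
        assert s1.P_red <= s0.P_tot  # cannot create mediator

    def test_open_circuit_has_no_electrode_flux(self, mp, ep):
        s0 = AnolyteState(X=0.1, S=5.0, P_red=0.01, P_ox=0.0)
        s1 = euler_step(s0, 0.01, mp, ep, Mode.OPEN_CIRCUIT)
        assert s1.P_ox == pytest.approx(0.0)  # nothing oxidized

    def test_bad_dt_rejected_and_warned(self, mp, ep, caplog):
        with pytest.raises(ValueError):
            euler_step(AnolyteState(), 0.0, mp, ep)
        with caplog.at_level("WARNING"):
            euler_step(AnolyteState(), 0.2, mp, ep)
        assert any("exceeds the recommended" in r.message for r in caplog.records)


class TestSimulateBatch:
    def test_empty_reactor_flat_until_horizon(self, mp, ep):
        traj = simulate_batch(AnolyteState(X=0, S=0), mp, ep,
                              TerminationSpec(t_max=1.0), 0.01)
        assert traj.termination_reason is TerminationReason.MAX_TIME
        assert np.all(traj.X == 0) and np.all(traj.j == 0)
        assert traj.t[-1] == pytest.approx(1.0)

    def test_baseline_monotone_structure(self, mp, ep, init):
        """No death term: X never decreases; no feeding: S never increases."""
        traj = simulate_batch(init, mp, ep, TerminationSpec(t_max=50.0), 0.01)
        assert np.all(np.diff(traj.X) >= 0)
        assert np.all(np.diff(traj.S) <= 0)
        assert np.all(np.diff(traj.t) > 0)

    def test_toxicity_stop_final_state_satisfies_trigger(self, ep, init):
        mp = MicrobialParams(alpha_P=0.3)
        term = TerminationSpec(t_max=200.0, P_tox_stop=0.02)
        traj = simulate_batch(init.replace(X=0.5), mp, ep, term, 0.01)
        assert traj.termination_reason is TerminationReason.TOXICITY
        assert traj.P_tot[-1] > 0.02
        assert np.all(traj.P_tot[:-1] <= 0.02)

    def test_substrate_floor_stop(self, mp, ep):
        term = TerminationSpec(t_max=200.0, S_floor=1.0)
        traj = simulate_batch(AnolyteState(X=0.5, S=20.0), mp, ep, term, 0.01)
        assert traj.termination_reason is TerminationReason.SUBSTRATE_FLOOR
        assert traj.S[-1] < 1.0

    def test_fine_step_oracle_agreement(self, mp, ep, init):
        """dt = 0.01 h matches a 10x finer run within 1% at t = 50 h."""
        term = TerminationSpec(t_max=50.0)
        coarse = simulate_batch(init, mp, ep, term, 0.01)
        fine = simulate_batch(init, mp, ep, term, 0.001)
        for name in ("X", "S", "P_red", "P_ox"):
            a = getattr(coarse, name)[-1]
            b = getattr(fine, name)[-1]
            scale = max(abs(b), 1e-6 * init.S)  # relative where meaningful
            assert abs(a - b) / scale < 0.01, name

    def test_richardson_terminal_state(self, mp, ep, init):
        """Halving dt changes the terminal state by < 0.5%."""
        term = TerminationSpec(t_max=50.0)
        t1 = simulate_batch(init, mp, ep, term, 0.01)
        t2 = simulate_batch(init, mp, ep, term, 0.005)
        for name in ("X", "S", "P_red", "P_ox"):
            a, b = getattr(t1, name)[-1], getattr(t2, name)[-1]
            assert abs(a - b) <= 0.005 * max(abs(b), 1e-6 * init.S), name

    def test_clamping_never_masks_dynamics(self, mp, ep, init):
        traj = simulate_batch(init, mp, ep, TerminationSpec(t_max=200.0), 0.01)
        assert traj.max_clamp_magnitude < 1e-6

    def test_charge_bookkeeping_matches_flux_integral(self, mp, ep, init):
        """Cumulative charge equals the converted trapezoidal flux integral."""
        traj = simulate_batch(init, mp, ep, TerminationSpec(t_max=20.0), 0.01)
        expected = ep.flux_to_j * np.trapezoid(traj.v_elec, traj.t)
        assert traj.cumulative_charge[-1] == pytest.approx(expected, rel=1e-9)
        assert np.all(np.diff(traj.cumulative_charge) >= 0)

    def test_luedeking_piret_closed_form(self, ep, init):
        """Toxicity off, degradation ~0: P_tot(t) = alpha*(X - X0) + beta*int X dt."""
        mp = MicrobialParams(K_inh=1e9, k_deg=1e-300, beta_P=0.001)
        traj = simulate_batch(init, mp, ep, TerminationSpec(t_max=10.0), 0.005)
        integral_X = np.concatenate(
            ([0.0], np.cumsum(0.5 * (traj.X[1:] + traj.X[:-1]) * np.diff(traj.t))))
        expected = mp.alpha_P * (traj.X - traj.X[0]) + mp.beta_P * integral_X
        assert traj.P_tot[-1] == pytest.approx(expected[-1], rel=5e-3)

    def test_trajectory_dataframe_schema(self, mp, ep, init, tmp_path):
        traj = simulate_batch(init, mp, ep, TerminationSpec(t_max=1.0), 0.01)
        df = traj.to_dataframe()
        assert list(df.columns) == [
            "t", "X", "S", "P_red", "P_ox", "P_tot", "v_elec",
            "j_A_m2", "j_mA_cm2", "E_an", "E_oc", "V_cell", "cumulative_charge",
        ]
        out = tmp_path / "traj.csv"
        traj.write_csv(out)
        assert out.exists() and out.with_suffix(".meta.json").exists()


class TestSummaryMetrics:
    def _traj(self, t, j):
        t = np.asarray(t, dtype=float)
        j = np.asarray(j, dtype=float)
        z = np.zeros_like(t)
        q = np.concatenate(([0.0], np.cumsum(0.5 * (j[1:] + j[:-1]) * np.diff(t))))
        return Trajectory(t=t, X=z, S=z, P_red=z, P_ox=z, v_elec=z, j=j,
                          E_an=z, E_oc=z, V_cell=z, cumulative_charge=q,
                          termination_reason=TerminationReason.MAX_TIME)

    def test_constant_current(self):
        m = summary_metrics(self._traj([0, 1, 2], [0.01, 0.01, 0.01]))
        assert m.avg_j == pytest.approx(0.01)
        assert m.cumulative_charge == pytest.approx(0.02)
        assert m.peak_j == pytest.approx(0.01)
        assert m.duration == pytest.approx(2.0)

    def test_zero_current(self):
        m = summary_metrics(self._traj([0, 1], [0.0, 0.0]))
        assert m.avg_j == m.peak_j == m.cumulative_charge == 0.0

    def test_triangular_profile(self):
        t = np.linspace(0, 10, 101)
        j = 0.1 * t / 10
        m = summary_metrics(self._traj(t, j))
        assert m.avg_j == pytest.approx(0.05, rel=1e-9)
        assert m.peak_j == pytest.approx(0.1)
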