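"""Kinase-model dynamics: signal pulse, conservation, regimes, interventions."""

import numpy as np
import pytest

import bsignal as b
from bsignal.model_a_kinase import SimulationError

from .oracles import rk4_kinase
from .conftest import KINASE_GRID, REGIMES


class TestSignalInput:
    def test_zero_at_time_zero(self):
        sp = b.SignalParams(amplitude=2.0, rise_rate=0.1, decay_rate=0.01)
        assert b.signal_input(0.0, sp) == 0.0

    def test_peak_time_matches_closed_form(self):
        # argmax of A(e^{-at} - e^{-bt}) is ln(b/a)/(b-a) ~ 25.58 min
        sp = b.SignalParams(amplitude=1.0, rise_rate=0.1, decay_rate=0.01)
        assert sp.peak_time == pytest.approx(np.log(10.0) / 0.09)
        t = np.linspace(0, 120, 120001)
        s = b.signal_input(t, sp)
        assert t[np.argmax(s)] == pytest.approx(25.58, abs=0.01)

    def test_zero_decay_rises_monotonically_to_amplitude(self):
        sp = b.SignalParams(amplitude=1.5, rise_rate=0.2, decay_rate=0.0)
        t = np.linspace(0, 60, 601)
        s = b.signal_input(t, sp)
        assert np.all(np.diff(s) > 0)
        assert b.signal_input(400.0, sp) == pytest.approx(1.5, rel=1e-4)

    def test_rise_not_exceeding_decay_rejected(self):
        with pytest.raises(ValueError, match="rise_rate"):
            b.SignalParams(rise_rate=0.01, decay_rate=0.1)


class TestSimulate:
    def test_no_signal_input_stays_at_zero(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        from dataclasses import replace

        params = replace(p0, k1=0.0, k4=0.0)
        traj = b.simulate(params, pf=pf, nf=nf, regime="full")
        assert np.all(traj.active == 0.0)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_conservation_all_regimes(self, p0, feedback_inputs, regime):
        pf, nf = feedback_inputs
        traj = b.simulate(p0, pf=pf, nf=nf, regime=regime)
        assert traj.conservation_error() < 1e-8

    def test_unknown_regime_names_valid_ones(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        with pytest.raises(ValueError, match="no_positive"):
            b.simulate(p0, pf=pf, nf=nf, regime="knockout")

    def test_full_with_zeroed_feedback_equals_no_feedback_bitwise(self, p0, feedback_inputs):
        from dataclasses import replace

        pf, nf = feedback_inputs
        params = replace(p0, k4=0.0, k5=0.0)
        a = b.simulate(params, pf=pf, nf=nf, regime="full")
        c = b.simulate(params, pf=pf, nf=nf, regime="no_feedback")
        assert np.array_equal(a.active, c.active)
        assert np.array_equal(a.inactive, c.inactive)

    @pytest.mark.parametrize("regime,k4,k5", [("full", None, None), ("no_positive", 0.0, None), ("no_feedback", 0.0, 0.0)])
    def test_matches_fine_step_rk4_oracle(self, p0, feedback_inputs, regime, k4, k5):
        pf, nf = feedback_inputs
        traj = b.simulate(p0, pf=pf, nf=nf, regime=regime, t_eval=KINASE_GRID)
        times, active = rk4_kinase(p0, pf, nf, dt=0.001, k4=k4, k5=k5)
        oracle = np.interp(KINASE_GRID, times, active)
        assert np.max(np.abs(traj.active - oracle)) < 1e-4

    def test_positive_feedback_only_adds_activation(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        full = b.simulate(p0, pf=pf, nf=nf, regime="full")
        nopos = b.simulate(p0, pf=pf, nf=nf, regime="no_positive")
        assert np.all(full.active >= nopos.active - 1e-9)

    def test_intervention_at_zero_equals_no_positive_regime(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        sched = b.InterventionSchedule(events=((0.0, "k4", 0.0),))
        a = b.simulate(p0, pf=pf, nf=nf, regime="full", schedule=sched)
        c = b.simulate(p0, pf=pf, nf=nf, regime="no_positive")
        assert np.array_equal(a.active, c.active)

    def test_mid_course_inhibitor_branches_from_full(self, p0, feedback_inputs):
        """IAP inhibitor at 10 min: identical to full before, between the
        knockout and full trajectories afterwards."""
        pf, nf = feedback_inputs
        grid = np.arange(0.0, 121.0, 1.0)
        sched = b.InterventionSchedule(events=((10.0, "k4", 0.0),))
        mid = b.simulate(p0, pf=pf, nf=nf, regime="full", schedule=sched, t_eval=grid)
        full = b.simulate(p0, pf=pf, nf=nf, regime="full", t_eval=grid)
        nopos = b.simulate(p0, pf=pf, nf=nf, regime="no_positive", t_eval=grid)
        pre = grid <= 10.0
        assert np.allclose(mid.active[pre], full.active[pre], atol=1e-7)
        # comparisons at solver-tolerance resolution: the branches differ by
        # only ~1e-5 where PF is still small
        post = grid > 20.0
        assert np.all(mid.active[post] <= full.active[post] + 1e-6)
        assert np.all(mid.active[post] >= nopos.active[post] - 1e-6)

    def test_schedule_requires_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            b.InterventionSchedule(events=((10.0, "k4", 0.0), (10.0, "k5", 0.0)))

    def test_event_outside_window_rejected(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        sched = b.InterventionSchedule(events=((150.0, "k4", 0.0),))
        with pytest.raises(ValueError, match="window"):
            b.simulate(p0, pf=pf, nf=nf, schedule=sched)


class TestDurationMetrics:
    def test_constant_trajectory(self):
        t = np.linspace(0, 80, 81)
        traj = b.KinaseTrajectory(times=t, active=np.full(81, 0.4), inactive=np.full(81, 0.6), total=1.0)
        m = b.duration_metrics(traj)
        assert m["t_half_duration"] == pytest.approx(80.0)
        assert m["auc"] == pytest.approx(0.4 * 80)
        assert m["peak"] == pytest.approx(0.4)

    def test_symmetric_triangle_half_base(self):
        t = np.linspace(0, 100, 201)
        x = np.where(t <= 50, t / 50, (100 - t) / 50)
        traj = b.KinaseTrajectory(times=t, active=x, inactive=1 - x, total=1.0)
        m = b.duration_metrics(traj)
        assert m["t_half_duration"] == pytest.approx(50.0)
        assert m["peak_time"] == pytest.approx(50.0)

    def test_all_zero_convention(self):
        t = np.linspace(0, 10, 11)
        traj = b.KinaseTrajectory(times=t, active=np.zeros(11), inactive=np.ones(11), total=1.0)
        m = b.duration_metrics(traj)
        assert m == {"peak": 0.0, "peak_time": 0.0, "t_half_duration": 0.0, "auc": 0.0}

    def test_positive_feedback_lengthens_duration(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        full = b.duration_metrics(b.simulate(p0, pf=pf, nf=nf, regime="full"))
        nopos = b.duration_metrics(b.simulate(p0, pf=pf, nf=nf, regime="no_positive"))
        assert full["t_half_duration"] >= nopos["t_half_duration"]
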