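"""Cycle detection, frequency locking, sweeps and phase portraits."""

import numpy as np
import pytest

import lymphangion as ly
from lymphangion.analysis import _snap_ratio


def _synthetic_trajectory(signal, t, params):
    """Wrap a plain signal as a radius trajectory (no events)."""
    R1 = 1e-4
    return ly.Trajectory(
        t=t, R=R1 + signal, dRdt=np.gradient(signal, t),
        C_Ca=np.full_like(t, params.C_Ca0), C_NO=np.zeros_like(t),
        events=[], params=params, mode="no_only", seed=0,
        dt=t[1] - t[0], stride=1, meta={"R1": R1})


class TestDetectCycles:
    def test_sawtooth_known_period(self, params):
        t = np.arange(0.0, 60.0, 0.01)
        saw = 1e-5 * ((t % 5.0) / 5.0)
        traj = _synthetic_trajectory(saw, t, params)
        stats = ly.detect_cycles(traj, "radius")
        assert stats.defined
        assert np.allclose(stats.periods, 5.0, atol=1e-9)
        assert stats.mean_period == pytest.approx(5.0, abs=1e-9)

    def test_undefined_below_two_cycles(self, params):
        t = np.arange(0.0, 10.0, 0.01)
        traj = _synthetic_trajectory(np.zeros_like(t), t, params)
        stats = ly.detect_cycles(traj, "radius")
        assert not stats.defined
        assert stats.mean_period != stats.mean_period  # NaN

    def test_pressure_raises_frequency_and_lowers_amplitude(self, params, params500):
        """Stiffer wall at higher pressure: shorter contraction intervals and
        smaller radius excursions at equal noise."""
        lo = ly.simulate(params.replace(sigma_Ca=0.01), "ca_only",
                         duration=150.0, seed=19)
        hi = ly.simulate(params500.replace(sigma_Ca=0.01), "ca_only",
                         duration=150.0, seed=19)
        s_lo = ly.detect_cycles(lo, "radius")
        s_hi = ly.detect_cycles(hi, "radius")
        assert s_hi.mean_period < s_lo.mean_period
        assert np.mean(s_hi.amplitudes) < np.mean(s_lo.amplitudes)


class TestSnapRatio:
    @pytest.mark.parametrize("ratio,expect", [
        (0.5, (1, 2)),
        (2.003, (2, 1)),
        (1.0, (1, 1)),
        (0.334, (1, 3)),
        (1.497, (3, 2)),
        (0.54, None),
        (3.2, (16, 5)),
    ])
    def test_examples(self, ratio, expect):
        got = _snap_ratio(ratio)
        if expect is None:
            assert got is None
        else:
            assert got[:2] == expect

    def test_reduces_fractions(self):
        assert _snap_ratio(0.5)[:2] == (1, 2)   # not 2:4 or 4:8


class TestLockingCa:
    def test_one_to_one_near_autonomous(self, params500):
        spec = ly.ForcingSpec("calcium", "sinusoid", 0.01, 0.12)
        traj = ly.simulate(params500.replace(dt=1e-3), "ca_only", (spec,),
                           duration=400.0, seed=31)
        lr = ly.locking_ratio(traj, spec)
        assert lr.locked and (lr.ratio_m, lr.ratio_n) == (1, 1)

    def test_half_locking_above_autonomous(self, params500):
        spec = ly.ForcingSpec("calcium", "sinusoid", 0.01, 0.3)
        traj = ly.simulate(params500.replace(dt=1e-3), "ca_only", (spec,),
                           duration=400.0, seed=31)
        lr = ly.locking_ratio(traj, spec)
        assert lr.locked and (lr.ratio_m, lr.ratio_n) == (1, 2)

    def test_unlocked_without_cycles(self, params500):
        spec = ly.ForcingSpec("calcium", "sinusoid", 0.01, 0.1)
        p = params500.replace(sigma_Ca=0.0, sigma_NO=0.0)
        traj = ly.simulate(p, "ca_only", (spec,), duration=30.0, seed=0,
                           trigger=False)
        lr = ly.locking_ratio(traj, spec)
        assert not lr.locked and lr.output_frequency == 0.0

    def test_requires_sinusoid(self, params500):
        traj = ly.simulate(params500, "ca_only", duration=10.0, seed=0)
        with pytest.raises(ValueError):
            ly.locking_ratio(traj, ly.ForcingSpec("calcium", "none"))


class TestArnoldSweep:
    def test_grid_shape_ratios_and_zero_amplitude(self, params):
        p = params.replace(dt=1e-3)
        freqs = [0.03, 0.05]
        amps = [0.0, 0.01]
        results = ly.arnold_sweep(p, "no_only", freqs, amps, seed=2,
                                  duration=200.0)
        assert len(results) == 2 and len(results[0]) == 2
        for r in results[0]:         # zero-amplitude row: nothing locks
            assert not r.locked
        for row in results:
            for r in row:
                if r.locked:
                    assert 1 <= r.ratio_n <= 8
        frame = ly.sweep_frame(p, "no_only", results, c_max=0.5)
        assert {"frequency", "amplitude", "ratio_m", "ratio_n", "locked",
                "f_autonomous"} <= set(frame.columns)
        # autonomous estimate 1/(t_c ln(C_max/amplitude))
        eq = ly.equilibrium_radius(p)
        tc = ly.time_constants(eq, p)
        expect = 1.0 / (tc.t_c_no * np.log(0.5 / 0.01))
        got = frame.loc[frame.amplitude == 0.01, "f_autonomous"].iloc[0]
        assert got == pytest.approx(expect, rel=1e-9)

    def test_tongue_nestedness(self, params):
        """The 1:1-locked frequency set widens with forcing amplitude."""
        p = params.replace(dt=1e-3)
        freqs = [0.025, 0.03, 0.04, 0.045, 0.05]
        locked = {}
        for amp in (0.005, 0.01, 0.02):
            cells = set()
            for f in freqs:
                spec = ly.ForcingSpec("nitric_oxide", "sinusoid", amp, f)
                traj = ly.simulate(p, "no_only", (spec,), duration=500.0,
                                   seed=61)
                lr = ly.locking_ratio(traj, spec)
                if lr.locked and (lr.ratio_m, lr.ratio_n) == (1, 1):
                    cells.add(f)
            locked[amp] = cells
        assert locked[0.005] <= locked[0.01] <= locked[0.02]
        assert len(locked[0.02]) > len(locked[0.005])


class TestPhasePortrait:
    def test_equilibrium_collapses_to_point(self, params500):
        p = params500.replace(sigma_Ca=0.0, sigma_NO=0.0)
        traj = ly.simulate(p, "coupled", duration=5.0, seed=0)
        x, y = ly.phase_portrait(traj, ("R", "dRdt"))
        assert np.ptp(x) < 1e-12 and np.ptp(y) < 1e-12

    def test_single_contraction_closed_loop(self, params, eq100):
        t = np.linspace(0.0, 20.0, 20001)
        w = ly.contraction_waveform(t, eq100, params)
        traj = _synthetic_trajectory(w, t, params)
        x, y = ly.phase_portrait(traj, ("R", "dRdt"))
        dR = x - 1e-4    # baseline radius of the synthetic trajectory
        # loop starts at dR = 0, returns to (0, 0), and encloses area
        assert abs(dR[0]) < 1e-15
        assert abs(dR[-1]) < 1e-3 * np.max(np.abs(dR))
        assert abs(y[-1]) < 1e-3 * np.max(np.abs(y))
        area = abs(0.5 * np.sum(dR[:-1] * y[1:] - dR[1:] * y[:-1]))
        assert area > 0.05 * np.max(np.abs(dR)) * np.max(np.abs(y))

    def test_cycles_retrace(self, params):
        """Successive noise-triggered contractions trace nearly identical
        loops in phase space."""
        traj = ly.simulate(params.replace(sigma_Ca=0.01), "ca_only",
                           duration=120.0, seed=7)
        ev = traj.event_times()
        h = traj.t[1] - traj.t[0]
        n_win = int(round(4.0 / h))
        gaps = np.diff(ev)
        loops = []
        for k, te in enumerate(ev[:-1]):
            i0 = int(round(te / h))
            # only windows not contaminated by the next contraction
            if i0 + n_win < traj.t.size and gaps[k] > 4.5:
                loops.append(traj.R[i0:i0 + n_win])
        loops = np.asarray(loops[:6])
        assert len(loops) >= 3
        diam = np.ptp(loops)
        worst = max(np.max(np.abs(loops[i + 1] - loops[i]))
                    for i in range(len(loops) - 1))
        assert worst < 0.05 * diam

    def test_chirality(self, params):
        """Stretch-Ca cycles run clockwise, shear-NO cycles counterclockwise
        in the (concentration, radius) plane (closed-loop signed area)."""
        p = params.replace(sigma_Ca=0.0, sigma_NO=0.0)
        eq = ly.equilibrium_radius(p)

        def closed_area(x, y):
            return 0.5 * (np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
                          + x[-1] * y[0] - x[0] * y[-1])

        ca0 = ly.SystemState(0.0, eq.R1, 0.0, p.S_Ca1, 0.0, True)
        ca = ly.simulate(p, "ca_only", duration=15.0, seed=0, initial_state=ca0)
        assert closed_area(ca.C_Ca, ca.R) < 0

        no0 = ly.SystemState(0.0, eq.R1, 0.0, 0.0, 0.05, False)
        no = ly.simulate(p, "no_only", duration=40.0, seed=0, initial_state=no0)
        assert closed_area(no.C_NO, no.R) > 0

    def test_rejects_unknown_axes(self, params500):
        traj = ly.simulate(params500, "coupled", duration=1.0, seed=0)
        with pytest.raises(ValueError):
            ly.phase_portrait(traj, ("R", "C_Ca"))


def test_period_law_slope_recovers_time_constant():
    sigmas = np.array([0.003, 0.01, 0.03])
    t_c, c_max = 1.7, 0.85
    periods = t_c * np.log(c_max / sigmas) + 0.4   # constant offset allowed
    got = ly.period_law_slope(sigmas, periods, [c_max] * 3)
    assert got == pytest.approx(t_c, rel=1e-9)
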