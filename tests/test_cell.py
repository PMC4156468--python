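"""Protocol handling, solver self-consistency and VIP-step observables."""

import numpy as np
import pytest

from fofr import (CellParameters, InternalizationStats, Protocol,
                  ProtocolSegment, internalization_metrics, run_vip_step,
                  simulate_cell)
from fofr.cell import CellTrajectory, basal_state
from fofr.species import IDX


class TestProtocol:
    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            ProtocolSegment(0.0)

    def test_rejects_negative_clamp(self):
        with pytest.raises(ValueError):
            ProtocolSegment(10.0, vip_clamp=-1.0)

    def test_duration_sums_segments(self):
        p = Protocol.vip_step(10.0, 100.0, 200.0)
        assert p.duration == 300.0


def test_clamp_events_honored_exactly(params):
    """Sensed VIP equals the clamp value during each segment, switching at
    the segment boundary."""
    proto = Protocol((ProtocolSegment(600.0, vip_clamp=5.0,
                                      secretion_on=False),
                      ProtocolSegment(600.0, vip_clamp=0.0,
                                      secretion_on=False)))
    traj = simulate_cell(params, proto, dt_out=10.0)
    L = traj.species("L")
    on = traj.t < 600.0
    assert np.all(L[on] == 5.0)
    assert np.all(np.abs(L[traj.t > 600.0]) < 1e-12)


def test_trajectory_nonnegative_and_bounded(free_run_8h):
    assert free_run_8h.y.min() >= 0.0
    sf = free_run_8h.surface_fraction
    assert sf.min() >= 0.0 and sf.max() <= 1.0 + 1e-9
    assert free_run_8h.firing_rate.min() >= 0.0


def test_solver_self_consistency_across_tolerances(params):
    """Halving the integration tolerances changes the final state by
    < 0.1% relative (on species above absolute tolerance scale)."""
    proto = Protocol.vip_step(100.0, 1800.0, 1800.0)
    a = simulate_cell(params, proto, rtol=1e-6, atol=1e-9).y[-1]
    b = simulate_cell(params, proto, rtol=5e-7, atol=5e-10).y[-1]
    mask = np.abs(a) > 1e-3
    rel = np.abs(a[mask] - b[mask]) / np.abs(a[mask])
    assert rel.max() < 1e-3


def test_default_cell_fofr_period_in_observed_band(free_run_8h):
    """The default cell free-runs with firing-rate oscillations whose
    period lies in the experimentally observed 20-60 min band."""
    from fofr.analysis import estimate_period_amplitude
    per, amp = estimate_period_amplitude(free_run_8h.t,
                                         free_run_8h.firing_rate,
                                         transient=2.5 * 3600.0)
    assert 20.0 <= per <= 60.0
    assert amp > 1.0
    assert free_run_8h.firing_rate[int(2.5 * 360):].min() < 0.05


def test_severed_loop_never_fires(params):
    p = params.replace(g_CNG0=0.0)
    traj = simulate_cell(p, Protocol.free_running(4 * 3600.0), dt_out=30.0)
    assert np.all(traj.firing_rate == 0.0)


class TestVipStep:
    def test_rejects_negative_concentration(self, params):
        with pytest.raises(ValueError):
            run_vip_step(params, -1.0, 100.0, 100.0)

    def test_zero_step_triggers_no_trafficking(self, params):
        """A 0-nM 'step' moves no receptors: the surface fraction stays
        at its resting value and cAMP only relaxes toward its VIP-free
        level (no stimulated response)."""
        traj = run_vip_step(params, 0.0, 1800.0, 600.0, dt_out=30.0)
        camp = traj.species("cAMP")
        assert camp.max() <= camp[0] * (1 + 1e-6)   # nothing is stimulated
        sf = traj.surface_fraction
        assert sf.min() > 0.99 * sf[0]

    def test_overshoot_grows_with_concentration(self, params):
        """The adaptive decline after the cAMP peak (PDE activation plus
        receptor internalization) deepens with VIP concentration: low
        concentrations give a near-plateau response, high concentrations a
        pronounced transient peak."""
        ratios = []
        for conc in (0.1, 10.0, 1000.0):
            traj = run_vip_step(params, conc, 1800.0, 60.0, dt_out=10.0)
            camp = traj.species("cAMP")[traj.t <= 1800.0]
            ratios.append(camp[-1] / camp.max())   # plateau / peak
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[0] > 0.7

    def test_high_vip_camp_peaks_then_declines(self, params):
        """Above ~1 nM cAMP shows a transient peak within 5-10 min of
        onset followed by a decline to a lower plateau."""
        traj = run_vip_step(params, 1000.0, 1800.0, 60.0, dt_out=5.0)
        sel = traj.t <= 1800.0
        camp = traj.species("cAMP")[sel]
        ipk = int(np.argmax(camp))
        t_peak_min = traj.t[sel][ipk] / 60.0
        assert t_peak_min <= 10.0           # early transient peak
        assert camp[-1] < 0.5 * camp[ipk]   # pronounced adaptive decline

    def test_washout_returns_camp_below_basal(self, vip_step_1um, basal):
        """After washout (sensed VIP clamped to zero) cAMP falls back
        below its VIP_0-maintained resting value."""
        camp = vip_step_1um.species("cAMP")
        assert camp[-1] < basal[IDX["cAMP"]]
        assert camp[-1] < 0.05 * camp.max()


class TestInternalizationMetrics:
    def test_synthetic_two_exponential_oracle(self, params):
        """On a synthesized surface-fraction trace with known kinetics the
        metrics reproduce the analytic half-times."""
        t = np.arange(0.0, 1800.0 + 3600.0, 1.0)
        k_in, k_out = np.log(2) / 240.0, np.log(2) / 1200.0
        s_min = 0.25
        step = t <= 1800.0
        s = np.where(step, s_min + (1 - s_min) * np.exp(-k_in * t),
                     1.0 + (s_min + (1 - s_min) * np.exp(-k_in * 1800.0)
                            - 1.0) * np.exp(-k_out * (t - 1800.0)))
        traj = _fake_traj(t, s, params)
        st = internalization_metrics(traj, (0.0, 1800.0))
        assert st.defined
        assert st.half_time_min == pytest.approx(4.0, abs=0.1)
        assert st.max_internalization_pct == pytest.approx(75.0, abs=0.5)
        assert st.recovery_half_time_min == pytest.approx(20.0, abs=0.5)

    def test_no_stimulus_flags_undefined(self, params):
        traj = run_vip_step(params, 0.0, 1800.0, 1800.0, dt_out=30.0)
        st = internalization_metrics(traj, (0.0, 1800.0))
        assert not st.defined
        assert np.isnan(st.half_time_min)

    def test_1um_step_metrics_defined(self, vip_step_1um):
        st = internalization_metrics(vip_step_1um, (0.0, 1800.0))
        assert st.defined
        assert st.half_time_min > 0
        assert 0 < st.max_internalization_pct < 100
        assert st.recovery_half_time_min > 0


def _fake_traj(t, surface_fraction, params):
    """CellTrajectory whose receptor pools realize a given surface-fraction
    series (all other species at rest)."""
    y = np.zeros((t.size, 47))
    y[:, IDX["R"]] = 300.0 * surface_fraction
    y[:, IDX["Rint"]] = 300.0 * (1.0 - surface_fraction)
    return CellTrajectory(t, y, params)
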