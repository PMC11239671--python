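"""Generator correctness: exact CTMC sampling, rendering, noise models."""

import numpy as np
import pytest

from channelphys import synthgen
from channelphys.synthgen import (
    GatingModel,
    VoltageProtocol,
    default_gating_model,
    gen_dose_response,
    gen_energy_traces,
    gen_lipid_frames,
    gen_ph_traces,
    hill_response,
    render_trace,
    simulate_gating,
    two_state_model,
)


class TestGatingModel:
    def test_closed_state_conductance_must_be_zero(self):
        with pytest.raises(ValueError, match="closed-state conductance"):
            GatingModel(("closed", "open"), (1.0, 60.0),
                        lambda v: np.array([[-1.0, 1.0], [1.0, -1.0]]))

    def test_invalid_rate_matrix_rejected(self):
        bad_offdiag = two_state_model(10, 10)
        object.__setattr__(bad_offdiag, "rates",
                           lambda v: np.array([[1.0, -1.0], [1.0, -1.0]]))
        with pytest.raises(ValueError, match="off-diagonal"):
            bad_offdiag.rate_matrix(0.0)
        rows_not_zero = two_state_model(10, 10)
        object.__setattr__(rows_not_zero, "rates",
                           lambda v: np.array([[-1.0, 2.0], [1.0, -1.0]]))
        with pytest.raises(ValueError, match="sum to zero"):
            rows_not_zero.rate_matrix(0.0)

    def test_default_model_pins_stationary_po(self):
        m = default_gating_model()
        assert m.stationary_po(0.0) == pytest.approx(0.0, abs=1e-12)
        assert m.stationary_po(90.0) == pytest.approx(0.6, abs=1e-12)
        assert m.stationary_po(-150.0) == pytest.approx(0.3, abs=1e-12)

    def test_step_protocol_default_family(self):
        p = VoltageProtocol()
        assert p.levels_mV[0] == 90.0 and p.levels_mV[-1] == -150.0
        assert np.allclose(np.diff(p.levels_mV), -30.0)


class TestSimulateGating:
    def test_absorbing_closed_state_spans_duration(self):
        m = default_gating_model()
        ev = simulate_gating(m, 0.0, 5000.0, seed=0)
        assert ev.events == [("closed", 5000.0)]

    def test_fixed_seed_reproducible(self, flicker_model):
        a = simulate_gating(flicker_model, 90.0, 2000.0, seed=42)
        b = simulate_gating(flicker_model, 90.0, 2000.0, seed=42)
        assert a.events == b.events

    def test_long_run_open_fraction_matches_stationary(self, flicker_model):
        # two-state chain: stationary open fraction = 26 / (26 + 41)
        duration = 3_000_000.0  # ~90k events
        ev = simulate_gating(flicker_model, 90.0, duration, seed=7)
        assert ev.n_events > 10_000
        po = ev.time_in(("open",)) / duration
        expected = 26.0 / (26.0 + 41.0)
        # renewal-process standard error of the time-average open fraction
        n_cyc = ev.n_events / 2
        se = np.sqrt(2 * expected**2 * (1 - expected)**2 * 67.0 / duration)
        assert abs(po - expected) < 3 * max(se, 1.0 / n_cyc)

    def test_mean_dwell_equals_inverse_exit_rate(self, flicker_model):
        ev = simulate_gating(flicker_model, 90.0, 1_000_000.0, seed=3)
        for label, tau in (("open", 26.0), ("closed", 41.0)):
            d = ev.durations(label)[:-1]  # drop possibly truncated last event
            assert abs(d.mean() - tau) < 3 * tau / np.sqrt(len(d))

    def test_adjacent_events_distinct_and_durations_sum(self, flicker_model):
        ev = simulate_gating(flicker_model, 90.0, 10_000.0, seed=1)
        states = [s for s, _ in ev.events]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert sum(d for _, d in ev.events) == pytest.approx(ev.total_ms)


class TestRenderTrace:
    def test_open_level_is_ohmic(self, flicker_model):
        ev = simulate_gating(flicker_model, 90.0, 1000.0, seed=0)
        tr = render_trace(ev, flicker_model, 90.0, noise_sd_pA=0.0)
        # g = 60 pS at +90 mV, Erev 0 -> 5.4 pA open level
        assert set(np.round(np.unique(tr.i_pA), 9)) <= {0.0, 5.4}
        if ev.time_in(("open",)) > 0:
            assert 5.4 in np.round(np.unique(tr.i_pA), 9)

    def test_noise_free_level_set_equals_events(self, flicker_model):
        # piecewise-constant trace: each sample carries exactly the
        # current of the event active at its time point
        ev = simulate_gating(flicker_model, 90.0, 2000.0, seed=5)
        tr = render_trace(ev, flicker_model, 90.0, 0.0, sampling_khz=10.0)
        expected = np.zeros(len(tr.t_ms))
        t0 = 0.0
        for s, d in ev.events:
            if s == "open":
                expected[(tr.t_ms >= t0) & (tr.t_ms < t0 + d)] = 5.4
            t0 += d
        assert np.array_equal(tr.i_pA, expected)
        assert set(np.unique(tr.i_pA)) <= {0.0, 5.4}

    def test_noise_sd_recovered(self, flicker_model):
        ev = simulate_gating(flicker_model, 0.0, 2000.0, seed=0,
                             start_state=0)
        tr = render_trace(ev, flicker_model, 0.0, noise_sd_pA=0.1,
                          sampling_khz=10.0, seed=9)
        assert len(tr.i_pA) >= 10_000
        assert tr.i_pA.std() == pytest.approx(0.1, rel=0.05)

    def test_negative_noise_rejected(self, flicker_model):
        ev = simulate_gating(flicker_model, 90.0, 100.0, seed=0)
        with pytest.raises(ValueError, match="noise_sd"):
            render_trace(ev, flicker_model, 90.0, noise_sd_pA=-1.0)

    def test_filter_needs_nyquist_headroom(self, flicker_model):
        ev = simulate_gating(flicker_model, 90.0, 100.0, seed=0)
        with pytest.raises(ValueError, match="2x the filter"):
            render_trace(ev, flicker_model, 90.0, sampling_khz=3.0,
                         filter_khz=2.0)


class TestDoseResponse:
    def test_midpoint_is_fifty_percent(self):
        assert hill_response(0.10, 0.10, -1.301) == pytest.approx(50.0)

    def test_limits_with_negative_slope(self):
        assert hill_response(1e9, 0.10, -1.301) < 1e-6
        assert hill_response(1e-9, 0.10, -1.301) > 100.0 - 1e-6

    def test_direct_evaluation(self):
        # 100 / (1 + (0.1/1)^-1.301) = 100 / (1 + 10^1.301)
        expected = 100.0 / (1.0 + 10.0 ** 1.301)
        assert hill_response(1.0, 0.10, -1.301) == pytest.approx(expected)
        assert expected == pytest.approx(4.762, abs=0.001)

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gen_dose_response(0.1, 0.0, [0.1, 1.0])

    def test_noise_free_table_exact_and_reproducible(self):
        concs = [0.01, 0.03, 0.1, 1.0, 10.0]
        dr = gen_dose_response(0.10, -1.301, concs, replicates=2)
        assert np.allclose(dr.response_pct,
                           np.tile(hill_response(np.array(concs), 0.10,
                                                 -1.301), 2))
        a = gen_dose_response(0.10, -1.301, concs, 3, 0.05, seed=11)
        b = gen_dose_response(0.10, -1.301, concs, 3, 0.05, seed=11)
        assert np.array_equal(a.response_pct, b.response_pct)


class TestEnergyTraces:
    def test_zero_sd_constant_at_means(self):
        out = gen_energy_traces(-40.0, -77.5, sd=0.0, n=100, seed=0)
        for eq, ev in out.values():
            assert np.all(eq == -40.0) and np.all(ev == -77.5)

    def test_sample_mean_clt_bound(self):
        # 4-sigma bound: ten independent means are checked at once
        out = gen_energy_traces(-40.0, -77.5, sd=3.0, n=4000, seed=2)
        for eq, ev in out.values():
            assert abs(eq.mean() + 40.0) < 4 * 3.0 / np.sqrt(4000)
            assert abs(ev.mean() + 77.5) < 4 * 3.0 / np.sqrt(4000)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            gen_energy_traces(0.0, 0.0, sd=-1.0, n=10)


class TestLipidFrames:
    def test_zero_jitter_single_center_constant(self):
        series, _ = gen_lipid_frames([(5.0, 10.0)], 150, 0.0, seed=0)
        assert np.all(series.dP == 5.0) and np.all(series.dR2_cent == 10.0)

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            gen_lipid_frames([(5.0, 10.0), (5.0, 10.0)], 10, 0.1)

    def test_frames_realize_emitted_distances(self):
        from channelphys import lipid_geometry as lg
        series, frames = gen_lipid_frames([(4.0, 7.0)], 5, 0.2, seed=8,
                                          with_frames=True)
        for k, fr in enumerate(frames):
            ax = lg.principal_axis_smallest_moment(fr)
            dp, dr2 = lg.axis_distances(fr, ax)
            assert dp == pytest.approx(series.dP[k], abs=1e-9)
            assert dr2 == pytest.approx(series.dR2_cent[k], abs=1e-9)


class TestPhTraces:
    def test_noiseless_flat_trace_constant_ratio(self, calib):
        fl = gen_ph_traces(6.0, calib, 0.0, onset_s=30.0, noise_cv=0.0)
        ratio = fl.f405 / fl.f475
        assert np.allclose(ratio, calib.ratio_of_ph(6.0))

    def test_out_of_domain_ph_rejected(self, calib):
        with pytest.raises(ValueError, match="calibration domain"):
            gen_ph_traces(3.0, calib, 0.0)

    def test_onset_stamped_on_trace(self, calib):
        fl = gen_ph_traces(6.0, calib, 0.5, onset_s=30.0, seed=1)
        assert fl.stimulus_onset_s == 30.0
        ratio = fl.f405 / fl.f475
        assert ratio[25] < ratio[45]  # alkalinization raises the ratio
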