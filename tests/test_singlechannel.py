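"""Idealization and single-channel kinetics: recovery against generator truth."""

import numpy as np
import pytest

from channelphys import singlechannel as sc
from channelphys import synthgen
from channelphys.synthgen import (
    EventSequence,
    TraceRecord,
    render_trace,
    simulate_gating,
    two_state_model,
    two_state_model_from_po,
)


def _square_trace(levels_pA, samples_per_level, sampling_khz=10.0,
                  holding_mV=90.0):
    i = np.repeat(levels_pA, samples_per_level).astype(float)
    t = np.arange(len(i)) / sampling_khz
    return TraceRecord(t, i, holding_mV, sampling_khz)


class TestIdealize:
    def test_noiseless_square_wave_exact_recovery(self):
        tr = _square_trace([0.0, 5.4, 0.0, 5.4, 0.0], 50)
        ev = sc.idealize(tr, 5.4)
        assert [s for s, _ in ev.events] == \
            ["closed", "open", "closed", "open", "closed"]
        assert all(d == pytest.approx(5.0) for _, d in ev.events)

    def test_all_baseline_single_closed_event(self):
        tr = _square_trace([0.0], 500)
        ev = sc.idealize(tr, 5.4)
        assert ev.events == [("closed", pytest.approx(50.0))]

    def test_zero_amplitude_rejected(self):
        tr = _square_trace([0.0], 100)
        with pytest.raises(ValueError):
            sc.idealize(tr, 0.0)

    def test_sign_mismatch_warns_but_proceeds(self):
        tr = _square_trace([0.0, -5.4, 0.0], 50, holding_mV=-150.0)
        with pytest.warns(UserWarning, match="sign"):
            ev = sc.idealize(tr, 5.4)
        # magnitude-based classification never sees the negative openings
        assert ev.events[0][0] == "closed"

    def test_dead_time_merges_short_gaps(self):
        # a 2-sample closure inside a long opening disappears at 0.5 ms dead time
        tr = _square_trace([0.0] * 1 + [5.4] * 1 + [0.0] * 1, [100, 200, 100],
                           sampling_khz=10.0)
        i = tr.i_pA.copy()
        i[150:152] = 0.0
        tr = TraceRecord(tr.t_ms, i, tr.holding_mV, tr.sampling_khz)
        ev = sc.idealize(tr, 5.4, dead_time_ms=0.5)
        assert [s for s, _ in ev.events] == ["closed", "open", "closed"]

    def test_noisy_po_recovery_within_generator_truth(self, flicker_model):
        ev_true = simulate_gating(flicker_model, 90.0, 60_000.0, seed=21)
        tr = render_trace(ev_true, flicker_model, 90.0, noise_sd_pA=0.54,
                          sampling_khz=10.0, filter_khz=2.0, seed=22)
        ev = sc.idealize(tr, 5.4, dead_time_ms=0.3)
        po_true = sc.open_probability(ev_true)
        assert sc.open_probability(ev) == pytest.approx(po_true, abs=0.02)

    def test_noise_free_round_trip_po_exact(self, flicker_model):
        # simulate -> render (no noise) -> idealize -> Po matches event Po
        # to within one sample period of quantization per event boundary
        ev_true = simulate_gating(flicker_model, 90.0, 20_000.0, seed=2)
        tr = render_trace(ev_true, flicker_model, 90.0, 0.0,
                          sampling_khz=10.0)
        ev = sc.idealize(tr, 5.4)
        quantization = ev_true.n_events * 0.1 / ev_true.total_ms
        assert abs(sc.open_probability(ev)
                   - sc.open_probability(ev_true)) <= quantization


class TestOpenProbability:
    def test_all_closed_zero(self):
        assert sc.open_probability(
            EventSequence([("closed", 10.0)], 10.0)) == 0.0

    def test_alternating_equal_dwells_half(self):
        ev = EventSequence([("closed", 5.0), ("open", 5.0)] * 3, 30.0)
        assert sc.open_probability(ev) == pytest.approx(0.5)

    def test_subconductance_counts_as_open(self):
        ev = EventSequence([("closed", 5.0), ("sub", 5.0)], 10.0)
        assert sc.open_probability(ev) == pytest.approx(0.5)

    def test_positive_limb_maximum_po(self):
        # generator pinned to the reported +90 mV maximum Po of 0.6
        m = two_state_model_from_po(0.6, mean_open_ms=26.0)
        ev = simulate_gating(m, 90.0, 120_000.0, seed=13)
        assert sc.open_probability(ev) == pytest.approx(0.6, abs=0.03)


class TestDwellFit:
    def test_mle_is_sample_mean(self):
        fit = sc.fit_dwell_exponential([2.0, 4.0, 6.0])
        assert fit.tau_ms == pytest.approx(4.0)

    def test_truncated_mle_subtracts_dead_time(self, rng):
        d = rng.exponential(50.0, 2000) + 1.5
        fit = sc.fit_dwell_exponential(d, dead_time_ms=1.5)
        assert fit.tau_ms == pytest.approx(d.mean() - 1.5)

    def test_recovery_of_long_negative_limb_constant(self, rng):
        # tau = 421 ms, the long-opening kinetics of the negative limb
        n = 5000
        d = rng.exponential(421.0, n)
        fit = sc.fit_dwell_exponential(d)
        assert abs(fit.tau_ms - 421.0) < 3 * 421.0 / np.sqrt(n)

    def test_time_rescaling_equivariance(self, rng):
        d = rng.exponential(10.0, 500)
        t1 = sc.fit_dwell_exponential(d).tau_ms
        t2 = sc.fit_dwell_exponential(3.7 * d).tau_ms
        assert t2 == pytest.approx(3.7 * t1)

    def test_insufficient_events_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sc.fit_dwell_exponential([5.0])


class TestAmplitudeHistogram:
    @staticmethod
    def _mixture_trace(rng, means=(0.0, -3.0), sds=(0.2, 0.2),
                       weights=(0.7, 0.3), n=20_000):
        comp = rng.choice(len(means), size=n, p=weights)
        x = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
        t = np.arange(n) / 10.0
        return TraceRecord(t, x, -90.0, 10.0)

    def test_two_component_recovery(self, rng):
        tr = self._mixture_trace(rng)
        fit = sc.amplitude_histogram_fit(tr, n_components=2)
        assert fit.means_pA == pytest.approx([-3.0, 0.0], abs=0.05)
        assert fit.weights == pytest.approx([0.3, 0.7], abs=0.05)

    def test_oracle_equivalence_threshold_classifier(self, rng):
        # on a well-separated mixture the EM fit must agree with the
        # midpoint-threshold classifier (an independent estimate)
        tr = self._mixture_trace(rng, n=10_000)
        fit = sc.amplitude_histogram_fit(tr, n_components=2)
        lower = tr.i_pA[tr.i_pA < -1.5]
        upper = tr.i_pA[tr.i_pA >= -1.5]
        assert fit.means_pA[0] == pytest.approx(lower.mean(), abs=0.02)
        assert fit.means_pA[1] == pytest.approx(upper.mean(), abs=0.02)
        assert fit.weights[0] == pytest.approx(len(lower) / len(tr.i_pA),
                                               abs=0.02)

    def test_single_level_degenerates_to_one_weight(self):
        # noiseless single-level trace: a 2-component fit degenerates to
        # one dominant component (or two coincident means)
        x = np.full(5000, 1.25)
        tr = TraceRecord(np.arange(5000) / 10.0, x, 90.0, 10.0)
        fit = sc.amplitude_histogram_fit(tr, n_components=2)
        assert fit.weights.max() >= 0.95 or abs(
            fit.means_pA[1] - fit.means_pA[0]) < 0.05

    def test_weights_normalized(self, rng):
        tr = self._mixture_trace(rng, n=5000)
        fit = sc.amplitude_histogram_fit(tr, n_components=2)
        assert fit.weights.sum() == pytest.approx(1.0)


class TestUnitaryIV:
    def test_linear_fit_recovers_conductance(self):
        v = np.array([-120.0, -60.0, 0.0, 60.0, 120.0])
        g, erev = 0.06, -10.0  # pA/mV and mV
        pts = np.column_stack([v, g * (v - erev)])
        fit = sc.unitary_iv_fit(pts, degree=1)
        assert fit.coefficients[1] == pytest.approx(g)
        assert fit.coefficients[0] == pytest.approx(-g * erev)

    def test_interpolating_fit_zero_residual(self, rng):
        v = np.array([-100.0, -50.0, 0.0, 50.0])
        a = rng.normal(size=4)
        fit = sc.unitary_iv_fit(np.column_stack([v, a]), degree=3)
        assert np.allclose(fit.residuals_pA, 0.0, atol=1e-9)

    def test_cubic_coefficient_recovery_under_noise(self, rng):
        coeffs = np.array([0.1, 0.05, -1e-4, 2e-6])
        v = np.linspace(-150, 100, 40)
        a = np.polynomial.polynomial.polyval(v, coeffs) + rng.normal(0, 0.05, 40)
        fit = sc.unitary_iv_fit(np.column_stack([v, a]), degree=3)
        assert fit.coefficients == pytest.approx(coeffs, abs=0.05)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="distinct voltages"):
            sc.unitary_iv_fit([(0.0, 0.0), (10.0, 1.0)], degree=3)


class TestMacroscopicReconstruction:
    @staticmethod
    def _linear_uiv(g=0.05, erev=0.0):
        v = np.linspace(-150, 100, 6)
        return sc.unitary_iv_fit(np.column_stack([v, g * (v - erev)]),
                                 degree=1)

    def test_unit_po_identity(self):
        uiv = self._linear_uiv()
        po = sc.PoCurve(np.linspace(-150, 100, 11), np.ones(11))
        v, prod, _ = sc.reconstruct_macroscopic(uiv, po)
        assert np.allclose(prod, np.asarray(uiv(v)))

    def test_zero_po_at_zero_mv(self):
        uiv = self._linear_uiv(erev=-20.0)
        po = sc.PoCurve(np.array([-150.0, 0.0, 100.0]),
                        np.array([0.3, 0.0, 0.6]))
        _, prod, _ = sc.reconstruct_macroscopic(uiv, po)
        assert prod[1] == 0.0

    def test_asymmetric_po_sharpens_rectification(self):
        # weakly rectifying unitary current x strongly asymmetric Po
        # must rectify more than the unitary current alone
        uiv = self._linear_uiv()
        v = np.linspace(-150, 100, 26)
        po = sc.PoCurve(v, np.where(v < 0, 0.6, 0.1))
        _, _, rect = sc.reconstruct_macroscopic(uiv, po)
        rect_unitary = sc.rectification_index(
            (v, np.asarray(uiv(v))))
        assert rect > rect_unitary

    def test_commutes_with_current_scaling(self):
        uiv = self._linear_uiv()
        po = sc.PoCurve(np.linspace(-150, 100, 11),
                        np.linspace(0.3, 0.6, 11))
        _, prod1, r1 = sc.reconstruct_macroscopic(uiv, po)
        uiv2 = sc.UnitaryIV(uiv.voltage_mV, 2 * uiv.amplitude_pA,
                            2 * uiv.coefficients, uiv.degree)
        _, prod2, r2 = sc.reconstruct_macroscopic(uiv2, po)
        assert np.allclose(prod2, 2 * prod1)
        assert r2 == pytest.approx(r1)

    def test_disjoint_ranges_rejected(self):
        uiv = self._linear_uiv()
        po = sc.PoCurve(np.array([500.0, 600.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="disjoint"):
            sc.reconstruct_macroscopic(uiv, po)


class TestRectificationIndex:
    def test_ohmic_through_origin(self):
        v = np.linspace(-150, 100, 51)
        assert sc.rectification_index((v, v)) == pytest.approx(1.5)

    def test_reported_wild_type_magnitude(self):
        v = np.array([-150.0, 0.0, 100.0])
        i = np.array([-2.7, 0.0, 1.0])
        assert sc.rectification_index((v, i)) == pytest.approx(2.7)

    def test_scale_invariance(self):
        v = np.linspace(-150, 100, 11)
        i = np.tanh(v / 50.0) * np.where(v < 0, 3.0, 1.0)
        assert sc.rectification_index((v, 2 * i)) == pytest.approx(
            sc.rectification_index((v, i)))

    def test_zero_positive_current_rejected(self):
        v = np.array([-150.0, 100.0])
        with pytest.raises(ValueError, match="undefined"):
            sc.rectification_index((v, np.array([-1.0, 0.0])))
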