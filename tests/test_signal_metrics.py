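import numpy as np
import pytest

from gevikit.dff_core import FluorTrace
from gevikit.signal_metrics import (
    background_degradation,
    noise_level,
    photon_budget,
    signal_amplitude,
    snr_report,
)
from gevikit.synthetic_scene import ap_attenuation


def trace_from(values, rate=100.0):
    return FluorTrace(np.asarray(values, float), rate, "raw")


class TestSignalAmplitude:
    @pytest.mark.parametrize("kind,kw", [
        ("long_depol", dict(stim_duration_s=0.1)),
        ("spike", dict(spike_index=0)),
        ("spike", dict(spike_index=1)),
    ])
    def test_flat_trace_gives_zero(self, kind, kw):
        trace = trace_from(np.zeros(100))
        assert signal_amplitude(trace, 50, kind, **kw) == 0.0

    def test_step_of_minus_59_bp_reads_059_percent(self):
        """A -0.59 % step during a 100 ms stimulus reads as 0.59 %."""
        v = np.zeros(100)
        v[50:60] = -0.0059
        trace = trace_from(v)
        amp = signal_amplitude(trace, 50, "long_depol", stim_duration_s=0.1)
        assert amp == pytest.approx(0.59)

    def test_ap_amplitude_recovers_through_kinetics(self):
        """First-spike rule returns the frame-integrated AP peak."""
        rate, tau, peak = 100.0, 0.025, 0.0014
        n_sub = 100
        t = (np.arange(300 * n_sub) + 0.5) / (rate * n_sub)
        w = np.where(t >= 1.0, -peak * np.exp(-(t - 1.0) / tau), 0.0)
        v = w.reshape(300, n_sub).mean(axis=1)
        amp = signal_amplitude(trace_from(v, rate), 100, "spike")
        expected = peak * ap_attenuation(tau, rate) * 100.0
        assert amp == pytest.approx(expected, rel=1e-3)

    def test_baseline_windows_follow_printed_rules(self):
        """First spike: median of 10 points; later: max of the 20 ms span."""
        rate = 100.0  # 20 ms -> 2 frames
        v = np.zeros(200)
        v[90:100] = [0.0, 1e-4, 2e-4, 3e-4, 4e-4, 5e-4, 6e-4, 7e-4, 3e-4, 1e-4]
        v[100:105] = -0.002
        trace = trace_from(v, rate)
        first = signal_amplitude(trace, 100, "spike", spike_index=0)
        later = signal_amplitude(trace, 100, "spike", spike_index=1)
        med10 = np.median(v[90:100])
        max2 = v[98:100].max()
        assert first == pytest.approx((med10 + 0.002) * 100.0)
        assert later == pytest.approx((max2 + 0.002) * 100.0)

    def test_constant_offset_invariance(self):
        v = np.zeros(100)
        v[50:60] = -0.004
        for kind, kw in [("long_depol", dict(stim_duration_s=0.1)),
                         ("spike", dict(spike_index=0)),
                         ("spike", dict(spike_index=1))]:
            a0 = signal_amplitude(trace_from(v), 50, kind, **kw)
            a1 = signal_amplitude(trace_from(v + 0.37), 50, kind, **kw)
            assert a0 == pytest.approx(a1, abs=1e-12)

    def test_insufficient_baseline_errors(self):
        trace = trace_from(np.zeros(100))
        with pytest.raises(ValueError, match="pre-stimulus"):
            signal_amplitude(trace, 5, "long_depol", stim_duration_s=0.1)


class TestNoiseLevel:
    def test_constant_baseline_gives_zero(self):
        assert noise_level(trace_from(np.zeros(50)), 30) == 0.0

    def test_alternating_sequence_matches_direct_formula(self):
        """+-c alternation: sample SD is c * sqrt(20/19)."""
        c = 0.001
        v = np.tile([c, -c], 25)
        got = noise_level(trace_from(v), 40)
        assert got == pytest.approx(100.0 * c * np.sqrt(20.0 / 19.0), rel=1e-12)

    def test_iid_noise_recovered_within_chi2_bounds(self):
        """SD of 0.0007 reads ~0.07 % within the chi2 spread at n=20."""
        estimates = [
            noise_level(
                trace_from(np.random.default_rng(s).normal(0, 7e-4, 60)), 40
            )
            for s in range(50)
        ]
        assert np.median(estimates) == pytest.approx(0.07, rel=0.15)
        assert all(0.07 * 0.5 < e < 0.07 * 1.6 for e in estimates)

    def test_short_baseline_errors(self):
        with pytest.raises(ValueError, match="20 pre-stimulus"):
            noise_level(trace_from(np.zeros(30)), 10)


class TestSnrReport:
    def make_trace(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 0.00059, 200)
        v[100:110] += -0.0059
        return trace_from(v)

    def test_snr_is_signal_over_noise(self):
        rep = snr_report(self.make_trace(), 100, "long_depol",
                        bleach_rate_pct_s=0.52, stim_duration_s=0.1)
        assert rep.snr == pytest.approx(rep.signal_pct / rep.noise_pct)
        assert rep.snr == pytest.approx(10.0, rel=0.5)

    def test_unit_bleach_rate_is_convention_anchor(self):
        rep = snr_report(self.make_trace(), 100, "long_depol",
                        bleach_rate_pct_s=1.0, stim_duration_s=0.1)
        assert rep.bleach_corrected_snr == pytest.approx(rep.snr)

    def test_nonpositive_bleach_rate_marks_unavailable(self):
        rep = snr_report(self.make_trace(), 100, "long_depol",
                        bleach_rate_pct_s=0.0, stim_duration_s=0.1)
        assert rep.bleach_corrected_snr is None
        assert "unavailable" in rep.correction_convention

    def test_corrected_snr_invariant_to_illumination(self, rng):
        """4x illumination doubles raw SNR but leaves corrected SNR fixed.

        Shot-noise scaling: noise SD ~ 1/sqrt(photons); bleach rate scales
        linearly with illumination.
        """
        def reports(scale, seed):
            r = np.random.default_rng(seed)
            noise_sd = 0.0008 / np.sqrt(scale)
            v = r.normal(0, noise_sd, 200)
            v[100:110] += -0.0059
            return snr_report(trace_from(v), 100, "long_depol",
                              bleach_rate_pct_s=0.5 * scale,
                              stim_duration_s=0.1)

        base = [reports(1.0, s) for s in range(30)]
        bright = [reports(4.0, s + 100) for s in range(30)]
        raw_ratio = np.median([b.snr for b in bright]) / np.median([b.snr for b in base])
        corr_ratio = (np.median([b.bleach_corrected_snr for b in bright])
                      / np.median([b.bleach_corrected_snr for b in base]))
        assert raw_ratio == pytest.approx(2.0, rel=0.1)
        assert corr_ratio == pytest.approx(1.0, abs=0.1)


class TestPhotonBudget:
    def test_one_percent_snr_one_needs_ten_thousand_photons(self):
        assert photon_budget(0.01, target_snr=1.0) == pytest.approx(10_000.0)

    def test_zero_photons_zero_snr(self):
        assert photon_budget(0.01, photons=0.0) == 0.0

    def test_forward_example(self):
        assert photon_budget(0.01, photons=1e6) == pytest.approx(10.0)

    def test_forward_inverse_roundtrip(self):
        for dff in (0.001, 0.0059, 0.02):
            for snr in (0.5, 1.0, 7.3):
                n = photon_budget(dff, target_snr=snr)
                assert photon_budget(dff, photons=n) == pytest.approx(snr)

    def test_invalid_queries_error(self):
        with pytest.raises(ValueError):
            photon_budget(0.01)
        with pytest.raises(ValueError):
            photon_budget(0.01, photons=1.0, target_snr=1.0)
        with pytest.raises(ValueError, match="infinite"):
            photon_budget(0.0, target_snr=1.0)


class TestBackgroundDegradation:
    def test_no_background_is_identity(self):
        assert background_degradation(0.0, 5.0, 0.01) == (0.01, 5.0)

    def test_printed_dilution_formula(self):
        dff, _ = background_degradation(0.75, 5.0, 0.01)
        assert dff == pytest.approx(0.0025)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            background_degradation(1.0, 5.0, 0.01)
        with pytest.raises(ValueError):
            background_degradation(-0.1, 5.0, 0.01)

    def test_sqrt_convention_matches_simulation(self):
        """Measured SNR ratio between f_b=0.5 and f_b=0 scenes is ~sqrt(0.5).

        Monte-Carlo oracle at the photon level: an ROI collecting N signal
        photons plus background so that the background fraction is f_b,
        at fixed total photon flux per pixel budget.
        """
        rng = np.random.default_rng(11)
        n_signal = 200_000.0
        dff0 = 0.01

        def measured_snr(f_b, n_rep=400):
            n_bg = n_signal * f_b / (1.0 - f_b)
            total = n_signal + n_bg
            # dff is measured against total collected fluorescence
            amp = dff0 * n_signal  # only signal photons modulate
            baseline = rng.poisson(total, n_rep)
            peak = rng.poisson(total - amp, n_rep)
            dffs = (peak - baseline.mean()) / (baseline.mean())
            signal = -dffs.mean()
            noise = (baseline / baseline.mean() - 1.0).std()
            return signal / noise

        snr0 = measured_snr(0.0)
        snr_half = measured_snr(0.5)
        expected = background_degradation(0.5, snr0, dff0)[1]
        linear = (1.0 - 0.5) * snr0
        # the sqrt convention should predict the simulated ratio better
        assert abs(snr_half - expected) < abs(snr_half - linear)
        assert snr_half / snr0 == pytest.approx(np.sqrt(0.5), rel=0.15)
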