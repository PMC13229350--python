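"""ERP preprocessing and MMN extraction, with surrogate ground truth and a
brute-force window-scan oracle."""

import numpy as np
import pytest

from pfceeg.erp import ERPTrace, erp_preprocess, firing_snr, mmn_amplitude
from pfceeg.surrogate import ERPSurrogateSpec, gen_erp_surrogate


def brute_force_mmn(trace: ERPTrace, lo=100.0, hi=200.0):
    """Independent oracle: exhaustive scan of the window."""

    best_amp, best_lat = 0.0, float("nan")
    for t, v in zip(trace.time_ms, trace.amplitude_nV):
        if lo <= t <= hi and v < 0 and -v > best_amp:
            best_amp, best_lat = -v, t
    return best_amp, best_lat


class TestErpPreprocess:
    def test_constant_signal_zero_erp(self):
        fs = 1000.0
        eeg = np.full(int(fs * 5), 7.3)
        erp = erp_preprocess(eeg, fs, [2000.0])
        np.testing.assert_allclose(erp.amplitude_nV, 0.0, atol=1e-9)

    def test_output_rate_100hz(self):
        fs = 2000.0
        eeg = np.zeros(int(fs * 5))
        erp = erp_preprocess(eeg, fs, [2000.0])
        assert erp.fs_hz == 100.0
        dt = np.diff(erp.time_ms)
        np.testing.assert_allclose(dt, 10.0)

    def test_lowpass_band_behavior(self):
        # 10 Hz passes; 80 Hz attenuated > 20 dB
        fs = 1000.0
        t = np.arange(0, 6, 1 / fs)
        stim = [3000.0]
        for freq, keep in [(10.0, True), (80.0, False)]:
            eeg = np.sin(2 * np.pi * freq * t)
            erp = erp_preprocess(eeg, fs, stim)
            out_amp = np.abs(erp.amplitude_nV).max()
            if keep:
                assert out_amp > 0.7
            else:
                assert out_amp < 0.1  # > 20 dB down

    def test_baseline_window_zero_mean(self):
        rng = np.random.default_rng(5)
        fs = 1000.0
        eeg = rng.normal(size=int(fs * 6))
        erp = erp_preprocess(eeg, fs, [3000.0])
        base = erp.amplitude_nV[(erp.time_ms >= -500) & (erp.time_ms < 0)]
        assert abs(base.mean()) < 1e-9

    def test_linearity(self):
        rng = np.random.default_rng(6)
        fs = 1000.0
        eeg = rng.normal(size=int(fs * 6))
        e1 = erp_preprocess(eeg, fs, [3000.0])
        e3 = erp_preprocess(3.0 * eeg, fs, [3000.0])
        np.testing.assert_allclose(e3.amplitude_nV, 3.0 * e1.amplitude_nV, atol=1e-9)

    def test_insufficient_prestimulus_rejected(self):
        with pytest.raises(ValueError):
            erp_preprocess(np.zeros(1000), 1000.0, [200.0])

    def test_no_stimuli_rejected(self):
        with pytest.raises(ValueError):
            erp_preprocess(np.zeros(5000), 1000.0, [])


class TestMmnAmplitude:
    def test_injected_trough_recovered(self):
        spec = ERPSurrogateSpec(trough_amplitude_nV=3.0, latency_ms=130.0,
                                noise_sd_nV=0.0, n_events=5)
        x, events = gen_erp_surrogate(spec)
        erp = erp_preprocess(x, spec.fs_hz, events)
        amp, lat = mmn_amplitude(erp)
        assert amp == pytest.approx(3.0, rel=0.05)
        assert lat == pytest.approx(130.0, abs=10.0)

    def test_all_positive_trace_sentinel(self):
        t = np.arange(-500, 400, 10.0)
        trace = ERPTrace(t, np.abs(np.sin(t / 50)) + 0.1)
        amp, lat = mmn_amplitude(trace)
        assert amp == 0.0 and np.isnan(lat)

    def test_trough_outside_window_excluded(self):
        # deep trough at 95 ms is ignored; the in-window extremum is reported
        t = np.arange(-500, 400, 10.0)
        x = np.zeros(t.size)
        x[np.argmin(np.abs(t - 90))] = -10.0
        x[np.argmin(np.abs(t - 150))] = -2.0
        trace = ERPTrace(t, x)
        amp, lat = mmn_amplitude(trace)
        assert amp == pytest.approx(2.0)
        assert lat == pytest.approx(150.0)

    def test_matches_brute_force_scan_on_random_traces(self, rng):
        # 100 random traces: extraction equals the exhaustive-scan oracle
        t = np.arange(-500, 400, 10.0)
        for _ in range(100):
            trace = ERPTrace(t, rng.normal(size=t.size))
            got = mmn_amplitude(trace)
            want = brute_force_mmn(trace)
            assert got[0] == pytest.approx(want[0])
            if got[0] > 0:
                assert got[1] == want[1]

    def test_window_not_covered_rejected(self):
        t = np.arange(-500, 150, 10.0)
        with pytest.raises(ValueError):
            mmn_amplitude(ERPTrace(t, np.zeros(t.size)))


class TestFiringSnr:
    def test_equal_rates_unity(self):
        assert firing_snr(2.0, 2.0) == 1.0

    def test_printed_rate_pair(self):
        # oddball 3.32 Hz over standard 0.61 Hz
        assert firing_snr(3.32, 0.61) == pytest.approx(5.44, abs=0.01)

    def test_zero_response(self):
        assert firing_snr(0.0, 1.0) == 0.0

    def test_zero_standard_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(firing_snr(1.0, 0.0))


class TestSurrogateErp:
    def test_zero_amplitude_sentinel(self):
        spec = ERPSurrogateSpec(trough_amplitude_nV=0.0, noise_sd_nV=0.0, n_events=3)
        x, events = gen_erp_surrogate(spec)
        erp = erp_preprocess(x, spec.fs_hz, events)
        amp, lat = mmn_amplitude(erp)
        assert amp == pytest.approx(0.0, abs=1e-9)

    def test_recovery_error_decreases_with_event_count(self):
        # averaging law: more events, smaller recovery error at fixed noise
        errs = []
        for n_events in (4, 16, 64):
            recovered = []
            for seed in range(5):
                spec = ERPSurrogateSpec(trough_amplitude_nV=3.0, noise_sd_nV=5.0,
                                        n_events=n_events, seed=seed)
                x, events = gen_erp_surrogate(spec)
                erp = erp_preprocess(x, spec.fs_hz, events)
                recovered.append(mmn_amplitude(erp)[0])
            errs.append(np.mean(np.abs(np.array(recovered) - 3.0)))
        assert errs[2] < errs[0]

    def test_too_dense_events_rejected(self):
        with pytest.raises(ValueError):
            gen_erp_surrogate(ERPSurrogateSpec(inter_event_ms=600.0))
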