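"""Welch PSD and aperiodic/periodic decomposition, validated against
surrogate signals with known ground-truth parameters."""

import numpy as np
import pytest

from pfceeg.spectral import (BANDS, band_power, fit_aperiodic_periodic,
                             peak_frequency, welch_psd, PSDDecomposition)
from pfceeg.surrogate import PSDSurrogateSpec, gen_psd_surrogate


class TestWelch:
    def test_sinusoid_peak_bin(self):
        fs = 250.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        f, p = welch_psd(x, fs)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)

    def test_parseval_white_noise(self, rng):
        # full-band PSD integral matches the signal variance within 5%
        fs = 500.0
        x = rng.normal(0, 2.0, size=int(fs * 60))
        f, p = welch_psd(x, fs, freq_range=None)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_output_restricted_to_3_30(self):
        fs = 250.0
        x = np.random.default_rng(0).normal(size=int(fs * 20))
        f, _ = welch_psd(x, fs)
        assert f.min() >= 3.0 and f.max() <= 30.0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(4), 250.0)


class TestDecomposition:
    def test_surrogate_recovery_single_peak(self):
        spec = PSDSurrogateSpec(offset=-1.0, exponent=1.5,
                                peaks=[(10.0, 1.5, 0.8)], duration_s=120, seed=3)
        x = gen_psd_surrogate(spec)
        f, p = welch_psd(x, spec.fs_hz)
        dec = fit_aperiodic_periodic(f, p)
        assert dec.exponent == pytest.approx(1.5, abs=0.15)
        assert len(dec.peaks) >= 1
        cf = peak_frequency(dec, (8.0, 12.0))
        assert cf == pytest.approx(10.0, abs=0.25)

    def test_pure_aperiodic_no_peaks(self):
        spec = PSDSurrogateSpec(offset=-1.0, exponent=1.0, peaks=[],
                                duration_s=120, seed=5)
        x = gen_psd_surrogate(spec)
        f, p = welch_psd(x, spec.fs_hz)
        dec = fit_aperiodic_periodic(f, p)
        assert len(dec.peaks) == 0
        assert dec.exponent == pytest.approx(1.0, abs=0.15)

    def test_never_more_than_four_peaks(self, rng):
        # jagged spectrum with many candidate bumps
        spec = PSDSurrogateSpec(
            offset=-1.0, exponent=1.0,
            peaks=[(6, 0.8, 0.6), (10, 0.8, 0.7), (15, 0.8, 0.5),
                   (20, 0.8, 0.6), (25, 0.8, 0.5)],
            duration_s=120, seed=7,
        )
        x = gen_psd_surrogate(spec)
        f, p = welch_psd(x, spec.fs_hz)
        dec = fit_aperiodic_periodic(f, p)
        assert len(dec.peaks) <= 4

    def test_parameter_recovery_grid(self):
        # median errors over a grid of exponents and peak positions
        exp_errors, cf_errors = [], []
        for i, exponent in enumerate([0.5, 1.0, 1.5, 2.0]):
            for j, cf in enumerate([6.0, 10.0, 15.0, 25.0]):
                for seed in range(5):
                    spec = PSDSurrogateSpec(
                        offset=-1.0, exponent=exponent, peaks=[(cf, 1.2, 0.7)],
                        duration_s=90, seed=100 * i + 10 * j + seed,
                    )
                    x = gen_psd_surrogate(spec)
                    f, p = welch_psd(x, spec.fs_hz)
                    dec = fit_aperiodic_periodic(f, p)
                    exp_errors.append(abs(dec.exponent - exponent))
                    got = peak_frequency(dec, (max(3.0, cf - 3), min(30.0, cf + 3)))
                    if got is not None:
                        cf_errors.append(abs(got - cf))
        assert np.median(exp_errors) < 0.15
        assert len(cf_errors) >= 0.8 * 80
        assert np.median(cf_errors) < 0.3

    def test_reconstruction_self_consistency(self):
        spec = PSDSurrogateSpec(offset=-1.5, exponent=1.2,
                                peaks=[(11, 1.5, 0.6)], duration_s=120, seed=11)
        x = gen_psd_surrogate(spec)
        f, p = welch_psd(x, spec.fs_hz)
        dec = fit_aperiodic_periodic(f, p)
        assert dec.fit_error < 0.1  # mean |log10 model - log10 psd|

    def test_deterministic(self):
        spec = PSDSurrogateSpec(peaks=[(10, 1.5, 0.5)], duration_s=60, seed=2)
        x = gen_psd_surrogate(spec)
        f, p = welch_psd(x, spec.fs_hz)
        d1 = fit_aperiodic_periodic(f, p)
        d2 = fit_aperiodic_periodic(f, p)
        assert d1.offset == d2.offset and d1.peaks == d2.peaks

    def test_nonpositive_psd_rejected(self):
        with pytest.raises(ValueError):
            fit_aperiodic_periodic(np.array([3.0, 4.0]), np.array([1.0, 0.0]))


class TestBandPower:
    def test_flat_psd_rectangle(self):
        f = np.arange(3.0, 30.1, 0.5)
        p = np.full(f.size, 2.0)
        assert band_power((f, p), (8.0, 12.0)) == pytest.approx(8.0, rel=1e-6)

    def test_zero_psd(self):
        f = np.arange(3.0, 30.1, 0.5)
        assert band_power((f, np.zeros(f.size)), "alpha") == 0.0

    def test_periodic_component_gaussian_area(self):
        # analytic check: integral of the linear-power excess of one peak
        f = np.arange(3.0, 30.01, 0.05)
        offset, exponent = -1.0, 1.0
        cf, bw, h = 10.0, 1.0, 0.5
        aper = offset - exponent * np.log10(f)
        model = aper + h * np.exp(-0.5 * ((f - cf) / bw) ** 2)
        dec = PSDDecomposition(f, 10.0**model, offset, exponent, [(cf, bw, h)])
        got = band_power(dec, (3.0, 30.0), "periodic")
        want = np.trapezoid(10.0**model - 10.0**aper, f)
        assert got == pytest.approx(want, rel=1e-9)

    def test_empty_band_rejected(self):
        f = np.arange(3.0, 30.1, 0.5)
        with pytest.raises(ValueError):
            band_power((f, np.ones(f.size)), (12.0, 12.0))

    def test_band_definitions(self):
        assert BANDS["alpha"] == (8.0, 12.0)
        assert BANDS["low_beta"] == (12.0, 20.0)


class TestPeakFrequency:
    def _dec(self, peaks):
        f = np.arange(3.0, 30.1, 0.5)
        return PSDDecomposition(f, np.ones(f.size), 0.0, 1.0, peaks)

    def test_single_peak(self):
        assert peak_frequency(self._dec([(11.2, 1.0, 0.5)]), "alpha") == 11.2

    def test_no_peak_sentinel(self):
        assert peak_frequency(self._dec([]), "alpha") is None
        assert peak_frequency(self._dec([(15.0, 1.0, 0.5)]), "alpha") is None

    def test_highest_power_selected(self):
        dec = self._dec([(10.0, 1.0, 0.3), (11.0, 1.0, 0.6)])
        assert peak_frequency(dec, (8.0, 12.0)) == 11.0
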