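"""Spectral analysis of simulated EEG: Welch PSD over 3-30 Hz, decomposition
into an aperiodic 1/f component (offset, exponent) plus up to four Gaussian
peaks in log10 power, band powers, and peak-frequency extraction.

The decomposition follows the standard spectral-parameterization recipe:
robust aperiodic fit in log-log space, iterative extraction of the largest
residual peak (Gaussian in log10 power over linear frequency), and a final
joint refit.  It is deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

__all__ = [
    "FREQ_RANGE",
    "BANDS",
    "PSDDecomposition",
    "welch_psd",
    "fit_aperiodic_periodic",
    "band_power",
    "peak_frequency",
]

FREQ_RANGE = (3.0, 30.0)

# half-open canonical bands within the 3-30 Hz analysis range
BANDS: dict[str, tuple[float, float]] = {
    "delta": (3.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "low_beta": (12.0, 20.0),
    "beta": (12.0, 30.0),
}


def welch_psd(
    x,
    fs: float,
    segment_s: float = 3.0,
    overlap: float = 0.5,
    freq_range: tuple[float, float] = FREQ_RANGE,
):
    """One-sided Welch PSD restricted to ``freq_range``.

    Hann taper, ``segment_s``-second segments (or the full length if the
    signal is shorter), fractional ``overlap``, constant detrend.
    Returns (frequencies Hz, PSD in input-units^2/Hz).
    """

    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(segment_s * fs)), x.size)
    if x.size < 2 or nperseg < 8:
        raise ValueError("signal shorter than one analysis segment")
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    if freq_range is not None:
        lo, hi = freq_range
        keep = (freqs >= lo) & (freqs <= hi)
        freqs, psd = freqs[keep], psd[keep]
    return freqs, psd


@dataclass
class PSDDecomposition:
    """Aperiodic (offset, exponent) + <=4 Gaussian peaks fitted to a PSD.

    ``offset`` is log10 power at 1 Hz; ``exponent`` the 1/f slope (PSD ~
    10^offset * f^-exponent); each peak is (center Hz, bandwidth-SD Hz,
    height in log10 units above the aperiodic component).
    """

    frequencies: np.ndarray
    psd: np.ndarray
    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    fit_error: float = float("nan")

    def aperiodic_model(self, freqs=None) -> np.ndarray:
        f = self.frequencies if freqs is None else np.asarray(freqs, dtype=float)
        return self.offset - self.exponent * np.log10(f)

    def full_model(self, freqs=None) -> np.ndarray:
        f = self.frequencies if freqs is None else np.asarray(freqs, dtype=float)
        model = self.aperiodic_model(f)
        for cf, bw, h in self.peaks:
            model = model + h * np.exp(-0.5 * ((f - cf) / bw) ** 2)
        return model


def _gauss(f, cf, bw, h):
    return h * np.exp(-0.5 * ((f - cf) / bw) ** 2)


def _robust_aperiodic(freqs, log_psd, n_rounds: int = 2):
    """Linear fit of log-power vs log-frequency, refit on the points least
    contaminated by peaks (those below the residual median + small margin)."""

    lf = np.log10(freqs)
    mask = np.ones(freqs.size, dtype=bool)
    coeffs = np.polyfit(lf, log_psd, 1)
    for _ in range(n_rounds):
        resid = log_psd - np.polyval(coeffs, lf)
        thresh = np.percentile(resid[mask], 40.0)
        mask = resid <= max(thresh, 0.0) + 1e-12
        if mask.sum() < max(4, freqs.size // 5):
            break
        coeffs = np.polyfit(lf[mask], log_psd[mask], 1)
    return coeffs  # slope, intercept in log-log


def fit_aperiodic_periodic(
    freqs,
    psd,
    max_peaks: int = 4,
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.12,
    min_bandwidth: float = 0.5,
    max_bandwidth: float = 12.0,
) -> PSDDecomposition:
    """Decompose a PSD into aperiodic and periodic components.

    Peaks are extracted greedily from the residual above the aperiodic fit
    (largest first, must exceed ``peak_threshold_sd`` residual SDs and the
    absolute floor ``min_peak_height`` in log10 units — the detection
    resolution limit that keeps estimation noise from being reported as
    peaks), each modelled as a Gaussian in log10 power and subtracted before
    the next search; at most ``max_peaks`` are kept, then the aperiodic
    component is refit on the peak-subtracted spectrum.
    """

    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if np.any(psd <= 0):
        raise ValueError("PSD must be strictly positive for log-space fitting")
    log_psd = np.log10(psd)
    lf = np.log10(freqs)

    slope, intercept = _robust_aperiodic(freqs, log_psd)
    aperiodic = intercept + slope * lf
    flat = log_psd - aperiodic

    peaks: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(max_peaks):
        sd = np.std(work)
        i = int(np.argmax(work))
        if sd <= 0 or work[i] < max(peak_threshold_sd * sd, min_peak_height):
            break
        cf0, h0 = freqs[i], work[i]
        # half-height width estimate for the bandwidth seed
        half = h0 / 2.0
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < work.size - 1 and work[ri] > half:
            ri += 1
        fwhm = max(freqs[ri] - freqs[li], 2.0 * min_bandwidth)
        bw0 = min(max(fwhm / 2.355, min_bandwidth), max_bandwidth)
        try:
            popt, _ = curve_fit(
                _gauss,
                freqs,
                work,
                p0=(cf0, bw0, h0),
                bounds=(
                    (max(freqs[0], cf0 - 2 * bw0), min_bandwidth, 0.0),
                    (min(freqs[-1], cf0 + 2 * bw0), max_bandwidth, 2.0 * h0 + 1e-9),
                ),
                maxfev=2000,
            )
        except RuntimeError:
            break
        cf, bw, h = (float(v) for v in popt)
        if h < min_peak_height / 2:
            break
        peaks.append((cf, bw, h))
        work = work - _gauss(freqs, cf, bw, h)

    # joint refit of the aperiodic part on the peak-subtracted spectrum
    peak_model = np.zeros_like(freqs)
    for cf, bw, h in peaks:
        peak_model += _gauss(freqs, cf, bw, h)
    slope, intercept = np.polyfit(lf, log_psd - peak_model, 1)

    decomp = PSDDecomposition(
        frequencies=freqs,
        psd=psd,
        offset=float(intercept),
        exponent=float(-slope),
        peaks=sorted(peaks, key=lambda p: p[0]),
    )
    decomp.fit_error = float(np.mean(np.abs(decomp.full_model() - log_psd)))
    return decomp


def band_power(
    source,
    band: tuple[float, float] | str,
    component: str = "raw",
) -> float:
    """Trapezoidal integral of a PSD component over a frequency band.

    ``source`` is a PSDDecomposition (any component) or a (freqs, psd) pair
    (raw only).  ``component``: "raw" integrates the measured PSD,
    "aperiodic" the 10^aperiodic-model curve ("broadband power" = aperiodic
    over the full 3-30 Hz range), "periodic" the linear-power excess of the
    fitted peaks over the aperiodic component.
    """

    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    if not (hi > lo):
        raise ValueError("empty frequency band")

    if isinstance(source, PSDDecomposition):
        freqs = source.frequencies
        if component == "raw":
            values = source.psd
        elif component == "aperiodic":
            values = 10.0 ** source.aperiodic_model()
        elif component == "periodic":
            values = 10.0 ** source.full_model() - 10.0 ** source.aperiodic_model()
        else:
            raise ValueError(f"unknown component {component!r}")
    else:
        if component != "raw":
            raise ValueError("component fits require a PSDDecomposition")
        freqs, values = (np.asarray(v, dtype=float) for v in source)

    # integration includes both band edges so adjacent bands partition the
    # spectrum exactly; half-open convention applies to peak membership
    keep = (freqs >= lo) & (freqs <= hi)
    if keep.sum() < 2:
        raise ValueError("band contains fewer than two frequency samples")
    return float(np.trapezoid(values[keep], freqs[keep]))


def peak_frequency(
    decomposition: PSDDecomposition,
    band: tuple[float, float] | str = "alpha",
) -> float | None:
    """Center frequency of the highest-power fitted peak inside ``band``,
    or None when no fitted peak falls in the band."""

    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    in_band = [(cf, bw, h) for cf, bw, h in decomposition.peaks if lo <= cf < hi]
    if not in_band:
        return None
    cf, _, _ = max(in_band, key=lambda p: p[2])
    return float(cf)
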