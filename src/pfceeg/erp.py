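"""Event-related-potential pipeline and mismatch-negativity extraction.

Simulated EEG is zero-phase lowpass filtered at 40 Hz, downsampled to
100 Hz, epoched around stimulus times, averaged, and baseline corrected with
the mean of the 500 ms window preceding the stimulus.  The MMN amplitude of
a difference trace (deviant minus standard) is the largest negative peak in
the 100-200 ms post-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["ERPTrace", "erp_preprocess", "mmn_amplitude", "firing_snr", "NO_PEAK"]

NO_PEAK = float("nan")  # sentinel latency when no negative deflection exists


@dataclass
class ERPTrace:
    """Stimulus-locked average EEG: time axis relative to the stimulus (ms)
    and amplitude (nV), at 100 Hz after preprocessing."""

    time_ms: np.ndarray
    amplitude_nV: np.ndarray
    fs_hz: float = 100.0
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_ms.shape != self.amplitude_nV.shape:
            raise ValueError("time and amplitude must align")

    def __sub__(self, other: "ERPTrace") -> "ERPTrace":
        if not np.allclose(self.time_ms, other.time_ms):
            raise ValueError("ERP traces have different time axes")
        return ERPTrace(
            self.time_ms.copy(),
            self.amplitude_nV - other.amplitude_nV,
            self.fs_hz,
            {"difference": True},
        )


def erp_preprocess(
    eeg_nV,
    fs_hz: float,
    stimulus_times_ms,
    window_ms: tuple[float, float] = (-500.0, 400.0),
    lowpass_hz: float = 40.0,
    target_fs_hz: float = 100.0,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
) -> ERPTrace:
    """Filter, downsample, epoch, average, and baseline-correct.

    Requires every stimulus to have at least the 500 ms pre-stimulus
    baseline (and the full epoch window) available in the recording.
    """

    eeg = np.asarray(eeg_nV, dtype=float)
    stim = np.sort(np.atleast_1d(np.asarray(stimulus_times_ms, dtype=float)))
    if stim.size == 0:
        raise ValueError("need at least one stimulus time")
    t_total = eeg.size / fs_hz * 1e3
    if np.any(stim + window_ms[0] < 0) or np.any(stim + window_ms[1] > t_total):
        raise ValueError("epoch window (incl. 500 ms baseline) not covered by data")

    # zero-phase 4th-order Butterworth lowpass, then decimation to 100 Hz
    sos = signal.butter(4, lowpass_hz, btype="low", fs=fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, eeg)
    step = fs_hz / target_fs_hz
    if abs(step - round(step)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 100 Hz")
    ds = filtered[:: int(round(step))]

    dt_ms = 1e3 / target_fs_hz
    n_pre = int(round(-window_ms[0] / dt_ms))
    n_post = int(round(window_ms[1] / dt_ms))
    time = (np.arange(-n_pre, n_post) + 0.0) * dt_ms
    epochs = []
    for t0 in stim:
        i0 = int(round(t0 / dt_ms))
        epochs.append(ds[i0 - n_pre : i0 + n_post])
    avg = np.mean(np.stack(epochs), axis=0)

    b0 = np.searchsorted(time, baseline_ms[0])
    b1 = np.searchsorted(time, baseline_ms[1])
    avg = avg - np.mean(avg[b0:b1])
    return ERPTrace(
        time_ms=time,
        amplitude_nV=avg,
        fs_hz=target_fs_hz,
        preprocessing={
            "lowpass_hz": lowpass_hz,
            "baseline_ms": baseline_ms,
            "n_events": int(stim.size),
        },
    )


def mmn_amplitude(
    erp_difference: ERPTrace,
    window_ms: tuple[float, float] = (100.0, 200.0),
) -> tuple[float, float]:
    """(|amplitude| in nV, latency in ms) of the largest negative peak of a
    difference trace within ``window_ms`` post-stimulus.

    Returns (0.0, NaN) when no sample in the window is negative.
    """

    t = erp_difference.time_ms
    x = erp_difference.amplitude_nV
    keep = (t >= window_ms[0]) & (t <= window_ms[1])
    if not keep.any() or t[-1] < window_ms[1] or t[keep][0] > window_ms[0] + 1e-9:
        raise ValueError("trace does not cover the search window")
    seg_t, seg_x = t[keep], x[keep]
    i = int(np.argmin(seg_x))
    if seg_x[i] >= 0:
        return 0.0, NO_PEAK
    return float(-seg_x[i]), float(seg_t[i])


def firing_snr(response_rate_hz: float, standard_rate_hz: float) -> float:
    """Oddball-window over standard-window firing-rate ratio.

    A zero standard rate yields NaN (undefined) rather than an error; a zero
    response rate yields 0.
    """

    if standard_rate_hz <= 0:
        import warnings

        warnings.warn("standard rate is zero; SNR undefined", RuntimeWarning)
        return float("nan")
    return float(response_rate_hz) / float(standard_rate_hz)
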