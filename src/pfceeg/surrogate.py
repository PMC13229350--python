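"""Surrogate-signal generators.

These produce signals with exactly the statistical structure the analysis
chain assumes — 1/f spectra with Gaussian peaks (via spectral synthesis with
randomized phases), stereotyped ERP troughs in noise, homogeneous Poisson
spike trains — so every analysis stage can be tested with known ground
truth, without running the circuit simulator.  Outputs use the same
conventions (units, file formats) as the simulator, making surrogates
drop-in replacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSDSurrogateSpec",
    "ERPSurrogateSpec",
    "SpikeSurrogateSpec",
    "gen_psd_surrogate",
    "gen_erp_surrogate",
    "gen_poisson_spikes",
]


@dataclass
class PSDSurrogateSpec:
    """Target spectrum: power ~ 10^offset / f^exponent plus Gaussian peaks
    (center Hz, bandwidth-SD Hz, height in log10 units)."""

    offset: float = -1.0
    exponent: float = 1.0
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    duration_s: float = 30.0
    fs_hz: float = 250.0
    seed: int = 0


def gen_psd_surrogate(spec: PSDSurrogateSpec) -> np.ndarray:
    """Time series whose PSD follows the spec'd aperiodic + peaks shape.

    Spectral synthesis: amplitudes set from the target PSD on the rFFT grid,
    phases i.i.d. uniform; deterministic per seed.
    """

    n = int(round(spec.duration_s * spec.fs_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs_hz)
    log_psd = np.full(freqs.size, -np.inf)
    pos = freqs > 0
    log_psd[pos] = spec.offset - spec.exponent * np.log10(freqs[pos])
    for cf, bw, h in spec.peaks:
        log_psd[pos] += h * np.exp(-0.5 * ((freqs[pos] - cf) / bw) ** 2)
    psd = np.where(pos, 10.0 ** log_psd, 0.0)
    # one-sided PSD -> rFFT amplitude: |X_k|^2 * 2 / (fs * n) = S(f_k)
    amp = np.sqrt(psd * spec.fs_hz * n / 2.0)
    rng = np.random.default_rng(spec.seed)
    phases = np.exp(2j * np.pi * rng.random(freqs.size))
    spectrum = amp * phases
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = np.abs(spectrum[-1])
    return np.fft.irfft(spectrum, n=n)


@dataclass
class ERPSurrogateSpec:
    """Repeated stereotyped negative trough (Gaussian in time) in noise."""

    trough_amplitude_nV: float = 3.0
    latency_ms: float = 130.0
    width_ms: float = 20.0
    noise_sd_nV: float = 0.0
    n_events: int = 20
    inter_event_ms: float = 1500.0
    fs_hz: float = 1000.0
    seed: int = 0


def gen_erp_surrogate(spec: ERPSurrogateSpec) -> tuple[np.ndarray, np.ndarray]:
    """(continuous signal, event times in ms).

    Events are spaced ``inter_event_ms`` apart, starting 1000 ms in, so every
    epoch has the 500 ms pre-stimulus baseline the ERP pipeline requires.
    """

    if spec.inter_event_ms < 1000.0:
        raise ValueError("events too dense for a 500 ms baseline + epoch")
    if not (0 < spec.latency_ms < spec.inter_event_ms - 500.0):
        raise ValueError("latency must fall inside the epoch")
    dt_ms = 1e3 / spec.fs_hz
    total_ms = 1000.0 + spec.inter_event_ms * spec.n_events + 1000.0
    t = np.arange(0.0, total_ms, dt_ms)
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(0.0, spec.noise_sd_nV, size=t.size) if spec.noise_sd_nV > 0 else np.zeros(t.size)
    events = 1000.0 + spec.inter_event_ms * np.arange(spec.n_events)
    for t0 in events:
        x -= spec.trough_amplitude_nV * np.exp(
            -0.5 * ((t - t0 - spec.latency_ms) / spec.width_ms) ** 2
        )
    return x, events


@dataclass
class SpikeSurrogateSpec:
    rate_hz: float = 5.0
    n_neurons: int = 100
    duration_s: float = 10.0
    seed: int = 0


def gen_poisson_spikes(spec: SpikeSurrogateSpec) -> dict[int, np.ndarray]:
    """Homogeneous Poisson spike trains, ms units, per-neuron sorted."""

    if spec.duration_s <= 0 or spec.rate_hz < 0:
        raise ValueError("need positive duration and non-negative rate")
    rng = np.random.default_rng(spec.seed)
    trains = {}
    for i in range(spec.n_neurons):
        n = rng.poisson(spec.rate_hz * spec.duration_s)
        trains[i] = np.sort(rng.uniform(0.0, spec.duration_s * 1e3, size=n))
    return trains
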