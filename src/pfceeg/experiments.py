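"""Experiment runners: baseline firing/EEG, oddball response + MMN, and
resting-state PSD comparisons across randomized circuits and conditions.

Circuits are seed-matched across conditions: circuit index i uses the same
placement/connectivity/background-noise seeds in every condition, so
healthy-vs-disease contrasts isolate the perturbation.  Desk-scale defaults
use 10 circuits per condition; ``paper_scale=True`` restores 30 (baseline) /
50 (oddball) / 25 (resting) circuits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import build_circuit
from .conditions import HEALTHY, Condition, apply_condition
from .config import CircuitConfig, config_to_dict, default_config
from .erp import ERPTrace, erp_preprocess, firing_snr, mmn_amplitude
from .forward import FourSphereModel, simulate_eeg
from .oddball import (OddballProtocol, StimulusCalibration, build_oddball_stimulus,
                      calibrate_stimulus, response_profile)
from .simulate import CalibrationResult, calibrate_background, run_simulation
from .spectral import band_power, fit_aperiodic_periodic, peak_frequency, welch_psd
from .stats import StatResult, two_sample_ttest

__all__ = [
    "ExperimentConfig",
    "CalibrationError",
    "ensure_calibration",
    "run_baseline_experiment",
    "run_oddball_experiment",
    "run_resting_comparison",
    "RESPONSE_WINDOW_MS",
]

RESPONSE_WINDOW_MS = (100.0, 160.0)
# the alpha peak migrates into low-beta under disease; the dominant-peak
# search therefore spans high-theta through low-beta
PEAK_SEARCH_BAND = (8.0, 20.0)


class CalibrationError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    n_circuits: int = 10
    conditions: list[Condition] = field(default_factory=lambda: [HEALTHY])
    master_seed: int = 0
    paper_scale: bool = False
    out_dir: str | None = None
    force: bool = False  # proceed on non-converged calibration

    def __post_init__(self) -> None:
        if self.n_circuits < 2:
            raise ValueError("need n_circuits >= 2")
        if not self.conditions:
            raise ValueError("need at least one condition")


def _seed_for(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([master, *path]).generate_state(1)[0] % (2**31))


def _provenance(ccfg: CircuitConfig, exp: ExperimentConfig, extra=None) -> dict:
    snapshot = config_to_dict(ccfg)
    blob = json.dumps(snapshot, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "master_seed": exp.master_seed,
        "n_circuits": exp.n_circuits,
        "conditions": [c.label for c in exp.conditions],
        **(extra or {}),
    }


def ensure_calibration(
    ccfg: CircuitConfig,
    master_seed: int = 0,
    calibration: CalibrationResult | None = None,
    force: bool = False,
) -> CalibrationResult:
    """Return a background calibration, running it on a dedicated circuit if
    none is supplied; non-convergence aborts unless ``force``."""

    if calibration is None:
        circuits = [build_circuit(ccfg, _seed_for(master_seed, 999, k)) for k in range(2)]
        calibration = calibrate_background(circuits, seed=_seed_for(master_seed, 998))
    if not calibration.converged and not force:
        raise CalibrationError(
            f"background calibration did not converge: achieved "
            f"{calibration.achieved_rates} vs targets {calibration.target_rates}"
        )
    return calibration


# ---------------------------------------------------------------------------
@dataclass
class BaselineExperimentResult:
    rates: pd.DataFrame  # circuit, condition, population, rate_hz
    psd_freqs: np.ndarray
    psds: dict[str, np.ndarray]  # condition label -> (n_circuits, n_freqs)
    stats: dict[str, StatResult]  # healthy-vs-condition Pyr-rate contrasts
    provenance: dict

    def mean_rate(self, condition: str, population: str) -> float:
        sub = self.rates[
            (self.rates["condition"] == condition)
            & (self.rates["population"] == population)
        ]
        return float(sub["rate_hz"].mean())

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rates.to_csv(out / "baseline_rates.csv", index=False)
        np.savetxt(out / "psd_freqs.csv", self.psd_freqs, delimiter=",")
        summary = {
            "stats": {k: dataclasses.asdict(v) for k, v in self.stats.items()},
            "provenance": self.provenance,
        }
        (out / "baseline_summary.json").write_text(json.dumps(summary, indent=2))


def run_baseline_experiment(
    exp: ExperimentConfig,
    ccfg: CircuitConfig | None = None,
    calibration: CalibrationResult | None = None,
) -> BaselineExperimentResult:
    """Baseline (resting) firing rates and EEG PSDs per condition."""

    ccfg = ccfg or default_config()
    n_circ = 30 if exp.paper_scale else exp.n_circuits
    calibration = ensure_calibration(ccfg, exp.master_seed, calibration, exp.force)
    factors = calibration.ou_factors
    head = FourSphereModel()
    k_z = head.potential_nV(np.array([0.0, 0.0, 1.0]))
    sim_p = ccfg.sim
    fs = 1e3 / sim_p.dt_ms
    t0, t1 = sim_p.transient_ms, sim_p.duration_resting_ms

    rows = []
    psds: dict[str, list] = {c.label: [] for c in exp.conditions}
    freqs = None
    for i in range(n_circ):
        circuit = build_circuit(ccfg, _seed_for(exp.master_seed, 1, i))
        run_seed = _seed_for(exp.master_seed, 2, i)
        for cond in exp.conditions:
            pc, _ = apply_condition(circuit, ccfg.tonic, cond)
            sim = run_simulation(pc, cond, None, sim_p.duration_resting_ms,
                                 seed=run_seed, ou_factors=factors)
            for pop, rate in sim.rates_by_type(t0, t1).items():
                rows.append((i, cond.label, pop, rate))
            eeg = k_z * sim.dipole_nAum[int(t0 / sim_p.dt_ms):]
            f, p = welch_psd(eeg, fs)
            freqs = f
            psds[cond.label].append(p)

    rates = pd.DataFrame(rows, columns=["circuit", "condition", "population", "rate_hz"])
    stats: dict[str, StatResult] = {}
    healthy_label = next((c.label for c in exp.conditions if c.is_healthy), None)
    if healthy_label is not None:
        h = rates[(rates["condition"] == healthy_label) & (rates["population"] == "Pyr")]
        for cond in exp.conditions:
            if cond.label == healthy_label:
                continue
            d = rates[(rates["condition"] == cond.label) & (rates["population"] == "Pyr")]
            stats[cond.label] = two_sample_ttest(h["rate_hz"], d["rate_hz"])

    result = BaselineExperimentResult(
        rates=rates,
        psd_freqs=freqs,
        psds={k: np.array(v) for k, v in psds.items()},
        stats=stats,
        provenance=_provenance(ccfg, exp, {"experiment": "baseline",
                                           "ou_factors": factors}),
    )
    if exp.out_dir:
        result.save(exp.out_dir)
    return result


# ---------------------------------------------------------------------------
@dataclass
class OddballExperimentResult:
    table: pd.DataFrame  # per circuit & condition: rates, snr, mmn, latency
    erps: dict[str, ERPTrace]  # condition -> mean difference ERP
    profiles: dict[str, np.ndarray]  # condition -> mean (3,) phase profile
    stats: dict[str, dict[str, StatResult]]
    provenance: dict

    def mean(self, condition: str, column: str) -> float:
        sub = self.table[self.table["condition"] == condition]
        return float(sub[column].mean())

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "oddball_table.csv", index=False)
        for label, erp in self.erps.items():
            pd.DataFrame({"time_ms": erp.time_ms, "amplitude_nV": erp.amplitude_nV}
                         ).to_csv(out / f"erp_diff_{label}.csv", index=False)
        summary = {
            "stats": {c: {k: dataclasses.asdict(v) for k, v in d.items()}
                      for c, d in self.stats.items()},
            "profiles": {k: list(v) for k, v in self.profiles.items()},
            "provenance": self.provenance,
        }
        (out / "oddball_summary.json").write_text(json.dumps(summary, indent=2))


def run_oddball_experiment(
    exp: ExperimentConfig,
    ccfg: CircuitConfig | None = None,
    calibration: CalibrationResult | None = None,
    protocol: OddballProtocol | None = None,
    stimulus_calibration: StimulusCalibration | None = None,
) -> OddballExperimentResult:
    """Seed-matched standard (baseline) and deviant runs per circuit:
    window firing rates, per-circuit SNR, difference ERPs and MMN."""

    ccfg = ccfg or default_config()
    n_circ = 50 if exp.paper_scale else exp.n_circuits
    calibration = ensure_calibration(ccfg, exp.master_seed, calibration, exp.force)
    factors = calibration.ou_factors
    protocol = protocol or OddballProtocol()
    if stimulus_calibration is not None:
        protocol = dataclasses.replace(protocol, scale=stimulus_calibration.scale)

    head = FourSphereModel()
    k_z = head.potential_nV(np.array([0.0, 0.0, 1.0]))
    sim_p = ccfg.sim
    fs = 1e3 / sim_p.dt_ms
    t0 = sim_p.stimulus_onset_ms
    w0, w1 = RESPONSE_WINDOW_MS

    rows = []
    erps: dict[str, list] = {c.label: [] for c in exp.conditions}
    profiles: dict[str, list] = {c.label: [] for c in exp.conditions}
    for i in range(n_circ):
        circuit = build_circuit(ccfg, _seed_for(exp.master_seed, 11, i))
        run_seed = _seed_for(exp.master_seed, 12, i)
        stim_seed = _seed_for(exp.master_seed, 13, i)
        for cond in exp.conditions:
            pc, _ = apply_condition(circuit, ccfg.tonic, cond)
            stim = build_oddball_stimulus(pc, protocol, cond, stim_seed, t0)
            standard = run_simulation(pc, cond, None, sim_p.duration_trial_ms,
                                      seed=run_seed, ou_factors=factors)
            deviant = run_simulation(pc, cond, stim, sim_p.duration_trial_ms,
                                     seed=run_seed, ou_factors=factors)
            r_std = standard.mean_rate("Pyr", t0 + w0, t0 + w1)
            r_odd = deviant.mean_rate("Pyr", t0 + w0, t0 + w1)
            snr = firing_snr(r_odd, r_std)
            erp_std = erp_preprocess(k_z * standard.dipole_nAum, fs, [t0])
            erp_odd = erp_preprocess(k_z * deviant.dipole_nAum, fs, [t0])
            diff = erp_odd - erp_std
            amp, lat = mmn_amplitude(diff)
            prof = response_profile(deviant, t0, ids=stim.attrs["stimulated"]["Pyr"])
            rows.append((i, cond.label, r_std, r_odd, snr, amp, lat))
            erps[cond.label].append(diff)
            profiles[cond.label].append(prof)

    table = pd.DataFrame(
        rows,
        columns=["circuit", "condition", "standard_rate_hz", "oddball_rate_hz",
                 "snr", "mmn_nV", "mmn_latency_ms"],
    )
    mean_erps = {
        label: ERPTrace(
            lst[0].time_ms.copy(),
            np.mean([e.amplitude_nV for e in lst], axis=0),
            lst[0].fs_hz,
            {"difference": True, "n_circuits": len(lst)},
        )
        for label, lst in erps.items()
    }
    stats: dict[str, dict[str, StatResult]] = {}
    healthy_label = next((c.label for c in exp.conditions if c.is_healthy), None)
    if healthy_label is not None:
        h = table[table["condition"] == healthy_label]
        for cond in exp.conditions:
            if cond.label == healthy_label:
                continue
            d = table[table["condition"] == cond.label]
            stats[cond.label] = {
                col: two_sample_ttest(h[col], d[col])
                for col in ("standard_rate_hz", "oddball_rate_hz", "snr", "mmn_nV")
            }
    result = OddballExperimentResult(
        table=table,
        erps=mean_erps,
        profiles={k: np.mean(v, axis=0) for k, v in profiles.items()},
        stats=stats,
        provenance=_provenance(ccfg, exp, {
            "experiment": "oddball",
            "ou_factors": factors,
            "stimulus_scale": protocol.scale,
        }),
    )
    if exp.out_dir:
        result.save(exp.out_dir)
    return result


# ---------------------------------------------------------------------------
@dataclass
class RestingComparisonResult:
    table: pd.DataFrame  # per circuit & condition: offset, exponent, powers, peak
    stats: dict[str, dict[str, StatResult]]
    percent_change: dict[str, dict[str, float]]
    provenance: dict

    def mean(self, condition: str, column: str) -> float:
        sub = self.table[self.table["condition"] == condition]
        return float(sub[column].mean(skipna=True))

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "resting_table.csv", index=False)
        summary = {
            "stats": {c: {k: dataclasses.asdict(v) for k, v in d.items()}
                      for c, d in self.stats.items()},
            "percent_change": self.percent_change,
            "provenance": self.provenance,
        }
        (out / "resting_summary.json").write_text(json.dumps(summary, indent=2))


def run_resting_comparison(
    exp: ExperimentConfig,
    ccfg: CircuitConfig | None = None,
    calibration: CalibrationResult | None = None,
) -> RestingComparisonResult:
    """Aperiodic/periodic PSD features of resting EEG per condition."""

    ccfg = ccfg or default_config()
    n_circ = 25 if exp.paper_scale else exp.n_circuits
    calibration = ensure_calibration(ccfg, exp.master_seed, calibration, exp.force)
    factors = calibration.ou_factors
    head = FourSphereModel()
    k_z = head.potential_nV(np.array([0.0, 0.0, 1.0]))
    sim_p = ccfg.sim
    fs = 1e3 / sim_p.dt_ms

    rows = []
    for i in range(n_circ):
        circuit = build_circuit(ccfg, _seed_for(exp.master_seed, 21, i))
        run_seed = _seed_for(exp.master_seed, 22, i)
        for cond in exp.conditions:
            pc, _ = apply_condition(circuit, ccfg.tonic, cond)
            sim = run_simulation(pc, cond, None, sim_p.duration_resting_ms,
                                 seed=run_seed, ou_factors=factors)
            eeg = k_z * sim.dipole_nAum[int(sim_p.transient_ms / sim_p.dt_ms):]
            f, p = welch_psd(eeg, fs)
            dec = fit_aperiodic_periodic(f, p)
            peak = peak_frequency(dec, PEAK_SEARCH_BAND)
            rows.append((
                i, cond.label, dec.offset, dec.exponent,
                band_power(dec, (3.0, 30.0), "aperiodic"),
                band_power(dec, "alpha", "raw"),
                band_power(dec, "low_beta", "raw"),
                band_power(dec, "beta", "raw"),
                band_power(dec, "alpha", "periodic"),
                band_power(dec, "low_beta", "periodic"),
                np.nan if peak is None else peak,
                len(dec.peaks),
            ))
    table = pd.DataFrame(
        rows,
        columns=["circuit", "condition", "offset", "exponent", "broadband_power",
                 "alpha_power", "low_beta_power", "beta_power",
                 "alpha_periodic_power", "low_beta_periodic_power",
                 "peak_frequency_hz", "n_peaks"],
    )
    metric_cols = [c for c in table.columns if c not in ("circuit", "condition")]
    stats: dict[str, dict[str, StatResult]] = {}
    pct: dict[str, dict[str, float]] = {}
    healthy_label = next((c.label for c in exp.conditions if c.is_healthy), None)
    if healthy_label is not None:
        h = table[table["condition"] == healthy_label]
        for cond in exp.conditions:
            if cond.label == healthy_label:
                continue
            d = table[table["condition"] == cond.label]
            stats[cond.label] = {}
            pct[cond.label] = {}
            for col in metric_cols:
                ha = h[col].dropna().to_numpy()
                da = d[col].dropna().to_numpy()
                if ha.size >= 2 and da.size >= 2:
                    stats[cond.label][col] = two_sample_ttest(ha, da)
                    if ha.mean() != 0:
                        pct[cond.label][col] = float(
                            100.0 * (da.mean() - ha.mean()) / abs(ha.mean())
                        )
    result = RestingComparisonResult(
        table=table,
        stats=stats,
        percent_change=pct,
        provenance=_provenance(ccfg, exp, {"experiment": "resting",
                                           "ou_factors": factors}),
    )
    if exp.out_dir:
        result.save(exp.out_dir)
    return result
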