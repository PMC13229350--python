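"""Network simulation driver: marshals a CircuitGraph into the compiled
kernel, runs it, and wraps the outputs.

Also hosts the background-drive calibration that brings population firing
rates to their target values by scaling the OU mean conductances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .circuit import CircuitGraph
from .conditions import HEALTHY, Condition
from .config import POPULATIONS, CircuitConfig
from .dynamics import double_exp_norm

__all__ = [
    "SimResult",
    "run_simulation",
    "calibrate_background",
    "CalibrationResult",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimResult:
    """Spike trains plus the aggregated current-dipole-moment time series of
    one simulation run.

    ``dipole_nAum`` is the z-component (radial, soma-minus-apical convention:
    a depolarized apical dendrite — an apical current sink — gives a negative
    moment, hence a negative potential at an overlying electrode).
    """

    spike_trains: dict[int, np.ndarray]
    dipole_nAum: np.ndarray
    dt_ms: float
    duration_ms: float
    condition: Condition
    seed_record: dict = field(default_factory=dict)
    neuron_types: pd.Series | None = None
    mean_vs: np.ndarray | None = None
    mean_va: np.ndarray | None = None

    def spike_counts(self, t_start: float, t_stop: float, ids=None) -> int:
        ids = self.spike_trains.keys() if ids is None else ids
        total = 0
        for i in ids:
            tr = self.spike_trains.get(int(i))
            if tr is not None and tr.size:
                total += int(np.searchsorted(tr, t_stop) - np.searchsorted(tr, t_start))
        return total

    def mean_rate(self, population: str | None = None, t_start: float | None = None,
                  t_stop: float | None = None, ids=None) -> float:
        """Population-mean firing rate in Hz over [t_start, t_stop) ms."""

        if t_start is None:
            t_start = 0.0
        if t_stop is None:
            t_stop = self.duration_ms
        if ids is None:
            if population is None:
                ids = np.arange(len(self.neuron_types))
            else:
                ids = np.flatnonzero((self.neuron_types == population).to_numpy())
        n = len(ids)
        if n == 0 or t_stop <= t_start:
            return float("nan")
        count = self.spike_counts(t_start, t_stop, ids)
        return count / (n * (t_stop - t_start) * 1e-3)

    def rates_by_type(self, t_start: float, t_stop: float) -> dict[str, float]:
        return {p: self.mean_rate(p, t_start, t_stop)
                for p in POPULATIONS if (self.neuron_types == p).any()}

    def spikes_dataframe(self) -> pd.DataFrame:
        rows_id, rows_t = [], []
        for i, tr in sorted(self.spike_trains.items()):
            rows_id.append(np.full(tr.size, i, dtype=int))
            rows_t.append(tr)
        if not rows_id:
            return pd.DataFrame({"neuron_id": [], "time_ms": []})
        return pd.DataFrame(
            {"neuron_id": np.concatenate(rows_id), "time_ms": np.concatenate(rows_t)}
        )


def _marshal_params(circuit: CircuitGraph, condition: Condition):
    cfg = circuit.config
    types = circuit.neurons["type"].to_numpy()
    n = len(types)
    cols = {}
    for name in ("C_m", "g_L", "E_L", "V_T", "delta_T", "V_reset", "a", "b",
                 "tau_w", "t_ref", "V_peak", "area_cm2", "C_a", "g_La", "g_c",
                 "d_um", "area_apical_cm2"):
        cols[name] = np.array(
            [getattr(cfg.neuron_params[t], name) for t in types], dtype=float
        )
    is_pyr = (types == "Pyr").astype(np.uint8)

    # tonic: density -> nS, attributed to PV (somatic share) and SST (apical
    # share) on Pyr; mixed by the configured attribution on interneurons
    tn = cfg.tonic
    g_density = tn.G_tonic * 1e6  # nS per cm^2
    pv_keep = 1.0 - condition.pv_output_reduction
    sst_keep = 1.0 - condition.sst_reduction
    mixed_keep = tn.pv_fraction * pv_keep + tn.sst_fraction * sst_keep
    g_tonic_soma = np.where(
        is_pyr == 1,
        g_density * cols["area_cm2"] * pv_keep,
        g_density * cols["area_cm2"] * mixed_keep,
    )
    g_tonic_apical = np.where(
        is_pyr == 1, g_density * cols["area_apical_cm2"] * sst_keep, 0.0
    )
    return cols, is_pyr, g_tonic_soma, g_tonic_apical


def _marshal_ou(circuit: CircuitGraph, ou_factors: dict[str, float] | None):
    cfg = circuit.config
    types = circuit.neurons["type"].to_numpy()
    n = len(types)
    ou = cfg.ou
    factors = {p: 1.0 for p in POPULATIONS}
    if ou_factors:
        factors.update(ou_factors)
    mu_s = np.array(
        [ou.base_pS[t] * ou.scale.get(t, 1.0) * factors[t] * 1e-3 for t in types]
    )  # nS
    # per-neuron excitability spread: lognormal factor on the OU mean (unit
    # mean), tied to the circuit's placement seed so it is part of the
    # randomized-microcircuit identity, not of the simulation run
    cv = ou.heterogeneity_cv
    if cv > 0:
        het_seed = circuit.seed_record.get("placement", 0)
        het_rng = np.random.default_rng(np.random.SeedSequence([int(het_seed), 0x4E7]))
        sigma_ln = np.sqrt(np.log(1.0 + cv * cv))
        het = het_rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, size=n)
        mu_s = mu_s * het
    sd_s = ou.sigma_frac * mu_s
    # the apical processes (base conductance scaled by exp(x_rel) at each
    # placement fraction) share one correlation time, so their sum is itself
    # an OU process; simulate the exact equivalent: mu = sum(mu_i),
    # sd = sqrt(sum(sd_i^2))
    mu_a = np.zeros((n, 1))
    sd_a = np.zeros((n, 1))
    pyr_mask = types == "Pyr"
    apical_gain = np.exp(np.asarray(ou.apical_fractions))
    base = (cfg.ou.base_pS["Pyr"] * ou.scale.get("Pyr", 1.0) * factors["Pyr"]
            * ou.apical_scale * 1e-3)
    het_pyr = het[pyr_mask] if cv > 0 else 1.0
    mu_a[pyr_mask, 0] = base * apical_gain.sum() * het_pyr
    sd_a[pyr_mask, 0] = ou.sigma_frac * base * np.sqrt((apical_gain**2).sum()) * het_pyr
    return mu_s, sd_s, mu_a, sd_a


def _marshal_edges(circuit: CircuitGraph):
    n = circuit.n_neurons
    e = circuit.edges
    if len(e) == 0:
        return (np.zeros(n + 1, dtype=np.int64),) + tuple(
            np.zeros(0, dtype=d) for d in (np.int64, float, float, float, np.uint8)
        )
    pre = e["pre"].to_numpy(dtype=np.int64)
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    out_idx = e["post"].to_numpy(dtype=np.int64)[order]
    out_gA = e["g_ampa_nS"].to_numpy(dtype=float)[order]
    out_gN = e["g_nmda_nS"].to_numpy(dtype=float)[order]
    out_gG = e["g_gaba_nS"].to_numpy(dtype=float)[order]
    out_ap = (e["compartment"].to_numpy()[order] == "apical").astype(np.uint8)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_ptr, pre + 1, 1)
    out_ptr = np.cumsum(out_ptr)
    return out_ptr, out_idx, out_gA, out_gN, out_gG, out_ap


def _marshal_stimulus(stimulus, dt: float, n_steps: int):
    """Stimulus = DataFrame with columns target, time_ms, g_ampa_nS,
    g_nmda_nS, g_gaba_nS, apical (see oddball.build_oddball_stimulus)."""

    if stimulus is None or len(stimulus) == 0:
        z = np.zeros(0)
        return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                z, z, z, np.zeros(0, dtype=np.uint8))
    steps = np.round(stimulus["time_ms"].to_numpy() / dt).astype(np.int64)
    keep = (steps >= 0) & (steps < n_steps)
    steps = steps[keep]
    order = np.argsort(steps, kind="stable")
    sub = stimulus.loc[keep].iloc[order]
    return (
        steps[order],
        sub["target"].to_numpy(dtype=np.int64),
        sub["g_ampa_nS"].to_numpy(dtype=float),
        sub["g_nmda_nS"].to_numpy(dtype=float),
        sub["g_gaba_nS"].to_numpy(dtype=float),
        sub["apical"].to_numpy().astype(np.uint8),
    )


def run_simulation(
    circuit: CircuitGraph,
    condition: Condition = HEALTHY,
    stimulus: pd.DataFrame | None = None,
    duration_ms: float | None = None,
    dt_ms: float | None = None,
    seed: int = 0,
    ou_factors: dict[str, float] | None = None,
) -> SimResult:
    """Integrate the circuit under a condition and optional stimulus.

    ``circuit`` should already carry any condition-dependent edge scaling
    (see :func:`pfceeg.conditions.apply_condition`); ``condition`` is used
    here for the tonic-conductance attribution and recorded in the result.
    Identical inputs and seed give bit-identical results.
    """

    cfg = circuit.config
    dt = cfg.sim.dt_ms if dt_ms is None else dt_ms
    if not (0 < dt <= 0.1):
        raise ValueError("dt must be in (0, 0.1] ms")
    duration = cfg.sim.duration_resting_ms if duration_ms is None else duration_ms
    n_steps = int(round(duration / dt))
    kin = cfg.kinetics

    cols, is_pyr, g_ton_s, g_ton_a = _marshal_params(circuit, condition)
    mu_s, sd_s, mu_a, sd_a = _marshal_ou(circuit, ou_factors)
    out = _marshal_edges(circuit)
    stim = _marshal_stimulus(stimulus, dt, n_steps)

    delay_steps = max(1, int(round(kin.delay_ms / dt)))
    ou_every = max(1, int(round(cfg.ou.update_every_ms / dt)))
    kernel_seed = int(np.random.SeedSequence([seed, 0xC1BC]).generate_state(1)[0] % (2**31))

    n = circuit.n_neurons
    spike_cap = int(n * duration * 1e-3 * 100) + 100_000
    spike_id = np.zeros(spike_cap, dtype=np.int64)
    spike_t = np.zeros(spike_cap)
    dipole = np.zeros(n_steps)
    mean_vs = np.zeros(n_steps)
    mean_va = np.zeros(n_steps)

    status, n_spikes, bad_neuron, bad_time = _kernel.integrate(
        n_steps, dt, delay_steps, ou_every, kernel_seed,
        cols["C_m"], cols["g_L"], cols["E_L"], cols["V_T"], cols["delta_T"],
        cols["V_reset"], cols["a"], cols["b"], cols["tau_w"],
        np.maximum(1, np.round(cols["t_ref"] / dt)).astype(np.int64), cols["V_peak"],
        is_pyr, cols["C_a"], cols["g_La"], cols["g_c"], cols["d_um"],
        g_ton_s, g_ton_a, cfg.tonic.V50, cfg.tonic.k, kin.E_inh,
        mu_s, sd_s, mu_a, sd_a, cfg.ou.tau_ms, cfg.ou.tau_apical_ms,
        math.exp(-dt / kin.tau_rise_ampa), math.exp(-dt / kin.tau_decay_ampa),
        math.exp(-dt / kin.tau_rise_nmda), math.exp(-dt / kin.tau_decay_nmda),
        math.exp(-dt / kin.tau_rise_gaba), math.exp(-dt / kin.tau_decay_gaba),
        double_exp_norm(kin.tau_rise_ampa, kin.tau_decay_ampa),
        double_exp_norm(kin.tau_rise_nmda, kin.tau_decay_nmda),
        double_exp_norm(kin.tau_rise_gaba, kin.tau_decay_gaba),
        kin.mg_mM / 3.57,
        *out, *stim,
        spike_id, spike_t, dipole, mean_vs, mean_va,
    )
    if status == _kernel.STATUS_DIVERGED:
        raise IntegrationError(
            f"integration diverged (|V| > 200 mV) at neuron {bad_neuron}, "
            f"t = {bad_time:.3f} ms"
        )
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise IntegrationError("spike buffer overflow; circuit is pathologically active")

    trains: dict[int, np.ndarray] = {}
    sid = spike_id[:n_spikes]
    st = spike_t[:n_spikes]
    order = np.lexsort((st, sid))
    sid, st = sid[order], st[order]
    bounds = np.searchsorted(sid, np.arange(n + 1))
    for i in range(n):
        lo, hi = bounds[i], bounds[i + 1]
        if hi > lo:
            trains[i] = st[lo:hi].copy()
        else:
            trains[i] = np.zeros(0)

    return SimResult(
        spike_trains=trains,
        dipole_nAum=dipole * 1e-3,  # pA*um -> nA*um
        dt_ms=dt,
        duration_ms=duration,
        condition=condition,
        seed_record={**circuit.seed_record, "simulation": kernel_seed, "run_seed": seed},
        neuron_types=circuit.neurons["type"],
        mean_vs=mean_vs,
        mean_va=mean_va,
    )


@dataclass
class CalibrationResult:
    ou_factors: dict[str, float]
    synaptic_factors: dict[str, float]
    achieved_rates: dict[str, float]
    target_rates: dict[str, float]
    converged: bool
    n_iterations: int


DEFAULT_TARGET_RATES = {"Pyr": 0.94, "PV": 7.44, "SST": 3.28, "VIP": 2.22}


def calibrate_background(
    circuit: CircuitGraph | list[CircuitGraph],
    target_rates: dict[str, float] | None = None,
    tolerance: float = 0.15,
    max_rounds: int = 3,
    max_bisect: int = 4,
    seed: int = 0,
    duration_ms: float = 2000.0,
) -> CalibrationResult:
    """Scale the per-population OU mean conductances until mean firing rates
    match the targets within ``tolerance`` (relative).

    Coordinate-wise search: an outer loop over populations, each adjusted by
    multiplicative bracketing/bisection of its own OU factor (rate is
    monotone in own drive) while the others are held fixed.  Cross-couplings
    are handled by repeating the outer loop up to ``max_rounds`` times.
    Passing a list of circuits calibrates against their pooled rates, which
    averages out circuit-to-circuit excitability differences.
    Non-convergence returns the best factors seen with ``converged=False``
    (never silently).
    """

    circuits = circuit if isinstance(circuit, list) else [circuit]
    targets = dict(DEFAULT_TARGET_RATES if target_rates is None else target_rates)
    if any(v <= 0 for v in targets.values()):
        raise ValueError("target rates must be positive")
    cfg = circuits[0].config
    transient = cfg.sim.transient_ms
    factors = {p: 1.0 for p in targets}
    order = [p for p in ("PV", "SST", "VIP", "Pyr") if p in targets]
    order += [p for p in targets if p not in order]

    n_evals = 0

    def rates_for(f: dict[str, float]) -> dict[str, float]:
        nonlocal n_evals
        n_evals += 1
        per_circuit = []
        for k, circ in enumerate(circuits):
            try:
                res = run_simulation(
                    circ, HEALTHY, None, duration_ms, None,
                    seed=int(np.random.SeedSequence([seed, n_evals, k])
                             .generate_state(1)[0] % (2**31)),
                    ou_factors=f,
                )
            except IntegrationError:
                # runaway activity: report huge rates so the search backs off
                per_circuit.append({p: 1e6 for p in targets})
                continue
            per_circuit.append(res.rates_by_type(transient, duration_ms))
        return {p: float(np.mean([r.get(p, 0.0) for r in per_circuit]))
                for p in per_circuit[0]}

    def worst_err(rates: dict[str, float]) -> float:
        return max(abs(rates.get(p, 0.0) - t) / t for p, t in targets.items())

    achieved = rates_for(factors)
    best_factors, best_rates = dict(factors), dict(achieved)
    converged = worst_err(achieved) <= tolerance
    rounds = 0
    while not converged and rounds < max_rounds:
        rounds += 1
        for p in order:
            # population gain is steep (supralinear), so bracket narrowly
            # around the current factor and expand only on demand
            lo, hi = factors[p] * 0.67, factors[p] * 1.5
            for _ in range(max_bisect):
                r = achieved.get(p, 0.0)
                tgt = targets[p]
                if abs(r - tgt) / tgt <= tolerance * 0.67:
                    break
                if r < tgt:
                    lo = factors[p]
                    if hi <= lo * 1.02:
                        hi = lo * 1.5
                else:
                    hi = factors[p]
                    if lo >= hi * 0.98:
                        lo = hi * 0.67
                factors[p] = float(np.sqrt(lo * hi))
                achieved = rates_for(factors)
                if worst_err(achieved) < worst_err(best_rates):
                    best_factors, best_rates = dict(factors), dict(achieved)
        achieved = rates_for(factors)
        if worst_err(achieved) < worst_err(best_rates):
            best_factors, best_rates = dict(factors), dict(achieved)
        converged = worst_err(achieved) <= tolerance
    if converged:
        best_factors, best_rates = dict(factors), dict(achieved)
    return CalibrationResult(
        ou_factors=best_factors,
        synaptic_factors={p: 1.0 for p in targets},
        achieved_rates=best_rates,
        target_rates=targets,
        converged=converged,
        n_iterations=n_evals,
    )
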