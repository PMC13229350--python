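"""Reduced conductance-based dynamics primitives.

These are the closed-form building blocks of the integrator: the
Jahr–Stevens NMDA magnesium block, normalized double-exponential synaptic
gating, outward-rectifying tonic inhibition, exact-discretization
Ornstein–Uhlenbeck background conductance, and the distance scaling of the
apical OU drive.  The full network integration lives in
:mod:`pfceeg.simulate`.
"""

from __future__ import annotations

import numpy as np

from .config import SynapseKinetics, TonicInhibitionParams

__all__ = [
    "mg_block",
    "double_exp_peak_time",
    "double_exp_norm",
    "synaptic_gating",
    "tonic_current",
    "ou_exact_coefficients",
    "ou_conductance_step",
    "scale_ou_with_distance",
]


def mg_block(V, mg_mM: float = 1.0):
    """Fraction of NMDA conductance unblocked at membrane potential ``V`` (mV).

    Jahr–Stevens sigmoid 1 / (1 + ([Mg]/3.57) * exp(-0.062 V)); rises
    monotonically from 0 (hyperpolarized) to 1 (depolarized).
    """

    if mg_mM < 0:
        raise ValueError("mg_mM must be >= 0")
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + (mg_mM / 3.57) * np.exp(-0.062 * V))


def double_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of exp(-t/tau_decay) - exp(-t/tau_rise), ms."""

    return (
        np.log(tau_decay / tau_rise)
        * tau_rise
        * tau_decay
        / (tau_decay - tau_rise)
    )


def double_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalization factor so a unit event peaks at exactly 1."""

    t_peak = double_exp_peak_time(tau_rise, tau_decay)
    return 1.0 / (np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise))


def synaptic_gating(
    event_times,
    kinetics: SynapseKinetics,
    receptor: str,
    t,
    peak_conductance: float = 1.0,
):
    """Conductance waveform g(t) from a set of presynaptic events.

    Each event contributes a peak-normalized double exponential of amplitude
    ``peak_conductance``; events superpose linearly.  Unordered event times
    are sorted internally.  ``receptor`` is one of "ampa", "nmda", "gaba".
    """

    receptor = receptor.lower()
    tau_r = getattr(kinetics, f"tau_rise_{receptor}")
    tau_d = getattr(kinetics, f"tau_decay_{receptor}")
    norm = double_exp_norm(tau_r, tau_d)
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    for t0 in np.sort(np.asarray(event_times, dtype=float)):
        dt = t - t0
        active = dt >= 0
        g[active] += norm * (np.exp(-dt[active] / tau_d) - np.exp(-dt[active] / tau_r))
    return peak_conductance * g


def tonic_current(V, params: TonicInhibitionParams, area_cm2: float):
    """Outward-rectifying tonic inhibition current in pA (positive = outward).

    I = G_tonic * area * sigma(V) * (V - E_rev), with sigma a rising logistic
    (more conductance open at depolarized potentials).  G_tonic is mS/cm^2;
    the product G_tonic*area*1e6 is in nS, so nS * mV = pA.
    """

    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    V = np.asarray(V, dtype=float)
    g_max_nS = params.G_tonic * area_cm2 * 1e6
    sigma = 1.0 / (1.0 + np.exp(-(V - params.V50) / params.k))
    return g_max_nS * sigma * (V - params.E_rev)


def ou_exact_coefficients(dt: float, tau: float, sigma: float):
    """Exact-discretization OU update coefficients (rho, noise_scale):
    g' = mu + rho*(g - mu) + noise_scale * xi,  xi ~ N(0,1)."""

    if dt <= 0:
        raise ValueError("dt must be positive")
    rho = np.exp(-dt / tau)
    noise = sigma * np.sqrt(1.0 - rho * rho)
    return rho, noise


def ou_conductance_step(g, dt: float, mu: float, sigma: float, tau: float, rng):
    """One exact OU step; the returned conductance is clipped at 0.

    Stationary mean ``mu`` and SD ``sigma`` (before clipping).
    """

    rho, noise = ou_exact_coefficients(dt, tau, sigma)
    g = np.asarray(g, dtype=float)
    xi = rng.standard_normal(size=g.shape if g.shape else None)
    return np.maximum(0.0, mu + rho * (g - mu) + noise * xi)


def scale_ou_with_distance(g_base_pS: float, x_rel: float) -> float:
    """Distance scaling of the apical OU drive: g = g_base * exp(x_rel),
    with x_rel the relative distance from the soma in [0, 1]."""

    if not (0.0 <= x_rel <= 1.0):
        raise ValueError("x_rel must be in [0, 1]")
    return g_base_pS * float(np.exp(x_rel))
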