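"""Numba-compiled network integrator.

Fixed-step integration: forward Euler for membrane voltages, exponential
Euler for the double-exponential receptor states (each receptor is a pair of
rise/decay exponentials; conductance = decay - rise), exact-discretization
OU background conductances updated on a coarser substep, a fixed synaptic
delay implemented as a ring buffer, and event-driven stimulus injection.

All quantities are in mV, ms, nS, pA, pF.  The per-step circuit dipole
moment is accumulated as sum over Pyr cells of g_c * (V_soma - V_apical) *
d_um (pA*um; the wrapper converts to nA*um).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_SPIKE_OVERFLOW = 2


@njit(cache=True, fastmath=True)
def integrate(
    # sizes / timing
    n_steps, dt, delay_steps, ou_every, seed,
    # per-neuron parameters
    Cs, gL, EL, VT, DT, Vre, a_w, b_w, tau_w, t_ref_steps, V_peak,
    is_pyr, Ca, gLa, gc, d_um,
    # tonic (effective max conductance nS per compartment, after condition)
    g_tonic_soma, g_tonic_apical, tonic_V50, tonic_k, E_inh,
    # OU (nS): somatic mean/SD, apical mean/SD per process (n, n_ap)
    ou_mu_s, ou_sd_s, ou_mu_a, ou_sd_a, ou_tau, ou_tau_a,
    # synaptic kinetics: per-receptor decay factors for rise/decay states
    fA_r, fA_d, fN_r, fN_d, fG_r, fG_d, normA, normN, normG, mg_factor,
    # connectivity CSR (sorted by presynaptic id)
    out_ptr, out_idx, out_gA, out_gN, out_gG, out_apical,
    # stimulus events (sorted by step)
    stim_step, stim_target, stim_gA, stim_gN, stim_gG, stim_apical,
    # outputs
    spike_id, spike_t, dipole, mean_vs, mean_va,
):
    np.random.seed(seed)
    n = Cs.size
    n_ap = ou_mu_a.shape[1]

    # state
    Vs = EL.copy()
    Va = EL.copy()
    w = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    sA_r = np.zeros(n); sA_d = np.zeros(n)
    sN_r = np.zeros(n); sN_d = np.zeros(n)
    sG_r = np.zeros(n); sG_d = np.zeros(n)
    aA_r = np.zeros(n); aA_d = np.zeros(n)
    aN_r = np.zeros(n); aN_d = np.zeros(n)
    aG_r = np.zeros(n); aG_d = np.zeros(n)
    ou_s = ou_mu_s.copy()
    ou_a = ou_mu_a.copy()

    inv_Cs = 1.0 / Cs
    inv_Ca = np.where(Ca > 0, 1.0 / np.maximum(Ca, 1e-12), 0.0)
    inv_tau_w = 1.0 / tau_w
    inv_DT = 1.0 / DT
    inv_tonic_k = 1.0 / tonic_k

    # OU exact-update coefficients on the coarse substep
    dt_ou = dt * ou_every
    rho = np.exp(-dt_ou / ou_tau)
    ou_noise = np.sqrt(1.0 - rho * rho)
    rho_a = np.exp(-dt_ou / ou_tau_a)
    ou_noise_a = np.sqrt(1.0 - rho_a * rho_a)

    # ring buffer for delayed spike delivery
    ring = np.zeros((delay_steps, n), dtype=np.int64)
    ring_count = np.zeros(delay_steps, dtype=np.int64)

    spike_cap = spike_id.size
    n_spikes = 0
    stim_ptr = 0
    n_stim = stim_step.size

    for step in range(n_steps):
        slot = step % delay_steps

        # 1. deliver spikes emitted delay_steps ago
        for k in range(ring_count[slot]):
            j = ring[slot, k]
            for e in range(out_ptr[j], out_ptr[j + 1]):
                tgt = out_idx[e]
                if out_apical[e]:
                    aA_r[tgt] += normA * out_gA[e]
                    aA_d[tgt] += normA * out_gA[e]
                    aN_r[tgt] += normN * out_gN[e]
                    aN_d[tgt] += normN * out_gN[e]
                    aG_r[tgt] += normG * out_gG[e]
                    aG_d[tgt] += normG * out_gG[e]
                else:
                    sA_r[tgt] += normA * out_gA[e]
                    sA_d[tgt] += normA * out_gA[e]
                    sN_r[tgt] += normN * out_gN[e]
                    sN_d[tgt] += normN * out_gN[e]
                    sG_r[tgt] += normG * out_gG[e]
                    sG_d[tgt] += normG * out_gG[e]
        ring_count[slot] = 0

        # 2. stimulus events scheduled for this step
        while stim_ptr < n_stim and stim_step[stim_ptr] == step:
            tgt = stim_target[stim_ptr]
            if stim_apical[stim_ptr]:
                aA_r[tgt] += normA * stim_gA[stim_ptr]
                aA_d[tgt] += normA * stim_gA[stim_ptr]
                aN_r[tgt] += normN * stim_gN[stim_ptr]
                aN_d[tgt] += normN * stim_gN[stim_ptr]
                aG_r[tgt] += normG * stim_gG[stim_ptr]
                aG_d[tgt] += normG * stim_gG[stim_ptr]
            else:
                sA_r[tgt] += normA * stim_gA[stim_ptr]
                sA_d[tgt] += normA * stim_gA[stim_ptr]
                sN_r[tgt] += normN * stim_gN[stim_ptr]
                sN_d[tgt] += normN * stim_gN[stim_ptr]
                sG_r[tgt] += normG * stim_gG[stim_ptr]
                sG_d[tgt] += normG * stim_gG[stim_ptr]
            stim_ptr += 1

        # 3. OU update on the coarse substep
        if step % ou_every == 0:
            for i in range(n):
                if ou_mu_s[i] > 0.0:
                    g = ou_mu_s[i] + rho * (ou_s[i] - ou_mu_s[i]) \
                        + ou_sd_s[i] * ou_noise * np.random.normal(0.0, 1.0)
                    ou_s[i] = g if g > 0.0 else 0.0
                for j in range(n_ap):
                    if ou_mu_a[i, j] > 0.0:
                        g = ou_mu_a[i, j] + rho_a * (ou_a[i, j] - ou_mu_a[i, j]) \
                            + ou_sd_a[i, j] * ou_noise_a * np.random.normal(0.0, 1.0)
                        ou_a[i, j] = g if g > 0.0 else 0.0

        # 4. integrate neurons
        dip = 0.0
        acc_vs = 0.0
        acc_va = 0.0
        n_pyr = 0
        for i in range(n):
            # exponential-Euler decay of the receptor states
            sA_r[i] *= fA_r; sA_d[i] *= fA_d
            sN_r[i] *= fN_r; sN_d[i] *= fN_d
            sG_r[i] *= fG_r; sG_d[i] *= fG_d
            Vsi = Vs[i]
            gA = sA_d[i] - sA_r[i]
            gN = sN_d[i] - sN_r[i]
            gG = sG_d[i] - sG_r[i]
            block = 1.0 / (1.0 + mg_factor * np.exp(-0.062 * Vsi))
            I_syn = gA * Vsi + gN * block * Vsi + gG * (Vsi - E_inh)
            sig = 1.0 / (1.0 + np.exp(-(Vsi - tonic_V50) * inv_tonic_k))
            I_ton = g_tonic_soma[i] * sig * (Vsi - E_inh)
            I_ou = ou_s[i] * Vsi
            I_couple = 0.0

            if is_pyr[i]:
                aA_r[i] *= fA_r; aA_d[i] *= fA_d
                aN_r[i] *= fN_r; aN_d[i] *= fN_d
                aG_r[i] *= fG_r; aG_d[i] *= fG_d
                Vai = Va[i]
                gAa = aA_d[i] - aA_r[i]
                gNa = aN_d[i] - aN_r[i]
                gGa = aG_d[i] - aG_r[i]
                block_a = 1.0 / (1.0 + mg_factor * np.exp(-0.062 * Vai))
                I_syn_a = gAa * Vai + gNa * block_a * Vai + gGa * (Vai - E_inh)
                sig_a = 1.0 / (1.0 + np.exp(-(Vai - tonic_V50) * inv_tonic_k))
                I_ton_a = g_tonic_apical[i] * sig_a * (Vai - E_inh)
                g_ou_a = 0.0
                for j in range(n_ap):
                    g_ou_a += ou_a[i, j]
                I_ou_a = g_ou_a * Vai
                I_couple = gc[i] * (Vai - Vsi)  # into the soma
                dVa = (
                    -gLa[i] * (Vai - EL[i]) - I_syn_a - I_ton_a - I_ou_a
                    - gc[i] * (Vai - Vsi)
                ) * inv_Ca[i]
                Va[i] = Vai + dt * dVa
                # dipole from the inter-compartment potential gradient; the
                # somatic action-potential excursion is clamped at threshold
                # (the reduced soma's spike waveform is not a dipole source)
                Vs_dip = Vsi if Vsi < VT[i] else VT[i]
                dip += gc[i] * (Vs_dip - Vai) * d_um[i]
                acc_va += Vai
                acc_vs += Vsi
                n_pyr += 1

            if ref[i] > 0:
                ref[i] -= 1
                Vs[i] = Vre[i]
                w[i] += dt * (a_w[i] * (Vre[i] - EL[i]) - w[i]) * inv_tau_w[i]
            else:
                ex_arg = (Vsi - VT[i]) * inv_DT[i]
                if ex_arg > 20.0:
                    ex_arg = 20.0
                I_exp = gL[i] * DT[i] * np.exp(ex_arg)
                dVs = (
                    -gL[i] * (Vsi - EL[i]) + I_exp - w[i]
                    - I_syn - I_ton - I_ou + I_couple
                ) * inv_Cs[i]
                Vs[i] = Vsi + dt * dVs
                w[i] += dt * (a_w[i] * (Vsi - EL[i]) - w[i]) * inv_tau_w[i]
                if Vs[i] >= V_peak[i]:
                    if n_spikes >= spike_cap:
                        return STATUS_SPIKE_OVERFLOW, n_spikes, -1, -1.0
                    spike_id[n_spikes] = i
                    spike_t[n_spikes] = step * dt
                    n_spikes += 1
                    Vs[i] = Vre[i]
                    w[i] += b_w[i]
                    ref[i] = t_ref_steps[i]
                    ring[slot, ring_count[slot]] = i
                    ring_count[slot] += 1
                if Vs[i] < -200.0 or (Vs[i] > 200.0):
                    return STATUS_DIVERGED, n_spikes, i, step * dt

        dipole[step] = dip
        if n_pyr > 0:
            mean_vs[step] = acc_vs / n_pyr
            mean_va[step] = acc_va / n_pyr

    return STATUS_OK, n_spikes, -1, -1.0
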