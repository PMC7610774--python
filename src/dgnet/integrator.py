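"""Numba-compiled integration kernels for single neurons and populations.

The kernels operate on packed float64 parameter vectors (one per neuron)
and state vectors; :func:`dgnet.neuron.pack_model` produces the parameter
layout.  Integration uses exponential Euler for gating variables and
forward Euler for voltage and cytosolic calcium (default dt = 25 us, i.e.
0.025 ms).

Layout of the packed parameter vector (length ``NP``)::

    0 area_cm2   1 C_m (uF/cm2)   2 g_leak (S/cm2)   3 e_leak (mV)
    4..12  maximal conductances (S/cm2) / permeabilities (cm/s) in the
           order NaF, KDR, KA, HCN, SK, BK, CaT, CaN, CaL
    13 E_Na  14 E_K  15 E_HCN (mV)
    16..81 eleven gates x (v_half, slope, tau_min, tau_amp, tau_vhalf,
           tau_slope), gate order as dgnet.kinetics.GATES
    82..84 SK (kd_mM, hill, tau_ms)
    85..89 BK (kd_mM, hill, v_half, slope, tau_ms)
    90 tau_Ca (ms)  91 shell depth (um)  92 [Ca]_inf (mM)
    93 calcium influx denominator constant (default 3.6)
    94 [Ca]_out (mM)  95 RT/F (mV)

State vector (length ``NS``): v (mV), [Ca]_c (mM), 11 gate variables,
SK gate, BK gate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import FARADAY

NP = 96
NS = 15

IDX_AREA, IDX_CM, IDX_GL, IDX_EL = 0, 1, 2, 3
IDX_G0 = 4            # 9 conductance/permeability slots
IDX_ENA, IDX_EK, IDX_EH = 13, 14, 15
IDX_GATE0 = 16        # 11 gates x 6 parameters
IDX_SK = 82
IDX_BK = 85
IDX_TAUCA, IDX_DPT, IDX_CAINF, IDX_CADEN, IDX_CAOUT, IDX_VT = 90, 91, 92, 93, 94, 95

# minimum cytosolic calcium (mM); keeps the GHK log arguments positive
_CA_FLOOR = 1e-7


@njit(cache=False, fastmath=True)
def _xinf(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(v - vh) / k))


@njit(cache=False, fastmath=True)
def _tauv(v, tmin, tamp, tvh, tk):
    return tmin + tamp / (1.0 + np.exp((v - tvh) / tk))


@njit(cache=False, fastmath=True)
def _ghk(v, p, z, cin, cout, vt):
    """GHK current density, mA/cm^2, outward positive (concentrations mM)."""
    w = v / vt
    u = z * w
    if u < 1e-4 and u > -1e-4:
        b = z * (cin - cout) + z * z * w * 0.5 * (cin + cout)
    else:
        e = np.exp(-u)
        b = z * z * w * (cin - cout * e) / (1.0 - e)
    return 1e-3 * p * FARADAY * b


@njit(cache=False, fastmath=True)
def _membrane_currents(p, s):
    """Total outward membrane current density and its calcium component."""
    v = s[0]
    ca = s[1]
    i = p[IDX_GL] * (v - p[IDX_EL])
    i += p[4] * s[2] * s[2] * s[2] * s[3] * (v - p[IDX_ENA])      # NaF m3h
    i += p[5] * s[4] * s[4] * (v - p[IDX_EK])                     # KDR n2
    i += p[6] * s[5] * s[6] * (v - p[IDX_EK])                     # KA ab
    i += p[7] * s[7] * (v - p[IDX_EH])                            # HCN
    i += p[8] * s[13] * (v - p[IDX_EK])                           # SK
    i += p[9] * s[14] * (v - p[IDX_EK])                           # BK
    vt = p[IDX_VT]
    cao = p[IDX_CAOUT]
    ica = _ghk(v, p[10] * s[8] * s[8] * s[9], 2.0, ca, cao, vt)   # CaT m2h
    ica += _ghk(v, p[11] * s[10] * s[10] * s[11], 2.0, ca, cao, vt)  # CaN m2h
    ica += _ghk(v, p[12] * s[12] * s[12], 2.0, ca, cao, vt)       # CaL m2
    return i + ica, ica


@njit(cache=False, fastmath=True)
def _update_gates(p, s, dt):
    v = s[0]
    ca = s[1]
    for g in range(11):
        b = IDX_GATE0 + 6 * g
        xinf = _xinf(v, p[b], p[b + 1])
        tau = _tauv(v, p[b + 2], p[b + 3], p[b + 4], p[b + 5])
        s[2 + g] += (xinf - s[2 + g]) * (1.0 - np.exp(-dt / tau))
    # SK: calcium-only gating
    cah = ca ** p[IDX_SK + 1]
    sinf = cah / (cah + p[IDX_SK] ** p[IDX_SK + 1])
    s[13] += (sinf - s[13]) * (1.0 - np.exp(-dt / p[IDX_SK + 2]))
    # BK: calcium x voltage gating
    cah = ca ** p[IDX_BK + 1]
    binf = cah / (cah + p[IDX_BK] ** p[IDX_BK + 1]) * _xinf(v, p[IDX_BK + 2], p[IDX_BK + 3])
    s[14] += (binf - s[14]) * (1.0 - np.exp(-dt / p[IDX_BK + 4]))


@njit(cache=False, fastmath=True)
def _step(p, s, i_inj_pA, i_syn_density, dt):
    """Advance one neuron by dt (ms).

    ``i_inj_pA`` is a depolarizing-positive absolute current (injected +
    afferent, pA); ``i_syn_density`` an outward-positive current density
    (mA/cm^2) from receptor currents.
    """
    itot, ica = _membrane_currents(p, s)
    itot += i_syn_density
    ica_total = ica  # receptor currents carry no calcium here (AMPA: Na/K)
    inj = i_inj_pA * 1e-9 / p[IDX_AREA]
    dv = 1000.0 * (inj - itot) / p[IDX_CM]
    dca = (-10000.0 * ica_total / (p[IDX_CADEN] * p[IDX_DPT] * FARADAY)
           + (p[IDX_CAINF] - s[1]) / p[IDX_TAUCA])
    _update_gates(p, s, dt)
    s[0] += dt * dv
    s[1] += dt * dca
    if s[1] < _CA_FLOOR:
        s[1] = _CA_FLOOR


@njit(cache=False, fastmath=True)
def _init_state(p, v0):
    s = np.zeros(NS)
    s[0] = v0
    s[1] = p[IDX_CAINF]
    for g in range(11):
        b = IDX_GATE0 + 6 * g
        s[2 + g] = _xinf(v0, p[b], p[b + 1])
    cah = s[1] ** p[IDX_SK + 1]
    s[13] = cah / (cah + p[IDX_SK] ** p[IDX_SK + 1])
    cah = s[1] ** p[IDX_BK + 1]
    s[14] = cah / (cah + p[IDX_BK] ** p[IDX_BK + 1]) * _xinf(v0, p[IDX_BK + 2], p[IDX_BK + 3])
    return s


# voltage outside this band marks a numerically exploded model
_V_ABORT = 500.0


@njit(cache=False, fastmath=True)
def _run(p, s, i_ext_pA, dt, record):
    n = i_ext_pA.shape[0]
    if record:
        v_out = np.empty(n)
    else:
        v_out = np.empty(0)
    for t in range(n):
        _step(p, s, i_ext_pA[t], 0.0, dt)
        if record:
            v_out[t] = s[0]
        if t % 128 == 0 and not (-_V_ABORT < s[0] < _V_ABORT):
            s[0] = np.nan
            if record:
                v_out[t:] = np.nan
            break
    return v_out


@njit(cache=False, fastmath=True)
def _run_const(p, s, amp_pA, n_steps, dt):
    """Run with constant input, recording v; returns the voltage trace."""
    v_out = np.empty(n_steps)
    for t in range(n_steps):
        _step(p, s, amp_pA, 0.0, dt)
        v_out[t] = s[0]
        if t % 128 == 0 and not (-_V_ABORT < s[0] < _V_ABORT):
            s[0] = np.nan
            v_out[t:] = np.nan
            break
    return v_out


@njit(cache=False, fastmath=True)
def _settle(p, s, n_steps, dt):
    for t in range(n_steps):
        _step(p, s, 0.0, 0.0, dt)
        if t % 128 == 0 and not (-_V_ABORT < s[0] < _V_ABORT):
            s[0] = np.nan
            break


@njit(cache=False, fastmath=True)
def _run_ca_only(p, ca0, n_steps, dt):
    """Integrate the cytosolic calcium ODE alone with I_Ca = 0."""
    out = np.empty(n_steps)
    ca = ca0
    for t in range(n_steps):
        ca += dt * (p[IDX_CAINF] - ca) / p[IDX_TAUCA]
        out[t] = ca
    return out


@njit(cache=False, fastmath=True)
def _count_spikes(v, dt, threshold, refractory_ms):
    """Upward threshold crossings with a refractory hold; returns times (ms)."""
    n = v.shape[0]
    times = np.empty(n // max(1, int(refractory_ms / dt)) + 1)
    count = 0
    last = -1e18
    for t in range(1, n):
        if v[t] >= threshold and v[t - 1] < threshold:
            tm = t * dt
            if tm - last >= refractory_ms:
                times[count] = tm
                count += 1
                last = tm
    return times[:count]


@njit(cache=False, fastmath=True)
def _run_network(params, states, dt, n_steps, steps_per_ms, aff_pA,
                 syn_post, syn_perm, syn_gaba,
                 out_indptr, out_synidx,
                 tau_r, tau_d, a_norm,
                 na_in, na_out, k_in, k_out, cl_in, cl_out,
                 spike_n, spike_t,
                 v_thresh, refractory_ms):
    """Co-integrate a population with double-exponential GHK synapses.

    Synapse gates are per-synapse pairs (A, B) decaying with tau_d/tau_r;
    a presynaptic spike increments both, s = clip(a_norm (A - B), 0, 1).
    Receptor currents use the GHK equation with the aggregate permeability
    of all active synapses onto each neuron.  Returns the number of
    recorded spikes, or -1 if the integration lost finiteness.
    """
    N = params.shape[0]
    S = syn_post.shape[0]
    max_spikes = spike_n.shape[0]
    A = np.zeros(S)
    B = np.zeros(S)
    dec_d = np.exp(-dt / tau_d)
    dec_r = np.exp(-dt / tau_r)
    last_spike = np.full(N, -1e18)
    p_ampa = np.zeros(N)
    p_gaba = np.zeros(N)
    nsp = 0
    for t in range(n_steps):
        ms = t // steps_per_ms
        for n in range(N):
            p_ampa[n] = 0.0
            p_gaba[n] = 0.0
        for j in range(S):
            A[j] *= dec_d
            B[j] *= dec_r
            sg = a_norm * (A[j] - B[j])
            if sg > 1.0:
                sg = 1.0
            elif sg < 0.0:
                sg = 0.0
            if syn_gaba[j] == 1:
                p_gaba[syn_post[j]] += syn_perm[j] * sg
            else:
                p_ampa[syn_post[j]] += syn_perm[j] * sg
        t_ms = t * dt
        for n in range(N):
            p = params[n]
            s = states[n]
            vt = p[IDX_VT]
            i_syn = 0.0
            if p_ampa[n] > 0.0:
                i_syn += _ghk(s[0], p_ampa[n], 1.0, na_in, na_out, vt)
                i_syn += _ghk(s[0], p_ampa[n], 1.0, k_in, k_out, vt)
            if p_gaba[n] > 0.0:
                i_syn += _ghk(s[0], p_gaba[n], -1.0, cl_in, cl_out, vt)
            v_prev = s[0]
            _step(p, s, aff_pA[n, ms], i_syn, dt)
            if not (-_V_ABORT < s[0] < _V_ABORT):
                return -1 - n
            if s[0] >= v_thresh and v_prev < v_thresh and t_ms - last_spike[n] >= refractory_ms:
                last_spike[n] = t_ms
                if nsp < max_spikes:
                    spike_n[nsp] = n
                    spike_t[nsp] = t_ms
                    nsp += 1
                for k in range(out_indptr[n], out_indptr[n + 1]):
                    jj = out_synidx[k]
                    A[jj] += 1.0
                    B[jj] += 1.0
        if t % 40000 == 0:
            ok = True
            for n in range(N):
                if not np.isfinite(states[n][0]):
                    ok = False
            if not ok:
                return -1
    for n in range(N):
        if not np.isfinite(states[n][0]):
            return -1
    return nsp


@njit(cache=False)
def _random_walk(n_ms, x0, y0, step_min, step_max, seed):
    """Bounded random walk in the unit arena; steps in metres per ms."""
    np.random.seed(seed)
    xs = np.empty(n_ms)
    ys = np.empty(n_ms)
    x = x0
    y = y0
    for t in range(n_ms):
        while True:
            ang = np.random.uniform(0.0, 2.0 * np.pi)
            step = np.random.uniform(step_min, step_max)
            nx = x + step * np.cos(ang)
            ny = y + step * np.sin(ang)
            if 0.0 <= nx <= 1.0 and 0.0 <= ny <= 1.0:
                break
        x = nx
        y = ny
        xs[t] = x
        ys[t] = y
    return xs, ys
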