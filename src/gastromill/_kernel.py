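"""Flat fixed-step integrator for the four-neuron gastric mill circuit.

The composable primitives in :mod:`gastromill.core` define the semantics
(exponential-Euler gating, forward-Euler voltage, outward-positive
currents); this module is the same scheme unrolled over the whole network
in a single numba-compiled loop so that a 100 s simulation at dt = 0.05 ms
runs in seconds.  Parameters are passed as one float64 vector addressed by
the index constants below; the mapping from a CircuitConfig is done in
:mod:`gastromill.circuit`.

LG's leak (plus any dynamic-clamp terms sharing its reversal) arrives
pre-fused as a linear form ``I = A*V - B``: this makes "clamp +delta with
E = E_leak" bit-identical to "g_leak + delta", and makes simultaneous
+delta/-delta clamps cancel exactly.
"""

import math

import numpy as np
from numba import njit

PARAM_NAMES = (
    # LG
    "LG_C", "LG_LEAK_A", "LG_LEAK_B", "LG_EL",
    "LG_GNA", "LG_GK", "LG_ENA", "LG_EK", "LG_SHNA", "LG_SHK",
    # modulator-induced current on LG (conductance gated by terminal transmitter)
    "MI_G", "MI_V0", "MI_S", "MI_TAU", "MI_E",
    # Int1
    "I1_C", "I1_GL", "I1_EL",
    "I1_GNA", "I1_GK", "I1_ENA", "I1_EK", "I1_SHNA", "I1_SHK",
    # MCN1 soma/axon
    "MC_C", "MC_GL", "MC_EL",
    "MC_GNA", "MC_GK", "MC_ENA", "MC_EK", "MC_SHNA", "MC_SHK",
    # MCN1 terminal compartment and its transmitter dynamics
    "TM_C", "TM_GL", "TM_EL",
    "AX_G", "AX_E", "AX_VTH", "AX_K", "AX_TAU",
    "T_VTH", "T_K", "T_RISE_RATE", "T_TAU_DECAY",
    # AB
    "AB_C", "AB_GL", "AB_EL",
    # graded synapses: (g_max, E_rev, V_th, k, tau) each
    "S_I1LG_G", "S_I1LG_E", "S_I1LG_VTH", "S_I1LG_K", "S_I1LG_TAU",
    "S_LGI1_G", "S_LGI1_E", "S_LGI1_VTH", "S_LGI1_K", "S_LGI1_TAU",
    "S_LGTM_G", "S_LGTM_E", "S_LGTM_VTH", "S_LGTM_K", "S_LGTM_TAU",
    "S_ABI1_G", "S_ABI1_E", "S_ABI1_VTH", "S_ABI1_K", "S_ABI1_TAU",
    "S_MCI1_G", "S_MCI1_E", "S_MCI1_VTH", "S_MCI1_K", "S_MCI1_TAU",
    # electrical coupling terminal <-> LG
    "GAP_G",
    # drives
    "MC_PERIOD_MS", "MC_PULSE_MS", "MC_PULSE_PA", "AB_F_HZ", "AB_AMP_PA",
    # spike detection
    "SPK_THR", "SPK_LOCKOUT_MS",
)

for _i, _name in enumerate(PARAM_NAMES):
    globals()[_name] = _i
N_PARAMS = len(PARAM_NAMES)

# trace rows
ROW_LG, ROW_INT1, ROW_MCN1, ROW_TERM, ROW_AB, ROW_T = 0, 1, 2, 3, 4, 5
N_ROWS = 6


@njit(cache=True)
def _linoid(x, k):
    r = x / k
    if abs(r) < 1e-7:
        return k * (1.0 + 0.5 * r)
    return x / -math.expm1(-r)


@njit(cache=True)
def _sig(v, vth, k):
    return 1.0 / (1.0 + math.exp(-(v - vth) / k))


@njit(cache=True)
def integrate(p, dt, n_steps, stride, vout, spk_lg, spk_i1, spk_mc):
    """Integrate the network for n_steps of dt (ms).

    vout: (6, n_rec) trace buffer sampled every `stride` steps (ignored when
    stride == 0).  spk_*: preallocated spike-time buffers (ms).  Returns
    (diverged_step, n_lg, n_i1, n_mc); diverged_step is -1 on success.
    """
    # --- unpack state initial conditions ------------------------------
    vlg = p[LG_EL]
    vi1 = p[I1_EL]
    vmc = p[MC_EL]
    vtm = p[TM_EL]
    vab = p[AB_EL]

    # gating at steady state for the initial voltages
    u = vlg - p[LG_SHNA]
    am = 0.1 * _linoid(u + 40.0, 10.0)
    bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    mlg = am / (am + bm)
    hlg = ah / (ah + bh)
    u = vlg - p[LG_SHK]
    an = 0.01 * _linoid(u + 55.0, 10.0)
    bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
    nlg = an / (an + bn)

    u = vi1 - p[I1_SHNA]
    am = 0.1 * _linoid(u + 40.0, 10.0)
    bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    mi1 = am / (am + bm)
    hi1 = ah / (ah + bh)
    u = vi1 - p[I1_SHK]
    an = 0.01 * _linoid(u + 55.0, 10.0)
    bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
    ni1 = an / (an + bn)

    u = vmc - p[MC_SHNA]
    am = 0.1 * _linoid(u + 40.0, 10.0)
    bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    mmc = am / (am + bm)
    hmc = ah / (ah + bh)
    u = vmc - p[MC_SHK]
    an = 0.01 * _linoid(u + 55.0, 10.0)
    bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
    nmc = an / (an + bn)

    ami = _sig(vlg, p[MI_V0], -p[MI_S])  # s = -10 -> increasing sigmoid
    T = 0.0
    s_i1lg = _sig(vi1, p[S_I1LG_VTH], p[S_I1LG_K])
    s_lgi1 = _sig(vlg, p[S_LGI1_VTH], p[S_LGI1_K])
    s_lgtm = _sig(vlg, p[S_LGTM_VTH], p[S_LGTM_K])
    s_abi1 = _sig(vab, p[S_ABI1_VTH], p[S_ABI1_K])
    s_mci1 = _sig(vmc, p[S_MCI1_VTH], p[S_MCI1_K])
    s_ax = _sig(vmc, p[AX_VTH], p[AX_K])

    # precomputed relaxation factors for fixed-tau states
    k_mi = -math.expm1(-dt / p[MI_TAU])
    dT_up = dt * p[T_RISE_RATE]  # zero-order replenishment, fraction per ms
    k_td = -math.expm1(-dt / p[T_TAU_DECAY])
    k_i1lg = -math.expm1(-dt / p[S_I1LG_TAU])
    k_lgi1 = -math.expm1(-dt / p[S_LGI1_TAU])
    k_lgtm = -math.expm1(-dt / p[S_LGTM_TAU])
    k_abi1 = -math.expm1(-dt / p[S_ABI1_TAU])
    k_mci1 = -math.expm1(-dt / p[S_MCI1_TAU])
    k_ax = -math.expm1(-dt / p[AX_TAU])

    two_pi_f = 2.0e-3 * math.pi * p[AB_F_HZ]  # rad per ms

    thr = p[SPK_THR]
    lockout = p[SPK_LOCKOUT_MS]
    n_lg = 0
    n_i1 = 0
    n_mc = 0
    last_lg = -1.0e12
    last_i1 = -1.0e12
    last_mc = -1.0e12
    cap_lg = spk_lg.shape[0]
    cap_i1 = spk_i1.shape[0]
    cap_mc = spk_mc.shape[0]

    if stride > 0:
        vout[ROW_LG, 0] = vlg
        vout[ROW_INT1, 0] = vi1
        vout[ROW_MCN1, 0] = vmc
        vout[ROW_TERM, 0] = vtm
        vout[ROW_AB, 0] = vab
        vout[ROW_T, 0] = T

    for i in range(n_steps):
        t = i * dt

        # drives
        i_mc = p[MC_PULSE_PA] if t % p[MC_PERIOD_MS] < p[MC_PULSE_MS] else 0.0
        i_ab = p[AB_AMP_PA] * math.sin(two_pi_f * t)

        # graded synapse and transmitter relaxation (pre-step voltages)
        s_i1lg += (_sig(vi1, p[S_I1LG_VTH], p[S_I1LG_K]) - s_i1lg) * k_i1lg
        s_lgi1 += (_sig(vlg, p[S_LGI1_VTH], p[S_LGI1_K]) - s_lgi1) * k_lgi1
        s_lgtm += (_sig(vlg, p[S_LGTM_VTH], p[S_LGTM_K]) - s_lgtm) * k_lgtm
        s_abi1 += (_sig(vab, p[S_ABI1_VTH], p[S_ABI1_K]) - s_abi1) * k_abi1
        s_mci1 += (_sig(vmc, p[S_MCI1_VTH], p[S_MCI1_K]) - s_mci1) * k_mci1
        s_ax += (_sig(vmc, p[AX_VTH], p[AX_K]) - s_ax) * k_ax
        tinf = _sig(vtm, p[T_VTH], p[T_K])
        if tinf > T:
            T = min(tinf, T + dT_up)
        else:
            T += (tinf - T) * k_td
        ami += (_sig(vlg, p[MI_V0], -p[MI_S]) - ami) * k_mi

        # LG gating
        u = vlg - p[LG_SHNA]
        am = 0.1 * _linoid(u + 40.0, 10.0)
        bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
        tau = 1.0 / (am + bm)
        mlg += (am * tau - mlg) * -math.expm1(-dt / tau)
        tau = 1.0 / (ah + bh)
        hlg += (ah * tau - hlg) * -math.expm1(-dt / tau)
        u = vlg - p[LG_SHK]
        an = 0.01 * _linoid(u + 55.0, 10.0)
        bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
        tau = 1.0 / (an + bn)
        nlg += (an * tau - nlg) * -math.expm1(-dt / tau)

        # Int1 gating
        u = vi1 - p[I1_SHNA]
        am = 0.1 * _linoid(u + 40.0, 10.0)
        bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
        tau = 1.0 / (am + bm)
        mi1 += (am * tau - mi1) * -math.expm1(-dt / tau)
        tau = 1.0 / (ah + bh)
        hi1 += (ah * tau - hi1) * -math.expm1(-dt / tau)
        u = vi1 - p[I1_SHK]
        an = 0.01 * _linoid(u + 55.0, 10.0)
        bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
        tau = 1.0 / (an + bn)
        ni1 += (an * tau - ni1) * -math.expm1(-dt / tau)

        # MCN1 soma gating
        u = vmc - p[MC_SHNA]
        am = 0.1 * _linoid(u + 40.0, 10.0)
        bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
        tau = 1.0 / (am + bm)
        mmc += (am * tau - mmc) * -math.expm1(-dt / tau)
        tau = 1.0 / (ah + bh)
        hmc += (ah * tau - hmc) * -math.expm1(-dt / tau)
        u = vmc - p[MC_SHK]
        an = 0.01 * _linoid(u + 55.0, 10.0)
        bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
        tau = 1.0 / (an + bn)
        nmc += (an * tau - nmc) * -math.expm1(-dt / tau)

        # membrane currents (outward positive) and voltage updates
        i_lg = (p[LG_LEAK_A] * vlg - p[LG_LEAK_B]
                + p[LG_GNA] * mlg * mlg * mlg * hlg * (vlg - p[LG_ENA])
                + p[LG_GK] * nlg * nlg * nlg * nlg * (vlg - p[LG_EK])
                + p[MI_G] * T * ami * (vlg - p[MI_E])
                + p[S_I1LG_G] * s_i1lg * (vlg - p[S_I1LG_E])
                + p[GAP_G] * (vlg - vtm))
        i_i1 = (p[I1_GL] * (vi1 - p[I1_EL])
                + p[I1_GNA] * mi1 * mi1 * mi1 * hi1 * (vi1 - p[I1_ENA])
                + p[I1_GK] * ni1 * ni1 * ni1 * ni1 * (vi1 - p[I1_EK])
                + p[S_LGI1_G] * s_lgi1 * (vi1 - p[S_LGI1_E])
                + p[S_ABI1_G] * s_abi1 * (vi1 - p[S_ABI1_E])
                + p[S_MCI1_G] * s_mci1 * (vi1 - p[S_MCI1_E]))
        i_mc_mem = (p[MC_GL] * (vmc - p[MC_EL])
                    + p[MC_GNA] * mmc * mmc * mmc * hmc * (vmc - p[MC_ENA])
                    + p[MC_GK] * nmc * nmc * nmc * nmc * (vmc - p[MC_EK]))
        i_tm = (p[TM_GL] * (vtm - p[TM_EL])
                + p[AX_G] * s_ax * (vtm - p[AX_E])
                + p[S_LGTM_G] * s_lgtm * (vtm - p[S_LGTM_E])
                + p[GAP_G] * (vtm - vlg))
        i_abm = p[AB_GL] * (vab - p[AB_EL])

        vlg_new = vlg + dt * (-i_lg) / p[LG_C]
        vi1_new = vi1 + dt * (-i_i1) / p[I1_C]
        vmc_new = vmc + dt * (i_mc - i_mc_mem) / p[MC_C]
        vtm_new = vtm + dt * (-i_tm) / p[TM_C]
        vab_new = vab + dt * (i_ab - i_abm) / p[AB_C]

        t_new = t + dt
        if vlg < thr <= vlg_new and t_new - last_lg >= lockout:
            if n_lg < cap_lg:
                spk_lg[n_lg] = t_new
            n_lg += 1
            last_lg = t_new
        if vi1 < thr <= vi1_new and t_new - last_i1 >= lockout:
            if n_i1 < cap_i1:
                spk_i1[n_i1] = t_new
            n_i1 += 1
            last_i1 = t_new
        if vmc < thr <= vmc_new and t_new - last_mc >= lockout:
            if n_mc < cap_mc:
                spk_mc[n_mc] = t_new
            n_mc += 1
            last_mc = t_new

        vlg = vlg_new
        vi1 = vi1_new
        vmc = vmc_new
        vtm = vtm_new
        vab = vab_new

        if stride > 0 and (i + 1) % stride == 0:
            j = (i + 1) // stride
            vout[ROW_LG, j] = vlg
            vout[ROW_INT1, j] = vi1
            vout[ROW_MCN1, j] = vmc
            vout[ROW_TERM, j] = vtm
            vout[ROW_AB, j] = vab
            vout[ROW_T, j] = T

        if (i & 4095) == 0:
            s = vlg + vi1 + vmc + vtm + vab
            if not math.isfinite(s) or abs(vlg) > 500.0 or abs(vi1) > 500.0:
                return i, n_lg, n_i1, n_mc

    return -1, n_lg, n_i1, n_mc
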