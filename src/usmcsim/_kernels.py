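"""Compiled numerical core: gating tables, current densities, ODE right-hand
side and fixed-step integrators.

Everything here operates on flat float64 vectors laid out per
:mod:`usmcsim._layout`.  The public modules (:mod:`usmcsim.currents`,
:mod:`usmcsim.model`, ...) wrap these kernels with typed interfaces; tests
cross-check the scalar wrappers against these compiled paths.

Unit system: mV, ms, mM, pA/pF, mM/ms.  Current densities are positive
outward; an inward Ca current therefore carries a negative sign and raises
intracellular Ca.
"""

import math

import numpy as np
from numba import njit

from ._layout import *  # noqa: F401,F403 - index constants S_*, P_*, C_*

# ---------------------------------------------------------------------------
# derived-constant vector (precomputed once per simulation)
# ---------------------------------------------------------------------------
DERIVED_NAMES = (
    "rt_f", "e_k", "e_na", "e_cl", "e_h", "e_ns",
    "ns_fcat", "ns_fmg", "ns_wca",
    "nak_scale",                      # inak_max * f_Na(Na_i) * f_K(K_o) * Q10 scale
    "nak_sigma",
    "jmem_factor", "jncx_factor",
)
NDERIVED = len(DERIVED_NAMES)
_g = globals()
for _i, _n in enumerate(DERIVED_NAMES):
    _g["D_" + _n.upper()] = _i
del _g, _i, _n

FLAG_OK = 0
FLAG_UNSTABLE = 1
FLAG_NONFINITE = 2


@njit(cache=True)
def safe_exp(x):
    if x > 700.0:
        x = 700.0
    elif x < -700.0:
        x = -700.0
    return math.exp(x)


@njit(cache=True)
def boltzmann_k(v, vh, k):
    # numerically stable logistic; k<0 flips orientation (inactivation)
    return 0.5 * (1.0 + math.tanh((v - vh) / (2.0 * k)))


@njit(cache=True)
def hill_act_k(x, km, n):
    if x <= 0.0:
        return 0.0
    r = n * (math.log(km) - math.log(x))
    return 1.0 / (1.0 + safe_exp(r))


@njit(cache=True)
def hill_inh_k(x, km, n):
    if x <= 0.0:
        return 1.0
    r = n * (math.log(x) - math.log(km))
    return 1.0 / (1.0 + safe_exp(r))


@njit(cache=True)
def _bell(v, base, amp, vc, k):
    z = (v - vc) / k
    return base + amp / (1.0 + z * z)


@njit(cache=True)
def ghk_current_sum(v, rt_f, perms, zs, c_in, c_out):
    """Sum of GHK constant-field flux terms (arbitrary units) over species."""
    tot = 0.0
    for i in range(perms.shape[0]):
        z = zs[i]
        u = z * v / rt_f
        if abs(u) < 1.0e-9:
            # limit of u/(1-e^-u) -> 1
            tot += perms[i] * z * (c_in[i] - c_out[i])
        else:
            e = safe_exp(-u)
            tot += perms[i] * z * u * (c_in[i] - c_out[i] * e) / (1.0 - e)
    return tot


@njit(cache=True)
def ghk_reversal_bisect(rt_f, perms, zs, c_in, c_out):
    """Zero-current potential of a multi-ion GHK conductance (mV)."""
    lo, hi = -400.0, 400.0
    flo = ghk_current_sum(lo, rt_f, perms, zs, c_in, c_out)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = ghk_current_sum(mid, rt_f, perms, zs, c_in, c_out)
        if (fm > 0.0) == (flo > 0.0):
            lo = mid
            flo = fm
        else:
            hi = mid
        if hi - lo < 1.0e-12:
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def derived_from_params(p):
    d = np.empty(NDERIVED)
    rt_f = p[P_GAS_CONST] * p[P_TEMPERATURE] / p[P_FARADAY]
    d[D_RT_F] = rt_f
    d[D_E_K] = rt_f * math.log(p[P_K_O] / p[P_K_I])
    d[D_E_NA] = rt_f * math.log(p[P_NA_O] / p[P_NA_I])
    d[D_E_CL] = -rt_f * math.log(p[P_CL_O] / p[P_CL_I])

    # I_h reversal: GHK over Na and K with permeability ratio P_Na/P_K
    perms = np.empty(2)
    zs = np.empty(2)
    cin = np.empty(2)
    cout = np.empty(2)
    perms[0] = p[P_H_PNA_PK]
    perms[1] = 1.0
    zs[0] = 1.0
    zs[1] = 1.0
    cin[0] = p[P_NA_I]
    cin[1] = p[P_K_I]
    cout[0] = p[P_NA_O]
    cout[1] = p[P_K_O]
    d[D_E_H] = ghk_reversal_bisect(rt_f, perms, zs, cin, cout)

    # NSCC reversal: GHK over Na, K and Ca (resting Ca_i; the Ca term is
    # negligible for the reversal but included for completeness)
    perms3 = np.empty(3)
    zs3 = np.empty(3)
    cin3 = np.empty(3)
    cout3 = np.empty(3)
    perms3[0] = p[P_NS_PNA]
    perms3[1] = p[P_NS_PK]
    perms3[2] = p[P_NS_PCA]
    zs3[0] = 1.0
    zs3[1] = 1.0
    zs3[2] = 2.0
    cin3[0] = p[P_NA_I]
    cin3[1] = p[P_K_I]
    cin3[2] = 1.0e-4
    cout3[0] = p[P_NA_O]
    cout3[1] = p[P_K_O]
    cout3[2] = p[P_CA_O]
    d[D_E_NS] = ghk_reversal_bisect(rt_f, perms3, zs3, cin3, cout3)

    # NSCC constant modulation factors (extracellular concentrations fixed)
    cat_o = p[P_NA_O] + p[P_K_O]
    d[D_NS_FCAT] = hill_act_k(cat_o, p[P_NS_KM_CAT], p[P_NS_N_CAT])
    d[D_NS_FMG] = hill_inh_k(p[P_MG_O], p[P_NS_KM_MG], p[P_NS_N_MG])
    wsum = (p[P_NS_PNA] * p[P_NA_O] + p[P_NS_PK] * p[P_K_O]
            + p[P_NS_PCA] * p[P_CA_O])
    d[D_NS_WCA] = p[P_NS_PCA] * p[P_CA_O] / wsum

    # Na-K pump: saturating Na_i / K_o factors and Q10 temperature scale
    fna = hill_act_k(p[P_NA_I], p[P_NAK_KM_NA], p[P_NAK_N_NA])
    fk = hill_act_k(p[P_K_O], p[P_NAK_KM_K], p[P_NAK_N_K])
    tscale = p[P_NAK_Q10] ** ((p[P_TEMPERATURE] - p[P_NAK_TREF]) / 10.0)
    d[D_NAK_SCALE] = p[P_INAK_MAX] * fna * fk * tscale
    d[D_NAK_SIGMA] = (math.exp(p[P_NA_O] / 67.3) - 1.0) / 7.0

    # pA/pF -> mM/ms conversion for membrane Ca fluxes
    conv = 1.0e-3 * p[P_ALPHA_FREE] * p[P_AV_RATIO] * p[P_CM] / p[P_FARADAY]
    d[D_JMEM_FACTOR] = conv / 2.0     # z_Ca = 2
    d[D_JNCX_FACTOR] = conv           # one Ca per elementary charge
    return d


# ---------------------------------------------------------------------------
# gating steady states and time constants
# ---------------------------------------------------------------------------
@njit(cache=True)
def gate_tables(v, ca, p, yinf, tau):
    """Fill steady-state and time-constant arrays for the 19 gates + force."""
    # L-type Ca: d, f1, f2
    yinf[0] = boltzmann_k(v, p[P_CAL_VH_D], p[P_CAL_K_D])
    tau[0] = _bell(v, p[P_CAL_TAUD_BASE], p[P_CAL_TAUD_AMP],
                   p[P_CAL_TAUD_VC], p[P_CAL_TAUD_K])
    finf = boltzmann_k(v, p[P_CAL_VH_F], -p[P_CAL_K_F])
    yinf[1] = finf
    tau[1] = p[P_CAL_TAU_F1]
    yinf[2] = finf
    tau[2] = p[P_CAL_TAUF2_MAX] - _bell(v, 0.0, p[P_CAL_TAUF2_AMP],
                                        p[P_CAL_TAUF2_VC], p[P_CAL_TAUF2_K])
    # Na: m, h
    yinf[3] = boltzmann_k(v, p[P_NA_VH_M], p[P_NA_K_M])
    tau[3] = p[P_NA_TAUM_BASE] + p[P_NA_TAUM_AMP] / (
        1.0 + safe_exp((v - p[P_NA_TAUM_VC]) / p[P_NA_TAUM_K]))
    yinf[4] = boltzmann_k(v, p[P_NA_VH_H], -p[P_NA_K_H])
    tau[4] = p[P_NA_TAUH_BASE] + p[P_NA_TAUH_AMP] / (
        1.0 + safe_exp((v - p[P_NA_TAUH_VC]) / p[P_NA_TAUH_K]))
    # T-type Ca: b, g
    yinf[5] = boltzmann_k(v, p[P_CAT_VH_B], p[P_CAT_K_B])
    tau[5] = _bell(v, p[P_CAT_TAUB_BASE], p[P_CAT_TAUB_AMP],
                   p[P_CAT_TAUB_VC], p[P_CAT_TAUB_K])
    gmin = p[P_CAT_G_MIN]
    yinf[6] = gmin + (1.0 - gmin) * boltzmann_k(v, p[P_CAT_VH_G],
                                                -p[P_CAT_K_G])
    tmax = p[P_CAT_TAUG_MAX]
    tau[6] = tmax - tmax / (
        (1.0 + safe_exp((v - p[P_CAT_TAUG_V1]) / p[P_CAT_TAUG_K1]))
        * (1.0 + safe_exp(-(v - p[P_CAT_TAUG_V2]) / p[P_CAT_TAUG_K2])))
    if tau[6] < 0.5:
        tau[6] = 0.5
    # I_h: y
    yinf[7] = boltzmann_k(v, p[P_H_VH_Y], -p[P_H_K_Y])
    tau[7] = 1.0 / (p[P_H_TAUY_A] * safe_exp(-p[P_H_TAUY_KA] * v)
                    + p[P_H_TAUY_B] * safe_exp(p[P_H_TAUY_KB] * v))
    # I_K1: q, r1, r2
    yinf[8] = p[P_K1_Q_MAX] * boltzmann_k(v, p[P_K1_VH_Q], p[P_K1_K_Q])
    tau[8] = _bell(v, 15.0, p[P_K1_TAUQ_AMP], p[P_K1_TAUQ_VC], p[P_K1_TAUQ_K])
    rinf = boltzmann_k(v, p[P_K1_VH_R], -p[P_K1_K_R])
    yinf[9] = rinf
    tau[9] = _bell(v, 300.0, p[P_K1_TAUR1_AMP],
                   p[P_K1_TAUR1_VC], p[P_K1_TAUR1_K])
    yinf[10] = rinf
    tau[10] = _bell(v, 3000.0, p[P_K1_TAUR2_AMP],
                    p[P_K1_TAUR2_VC], p[P_K1_TAUR2_K])
    # I_K2: p_gate, k1, k2
    yinf[11] = boltzmann_k(v, p[P_K2_VH_P], p[P_K2_K_P])
    tau[11] = _bell(v, 20.0, p[P_K2_TAUP_AMP], p[P_K2_TAUP_VC], p[P_K2_TAUP_K])
    kinf = boltzmann_k(v, p[P_K2_VH_K], -p[P_K2_K_K])
    yinf[12] = kinf
    tau[12] = _bell(v, 1000.0, p[P_K2_TAUK1_AMP],
                    p[P_K2_TAUK1_VC], p[P_K2_TAUK1_K])
    yinf[13] = kinf
    tau[13] = p[P_K2_TAUK2]
    # I_KA: s, x
    yinf[14] = boltzmann_k(v, p[P_KA_VH_S], p[P_KA_K_S])
    tau[14] = _bell(v, 1.0, p[P_KA_TAUS_AMP], p[P_KA_TAUS_VC], p[P_KA_TAUS_K])
    xmin = p[P_KA_X_MIN]
    yinf[15] = xmin + (1.0 - xmin) * boltzmann_k(v, p[P_KA_VH_X], -p[P_KA_K_X])
    tau[15] = _bell(v, p[P_KA_TAUX_BASE], p[P_KA_TAUX_AMP],
                    p[P_KA_TAUX_VC], p[P_KA_TAUX_K])
    # BK: xa, xab  (Ca-dependent half-activation and gating charge)
    rt_f = p[P_GAS_CONST] * p[P_TEMPERATURE] / p[P_FARADAY]
    logca = math.log10(max(ca, 1.0e-7))
    vha = p[P_BKA_VH0] + p[P_BKA_VH_SLOPE] * logca
    za = p[P_BKA_Z0] + p[P_BKA_ZSLOPE] * logca
    yinf[16] = 1.0 / (1.0 + safe_exp(-za * (v - vha) / rt_f))
    btau = p[P_BK_TAU_BASE] + p[P_BK_TAU_AMP] / (
        1.0 + safe_exp((v - p[P_BK_TAU_VC]) / p[P_BK_TAU_K]))
    tau[16] = btau
    vhab = p[P_BKAB_VH0] + p[P_BKAB_VH_SLOPE] * logca
    zab = p[P_BKAB_Z0] + p[P_BKAB_ZSLOPE] * logca
    yinf[17] = 1.0 / (1.0 + safe_exp(-zab * (v - vhab) / rt_f))
    tau[17] = btau
    # I_Cl(Ca): c  (steady state joint in Ca and V; tau voltage-only)
    kd = p[P_CL_KD0] * safe_exp(-v / p[P_CL_KDK])
    yinf[18] = hill_act_k(ca, kd, p[P_CL_N])
    tau[18] = p[P_CL_TAU_BASE] + p[P_CL_TAU_AMP] / (
        1.0 + safe_exp((v - p[P_CL_TAU_VC]) / p[P_CL_TAU_K]))
    # force: w
    yinf[19] = hill_act_k(ca, p[P_FORCE_KM], p[P_FORCE_N])
    tau[19] = p[P_FTAU_BASE] + p[P_FTAU_AMP] * hill_inh_k(
        ca, p[P_FTAU_KM], p[P_FTAU_N])


# ---------------------------------------------------------------------------
# membrane currents
# ---------------------------------------------------------------------------
@njit(cache=True)
def eval_currents(y, p, d, out):
    """Current density (pA/pF) of the 14 components; returns NSCC Ca part."""
    v = y[S_V]
    ca = y[S_CA_I]
    # L-type Ca with Ca-dependent inactivation (Hill, coefficient n_cdi)
    fca = hill_inh_k(ca, p[P_KM_CDI], p[P_N_CDI])
    wf = p[P_CAL_WF]
    out[C_ICAL] = (p[P_G_CAL] * y[S_D] ** 2 * (wf * y[S_F1] + (1.0 - wf) * y[S_F2])
                   * fca * (v - p[P_E_CAL]))
    out[C_ICAT] = p[P_G_CAT] * y[S_B] ** 2 * y[S_G] * (v - p[P_E_CAT])
    out[C_INA] = p[P_G_NA] * y[S_M] ** 3 * y[S_H] * (v - d[D_E_NA])
    out[C_IH] = p[P_G_H] * y[S_Y] * (v - d[D_E_H])
    ek = d[D_E_K]
    wr = p[P_K1_W_R1]
    out[C_IK1] = (p[P_G_K1] * y[S_Q]
                  * (wr * y[S_R1] + (1.0 - wr) * y[S_R2]) * (v - ek))
    wk = p[P_K2_W_K1]
    out[C_IK2] = (p[P_G_K2] * y[S_P]
                  * (wk * y[S_K1] + (1.0 - wk) * y[S_K2]) * (v - ek))
    out[C_IKA] = p[P_G_KA] * y[S_S] * y[S_X] * (v - ek)
    ab = p[P_BK_AB_FRAC]
    out[C_IBKA] = p[P_G_BK] * (1.0 - ab) * y[S_XA] * (v - ek)
    out[C_IBKAB] = p[P_G_BK] * ab * y[S_XAB] * (v - ek)
    out[C_IKB] = p[P_G_KB] * (v - ek)
    out[C_ICLCA] = p[P_G_CL] * y[S_C] * (v - d[D_E_CL])
    gns = p[P_G_NS] * d[D_NS_FMG] * d[D_NS_FCAT]
    out[C_INSCC] = (gns + p[P_G_NS_LEAK]) * (v - d[D_E_NS])
    i_ns_ca = d[D_NS_WCA] * gns * (v - d[D_E_NS])
    # Na-K pump (outward positive, Nakao-Gadsby voltage dependence)
    u = v / d[D_RT_F]
    fv = 1.0 / (1.0 + 0.1245 * safe_exp(-0.1 * u)
                + 0.0365 * d[D_NAK_SIGMA] * safe_exp(-u))
    out[C_INAK] = d[D_NAK_SCALE] * fv
    # Na-Ca exchanger, Weber formulation with allosteric Ca_i activation
    out[C_INCX] = _incx(v, ca, p, d)
    return i_ns_ca


@njit(cache=True)
def _incx(v, ca, p, d):
    u = v / d[D_RT_F]
    nai3 = p[P_NA_I] ** 3
    nao3 = p[P_NA_O] ** 3
    cao = p[P_CA_O]
    allo = hill_act_k(ca, p[P_NCX_KM_ALLO], p[P_NCX_N_ALLO])
    g = p[P_NCX_GAMMA]
    ef = safe_exp(g * u)
    er = safe_exp((g - 1.0) * u)
    num = p[P_NCX_VMAX] * allo * (ef * nai3 * cao - er * nao3 * ca)
    den = (p[P_NCX_KM_CAO] * nai3
           + p[P_NCX_KM_NAO] ** 3 * ca
           + p[P_NCX_KM_NAI] ** 3 * cao * (1.0 + ca / p[P_NCX_KM_CAI])
           + p[P_NCX_KM_CAI] * nao3 * (1.0 + nai3 / p[P_NCX_KM_NAI] ** 3)
           + nai3 * cao + nao3 * ca) * (1.0 + p[P_NCX_KSAT] * er)
    return num / den


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------
@njit(cache=True)
def stim_at(t, pulses):
    s = 0.0
    for i in range(pulses.shape[0]):
        if pulses[i, 0] <= t < pulses[i, 0] + pulses[i, 1]:
            s += pulses[i, 2]
    return s


@njit(cache=True)
def rhs(t, y, p, d, mask, pulses, dy, icomp, yinf, tau, clamp_v, clamp_ca):
    """dy/dt in place; also fills the per-component current vector icomp."""
    i_ns_ca = eval_currents(y, p, d, icomp)
    itot = 0.0
    for i in range(NCOMP):
        icomp[i] *= mask[i]
        itot += icomp[i]
    if clamp_v:
        dy[S_V] = 0.0
    else:
        dy[S_V] = -(itot - stim_at(t, pulses)) / p[P_CM]
    # calcium balance: membrane channel influx, NCX, PMCA
    i_ca_tot = icomp[C_ICAL] + icomp[C_ICAT] + mask[C_INSCC] * i_ns_ca
    jmem = -d[D_JMEM_FACTOR] * i_ca_tot
    jncx = d[D_JNCX_FACTOR] * icomp[C_INCX]
    ca = y[S_CA_I]
    jpmca = p[P_JPMCA_MAX] * hill_act_k(ca, p[P_KM_PMCA], p[P_N_PMCA])
    if clamp_ca:
        dy[S_CA_I] = 0.0
    else:
        dy[S_CA_I] = jmem + jncx - jpmca
    gate_tables(y[S_V], ca, p, yinf, tau)
    for i in range(NGATES):
        dy[GATE0 + i] = (yinf[i] - y[GATE0 + i]) / tau[i]
    return jmem, jncx, jpmca


@njit(cache=True)
def _clip_gates(y):
    """Clamp gates to [0,1]; returns the largest excursion corrected."""
    worst = 0.0
    for i in range(GATE0, NSTATES):
        if y[i] < 0.0:
            if -y[i] > worst:
                worst = -y[i]
            y[i] = 0.0
        elif y[i] > 1.0:
            if y[i] - 1.0 > worst:
                worst = y[i] - 1.0
            y[i] = 1.0
    return worst


@njit(cache=True)
def integrate_kernel(y0, p, d, mask, pulses, t0, duration, dt, use_rk4,
                     stride, vsched, clamp_v, clamp_ca):
    """Fixed-step integration with periodic recording.

    vsched: (n, 2) array of [t_switch, V] rows applied when clamp_v is True
    (piecewise-constant command potential); empty otherwise.
    Returns (t_rec, y_rec, i_rec, j_rec, flag).
    """
    nsteps = int(round(duration / dt))
    nrec = nsteps // stride + 1
    t_rec = np.empty(nrec)
    y_rec = np.empty((nrec, NSTATES))
    i_rec = np.empty((nrec, NCOMP))
    j_rec = np.empty((nrec, 3))
    y = y0.copy()
    dy = np.empty(NSTATES)
    k2 = np.empty(NSTATES)
    k3 = np.empty(NSTATES)
    k4 = np.empty(NSTATES)
    ytmp = np.empty(NSTATES)
    icomp = np.empty(NCOMP)
    yinf = np.empty(NGATES)
    tau = np.empty(NGATES)
    flag = FLAG_OK
    irec = 0
    excursion = 0.0
    nsched = vsched.shape[0]
    isched = 0
    for k in range(nsteps + 1):
        t = t0 + k * dt
        if clamp_v:
            while isched < nsched and t >= vsched[isched, 0] - 1.0e-12:
                y[S_V] = vsched[isched, 1]
                isched += 1
        if k % stride == 0:
            jm, jx, jp = rhs(t, y, p, d, mask, pulses, dy, icomp, yinf, tau,
                             clamp_v, clamp_ca)
            t_rec[irec] = t
            for i in range(NSTATES):
                y_rec[irec, i] = y[i]
            for i in range(NCOMP):
                i_rec[irec, i] = icomp[i]
            j_rec[irec, 0] = jm
            j_rec[irec, 1] = jx
            j_rec[irec, 2] = jp
            irec += 1
        if k == nsteps:
            break
        if use_rk4:
            rhs(t, y, p, d, mask, pulses, dy, icomp, yinf, tau,
                clamp_v, clamp_ca)
            for i in range(NSTATES):
                ytmp[i] = y[i] + 0.5 * dt * dy[i]
            rhs(t + 0.5 * dt, ytmp, p, d, mask, pulses, k2, icomp, yinf, tau,
                clamp_v, clamp_ca)
            for i in range(NSTATES):
                ytmp[i] = y[i] + 0.5 * dt * k2[i]
            rhs(t + 0.5 * dt, ytmp, p, d, mask, pulses, k3, icomp, yinf, tau,
                clamp_v, clamp_ca)
            for i in range(NSTATES):
                ytmp[i] = y[i] + dt * k3[i]
            rhs(t + dt, ytmp, p, d, mask, pulses, k4, icomp, yinf, tau,
                clamp_v, clamp_ca)
            for i in range(NSTATES):
                y[i] += dt / 6.0 * (dy[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        else:
            rhs(t, y, p, d, mask, pulses, dy, icomp, yinf, tau,
                clamp_v, clamp_ca)
            for i in range(NSTATES):
                y[i] += dt * dy[i]
        w = _clip_gates(y)
        if w > excursion:
            excursion = w
        if y[S_CA_I] < 1.0e-9:
            y[S_CA_I] = 1.0e-9
        if not np.isfinite(y[S_V]):
            flag = FLAG_NONFINITE
            break
        if abs(y[S_V]) > 500.0:
            flag = FLAG_UNSTABLE
            break
    if flag != FLAG_OK:
        # truncate records to what was written
        t_rec = t_rec[:irec]
        y_rec = y_rec[:irec]
        i_rec = i_rec[:irec]
        j_rec = j_rec[:irec]
    return t_rec, y_rec, i_rec, j_rec, flag, excursion


@njit(cache=True)
def steady_gates(v, ca, p):
    """Gate steady-state vector at fixed V and Ca (for pre-equilibration)."""
    yinf = np.empty(NGATES)
    tau = np.empty(NGATES)
    gate_tables(v, ca, p, yinf, tau)
    return yinf
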