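"""Flat state/parameter vector layout shared by the numba kernels.

The dynamical state and the constant-parameter registry are packed into
1-D float64 arrays so the right-hand side can be compiled.  Index
constants ``S_<NAME>`` / ``P_<NAME>`` are generated from the ordered name
tuples below; the JSON parameter registry and the public dataclasses all
round-trip through this layout.
"""

# Dynamical variables.  Gating-variable letters follow the model's own
# nomenclature: d/f1/f2 (L-type Ca), m/h (Na), b/g (T-type Ca), y (I_h),
# q/r1/r2 (I_K1), p/k1/k2 (I_K2), s/x (I_KA), xa/xab (BK alpha, alpha+beta),
# c (I_Cl(Ca)), w (force activation).
STATE_NAMES = (
    "v", "ca_i",
    "d", "f1", "f2",
    "m", "h",
    "b", "g",
    "y",
    "q", "r1", "r2",
    "p", "k1", "k2",
    "s", "x",
    "xa", "xab",
    "c",
    "w",
)
NSTATES = len(STATE_NAMES)
NGATES = NSTATES - 2          # everything except v and ca_i
GATE0 = 2                     # index of the first gate in the state vector

# Electrogenic components, in summation order.
COMPONENTS = (
    "ical", "icat", "ina", "ih",
    "ik1", "ik2", "ika", "ibka", "ibkab", "ikb",
    "iclca", "inscc", "inak", "incx",
)
NCOMP = len(COMPONENTS)

PARAM_NAMES = (
    # physical context / ionic milieu
    "temperature", "gas_const", "faraday",
    "na_o", "na_i", "k_o", "k_i", "cl_o", "cl_i", "ca_o", "mg_o",
    # cell geometry / calcium handling
    "cm", "av_ratio", "alpha_free",
    "jpmca_max", "km_pmca", "n_pmca",
    # L-type Ca current
    "g_cal", "e_cal", "km_cdi", "n_cdi", "cal_wf",
    "cal_vh_d", "cal_k_d", "cal_vh_f", "cal_k_f",
    "cal_taud_base", "cal_taud_amp", "cal_taud_vc", "cal_taud_k",
    "cal_tau_f1",
    "cal_tauf2_max", "cal_tauf2_amp", "cal_tauf2_vc", "cal_tauf2_k",
    # fast Na current
    "g_na",
    "na_vh_m", "na_k_m", "na_vh_h", "na_k_h",
    "na_taum_base", "na_taum_amp", "na_taum_vc", "na_taum_k",
    "na_tauh_base", "na_tauh_amp", "na_tauh_vc", "na_tauh_k",
    # T-type Ca current
    "g_cat", "e_cat",
    "cat_vh_b", "cat_k_b", "cat_vh_g", "cat_k_g", "cat_g_min",
    "cat_taub_base", "cat_taub_amp", "cat_taub_vc", "cat_taub_k",
    "cat_taug_max", "cat_taug_v1", "cat_taug_k1", "cat_taug_v2", "cat_taug_k2",
    # hyperpolarization-activated current
    "g_h", "h_pna_pk",
    "h_vh_y", "h_k_y",
    "h_tauy_a", "h_tauy_ka", "h_tauy_b", "h_tauy_kb",
    # voltage-gated K current 1
    "g_k1", "k1_q_max", "k1_vh_q", "k1_k_q", "k1_vh_r", "k1_k_r", "k1_w_r1",
    "k1_tauq_amp", "k1_tauq_vc", "k1_tauq_k",
    "k1_taur1_amp", "k1_taur1_vc", "k1_taur1_k",
    "k1_taur2_amp", "k1_taur2_vc", "k1_taur2_k",
    # voltage-gated K current 2
    "g_k2", "k2_vh_p", "k2_k_p", "k2_vh_k", "k2_k_k", "k2_w_k1",
    "k2_taup_amp", "k2_taup_vc", "k2_taup_k",
    "k2_tauk1_amp", "k2_tauk1_vc", "k2_tauk1_k",
    "k2_tauk2",
    # A-type transient K current
    "g_ka", "ka_vh_s", "ka_k_s", "ka_vh_x", "ka_k_x", "ka_x_min",
    "ka_taus_amp", "ka_taus_vc", "ka_taus_k",
    "ka_taux_base", "ka_taux_amp", "ka_taux_vc", "ka_taux_k",
    # large-conductance Ca-activated K current (alpha and alpha+beta)
    "g_bk", "bk_ab_frac",
    "bka_vh0", "bka_vh_slope", "bka_z0", "bka_zslope",
    "bkab_vh0", "bkab_vh_slope", "bkab_z0", "bkab_zslope",
    "bk_tau_base", "bk_tau_amp", "bk_tau_vc", "bk_tau_k",
    # background K current
    "g_kb",
    # Ca-activated Cl current
    "g_cl", "cl_kd0", "cl_kdk", "cl_n",
    "cl_tau_base", "cl_tau_amp", "cl_tau_vc", "cl_tau_k",
    # non-selective cation current
    "g_ns", "g_ns_leak",
    "ns_pna", "ns_pk", "ns_pca",
    "ns_km_cat", "ns_n_cat", "ns_km_mg", "ns_n_mg",
    # Na-K pump
    "inak_max", "nak_km_k", "nak_n_k", "nak_km_na", "nak_n_na",
    "nak_q10", "nak_tref",
    # Na-Ca exchanger (Weber formulation)
    "ncx_vmax",
    "ncx_km_cai", "ncx_km_cao", "ncx_km_nai", "ncx_km_nao",
    "ncx_ksat", "ncx_gamma", "ncx_km_allo", "ncx_n_allo",
    # Ca-dependent phasic force
    "force_km", "force_n",
    "ftau_base", "ftau_amp", "ftau_km", "ftau_n",
)
NPARAMS = len(PARAM_NAMES)

_g = globals()
for _i, _name in enumerate(STATE_NAMES):
    _g["S_" + _name.upper()] = _i
for _i, _name in enumerate(PARAM_NAMES):
    _g["P_" + _name.upper()] = _i
for _i, _name in enumerate(COMPONENTS):
    _g["C_" + _name.upper()] = _i
del _g, _i, _name

STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}
PARAM_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}
COMPONENT_INDEX = {n: i for i, n in enumerate(COMPONENTS)}
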