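"""Parameter registry for the uterine smooth muscle cell model.

All constants are kept in a flat name -> value mapping mirroring the
kernel vector layout (:mod:`usmcsim._layout`).  Units follow the project
convention: mV, ms, mM, pA/pF, nS/pF, mM/ms; temperature in K.

``Params`` is the typed handle the rest of the package uses; it can be
serialized to / loaded from a plain-text JSON registry (see
:mod:`usmcsim.io`), with per-symbol units and source annotations so the
provenance of every constant is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._layout import (NPARAMS, NSTATES, PARAM_INDEX, PARAM_NAMES,
                      STATE_INDEX, STATE_NAMES)

#: name -> (default value, unit, source note)
PARAM_TABLE: dict[str, tuple[float, str, str]] = {
    # --- physical context & ionic milieu -------------------------------
    "temperature": (308.15, "K", "whole-cell simulations at 35 C"),
    "gas_const": (8314.462618, "mJ/(mol K)", "CODATA"),
    "faraday": (96485.33212, "C/mol", "CODATA"),
    "na_o": (130.0, "mM", "physiological bath"),
    "na_i": (4.0, "mM", "pipette"),
    "k_o": (6.0, "mM", "physiological bath"),
    "k_i": (140.0, "mM", "pipette"),
    "cl_o": (130.0, "mM", "physiological bath"),
    "cl_i": (46.0, "mM", "smooth muscle Cl accumulation"),
    "ca_o": (2.5, "mM", "physiological bath"),
    "mg_o": (0.5, "mM", "physiological bath"),
    # --- geometry & Ca handling ----------------------------------------
    "cm": (1.0, "uF/cm^2", "specific membrane capacitance"),
    "av_ratio": (7500.0, "1/cm",
                 "double-cone cell, ~120 um long, 4 um radius (S/V = 3/r)"),
    "alpha_free": (0.02, "", "free fraction of membrane Ca influx"),
    "jpmca_max": (1.2e-6, "mM/ms", "fit to Ca transient decay"),
    "km_pmca": (5.0e-4, "mM", "PMCA half-saturation (0.5 uM)"),
    "n_pmca": (2.0, "", "PMCA Hill coefficient"),
    # --- L-type Ca current ---------------------------------------------
    "g_cal": (1.2, "nS/pF", "scaled to AP upstroke velocity"),
    "e_cal": (45.0, "mV", "fixed apparent reversal (not GHK)"),
    "km_cdi": (1.0e-3, "mM", "Ca-dependent inactivation half-saturation"),
    "n_cdi": (4.0, "", "Ca-dependent inactivation Hill coefficient"),
    "cal_wf": (0.2, "", "weight of fast inactivation gate"),
    "cal_vh_d": (-22.0, "mV", "activation half-voltage"),
    "cal_k_d": (7.0, "mV", "activation slope"),
    "cal_vh_f": (-45.0, "mV", "inactivation half-voltage"),
    "cal_k_f": (5.0, "mV", "inactivation slope"),
    "cal_taud_base": (2.29, "ms", ""),
    "cal_taud_amp": (5.7, "ms", ""),
    "cal_taud_vc": (-29.97, "mV", ""),
    "cal_taud_k": (9.0, "mV", ""),
    "cal_tau_f1": (12.0, "ms", "voltage-independent fast inactivation"),
    "cal_tauf2_max": (1200.0, "ms", "slow inactivation tau, plateau"),
    "cal_tauf2_amp": (900.0, "ms", "dip amplitude (min 300 ms at 0 mV)"),
    "cal_tauf2_vc": (0.0, "mV", "slow inactivation tau minimum position"),
    "cal_tauf2_k": (25.0, "mV", ""),
    # --- fast Na current -----------------------------------------------
    "g_na": (0.12, "nS/pF", "upper end of reported density range"),
    "na_vh_m": (-35.9, "mV", ""),
    "na_k_m": (9.0, "mV", ""),
    "na_vh_h": (-57.0, "mV", ""),
    "na_k_h": (8.0, "mV", ""),
    "na_taum_base": (0.25, "ms", ""),
    "na_taum_amp": (7.0, "ms", ""),
    "na_taum_vc": (-38.0, "mV", ""),
    "na_taum_k": (10.0, "mV", ""),
    "na_tauh_base": (2.0, "ms", ""),
    "na_tauh_amp": (80.0, "ms", ""),
    "na_tauh_vc": (-50.0, "mV", ""),
    "na_tauh_k": (9.0, "mV", ""),
    # --- T-type Ca current ---------------------------------------------
    "g_cat": (0.058, "nS/pF", "matched to human myometrial density"),
    "e_cat": (42.0, "mV", "fixed apparent reversal"),
    "cat_vh_b": (-54.23, "mV", "activation half-voltage (Cav3.1 data)"),
    "cat_k_b": (9.88, "mV", ""),
    "cat_vh_g": (-72.98, "mV", "inactivation half-voltage"),
    "cat_k_g": (4.64, "mV", ""),
    "cat_g_min": (0.02, "", "non-inactivating pedestal"),
    "cat_taub_base": (0.45, "ms", ""),
    "cat_taub_amp": (3.9, "ms", ""),
    "cat_taub_vc": (-66.0, "mV", ""),
    "cat_taub_k": (26.0, "mV", ""),
    "cat_taug_max": (150.0, "ms", ""),
    "cat_taug_v1": (417.43, "mV", ""),
    "cat_taug_k1": (203.18, "mV", ""),
    "cat_taug_v2": (-61.11, "mV", ""),
    "cat_taug_k2": (8.07, "mV", ""),
    # --- hyperpolarization-activated current ---------------------------
    "g_h": (0.0542, "nS/pF", ""),
    "h_pna_pk": (0.35, "", "GHK permeability ratio P_Na/P_K"),
    "h_vh_y": (-105.39, "mV", "activation half-voltage"),
    "h_k_y": (8.6594, "mV", ""),
    "h_tauy_a": (3.5e-6, "1/ms", "alpha-rate coefficient"),
    "h_tauy_ka": (0.0497, "1/mV", ""),
    "h_tauy_b": (0.04, "1/ms", "beta-rate coefficient"),
    "h_tauy_kb": (0.0521, "1/mV", ""),
    # --- voltage-gated K current 1 (slow rectifier, C1-type) -----------
    "g_k1": (0.2275, "nS/pF", ""),
    "k1_q_max": (0.978613, "", "activation steady-state scale"),
    "k1_vh_q": (-18.6, "mV", "activation half-voltage"),
    "k1_k_q": (26.6, "mV", ""),
    "k1_vh_r": (-63.0, "mV", "inactivation half-voltage"),
    "k1_k_r": (6.3, "mV", ""),
    "k1_w_r1": (0.38, "", "fast inactivation weight"),
    "k1_tauq_amp": (800.0, "ms", ""),
    "k1_tauq_vc": (-60.71, "mV", ""),
    "k1_tauq_k": (15.79, "mV", ""),
    "k1_taur1_amp": (5000.0, "ms", "fast inactivation tau amplitude"),
    "k1_taur1_vc": (-62.71, "mV", ""),
    "k1_taur1_k": (35.86, "mV", ""),
    "k1_taur2_amp": (30000.0, "ms", "slow inactivation tau amplitude"),
    "k1_taur2_vc": (-0.52, "mV", ""),
    "k1_taur2_k": (35.87, "mV", ""),
    # --- voltage-gated K current 2 (fast rectifier, C2-type) -----------
    "g_k2": (0.0775, "nS/pF", ""),
    "k2_vh_p": (-17.91, "mV", "activation half-voltage"),
    "k2_k_p": (18.4, "mV", ""),
    "k2_vh_k": (-21.2, "mV", "inactivation half-voltage (depolarized)"),
    "k2_k_k": (5.7, "mV", ""),
    "k2_w_k1": (0.75, "", "fast inactivation weight"),
    "k2_taup_amp": (600.0, "ms", ""),
    "k2_taup_vc": (-64.1, "mV", ""),
    "k2_taup_k": (28.67, "mV", ""),
    "k2_tauk1_amp": (20000.0, "ms", ""),
    "k2_tauk1_vc": (-60.0, "mV", ""),
    "k2_tauk1_k": (60.0, "mV", ""),
    "k2_tauk2": (80000.0, "ms", "very slow inactivation"),
    # --- A-type transient K current ------------------------------------
    "g_ka": (0.0477, "nS/pF", "set by peak-I_KA / peak-total-K ratio"),
    "ka_vh_s": (-27.79, "mV", "activation half-voltage"),
    "ka_k_s": (7.57, "mV", ""),
    "ka_vh_x": (-69.5, "mV", "inactivation half-voltage"),
    "ka_k_x": (6.0, "mV", ""),
    "ka_x_min": (0.02, "", "non-inactivating pedestal"),
    "ka_taus_amp": (17.0, "ms", ""),
    "ka_taus_vc": (-20.52, "mV", ""),
    "ka_taus_k": (35.0, "mV", ""),
    "ka_taux_base": (7.5, "ms", ""),
    "ka_taux_amp": (30.0, "ms", ""),
    "ka_taux_vc": (-50.0, "mV", ""),
    "ka_taux_k": (30.0, "mV", ""),
    # --- BK current (alpha-only and alpha+beta components) -------------
    "g_bk": (0.8, "nS/pF", "total BK conductance"),
    "bk_ab_frac": (0.33333333333333331, "",
                   "proportion of conductance through alpha+beta channels"),
    "bka_vh0": (-90.0, "mV", "alpha half-activation at 1 mM Ca"),
    "bka_vh_slope": (-62.5, "mV/decade", "Ca shift of alpha half-activation"),
    "bka_z0": (0.58, "e", ""),
    "bka_zslope": (-0.22, "e/decade", ""),
    "bkab_vh0": (-170.0, "mV", "alpha+beta half-activation at 1 mM Ca"),
    "bkab_vh_slope": (-60.0, "mV/decade", ""),
    "bkab_z0": (0.43, "e", ""),
    "bkab_zslope": (-0.2, "e/decade", ""),
    "bk_tau_base": (2.4, "ms", ""),
    "bk_tau_amp": (15.0, "ms", ""),
    "bk_tau_vc": (-25.0, "mV", ""),
    "bk_tau_k": (20.0, "mV", ""),
    # --- background K current ------------------------------------------
    "g_kb": (0.004, "nS/pF", "linear, collects SK/Kv7-like residue"),
    # --- Ca-activated Cl current (Arreola-type) ------------------------
    "g_cl": (0.1875, "nS/pF", ""),
    "cl_kd0": (1.5e-3, "mM", "apparent Ca dissociation at 0 mV"),
    "cl_kdk": (77.0, "mV", "e-fold voltage dependence of K_d"),
    "cl_n": (2.0, "", "Ca binding cooperativity"),
    "cl_tau_base": (50.0, "ms", "activation tau, voltage-only"),
    "cl_tau_amp": (150.0, "ms", ""),
    "cl_tau_vc": (-50.0, "mV", ""),
    "cl_tau_k": (15.0, "mV", ""),
    # --- non-selective cation current ----------------------------------
    "g_ns": (0.0123, "nS/pF", "cation-modulated conductance scale"),
    "g_ns_leak": (8.0e-3, "nS/pF", "leak component"),
    "ns_pna": (0.9, "", "relative permeability P_Na/P_Cs"),
    "ns_pk": (1.3, "", "relative permeability P_K/P_Cs"),
    "ns_pca": (0.89, "", "relative permeability P_Ca/P_Cs"),
    "ns_km_cat": (150.0, "mM",
                  "half-saturating extracellular monovalent cation conc."),
    "ns_n_cat": (2.0, "", "cation saturation Hill coefficient"),
    "ns_km_mg": (0.28, "mM", "half-saturating Mg inhibition"),
    "ns_n_mg": (1.3, "", "Mg inhibition Hill coefficient"),
    # --- Na-K pump ------------------------------------------------------
    "inak_max": (1.7, "pA/pF", "maximal turnover current"),
    "nak_km_k": (2.0, "mM", "K_o half-saturation"),
    "nak_n_k": (1.5, "", ""),
    "nak_km_na": (11.0, "mM", "Na_i half-saturation"),
    "nak_n_na": (1.5, "", ""),
    "nak_q10": (1.87, "", "temperature sensitivity"),
    "nak_tref": (308.15, "K", "reference temperature of the fit"),
    # --- Na-Ca exchanger (Weber) ---------------------------------------
    "ncx_vmax": (6.0, "pA/pF", "maximal exchanger current scale"),
    "ncx_km_cai": (3.59e-3, "mM", "Ca_i transport dissociation"),
    "ncx_km_cao": (1.3, "mM", "Ca_o transport dissociation"),
    "ncx_km_nai": (12.29, "mM", "Na_i transport dissociation"),
    "ncx_km_nao": (87.5, "mM", "Na_o transport dissociation"),
    "ncx_ksat": (0.27, "", "saturation factor at negative V"),
    "ncx_gamma": (0.35, "", "energy partition"),
    "ncx_km_allo": (3.0e-4, "mM", "allosteric Ca_i activation"),
    "ncx_n_allo": (2.0, "", "allosteric Hill coefficient"),
    # --- Ca-dependent force --------------------------------------------
    "force_km": (4.0e-4, "mM", "half-activating Ca of steady-state force"),
    "force_n": (3.0, "", "steady-state force Hill coefficient"),
    "ftau_base": (40.0, "ms", "force time constant floor"),
    "ftau_amp": (900.0, "ms", "Ca-dependent slowing at low Ca"),
    "ftau_km": (3.5e-4, "mM", ""),
    "ftau_n": (2.0, "", ""),
}

assert tuple(PARAM_TABLE) == PARAM_NAMES, "registry out of sync with layout"

#: resting state: the numerical equilibrium of the default parameter set
#: (found by long unstimulated relaxation + Newton refinement; the model
#: relaxes back onto these values, see model.find_equilibrium)
INITIAL_STATE: dict[str, float] = {
    "v": -66.71035188583086,
    "ca_i": 8.597734905363701e-05,
    "d": 0.001680145830599672,
    "f1": 0.987157509626767,
    "f2": 0.987157509626767,
    "m": 0.031572949518141234,
    "h": 0.7709695625820233,
    "b": 0.22042463702847187,
    "g": 0.22155800626107974,
    "y": 0.01135382803404508,
    "q": 0.13778888025127986,
    "r1": 0.6431229843039363,
    "r2": 0.6431229843039363,
    "p": 0.0658539714065319,
    "k1": 0.9996593356863631,
    "k2": 0.9996593356863631,
    "s": 0.005815512303529852,
    "x": 0.39809796928181024,
    "xa": 2.717314729214722e-06,
    "xab": 0.001379968063265471,
    "c": 0.0005805177871428906,
    "w": 0.009832878628301886,
}


@dataclass
class Params:
    """Typed handle over the flat parameter vector."""

    vector: np.ndarray = field(
        default_factory=lambda: np.array(
            [PARAM_TABLE[n][0] for n in PARAM_NAMES]))

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (NPARAMS,):
            raise ValueError(f"expected {NPARAMS} parameters, got {v.shape}")
        self.vector = v.copy()

    @classmethod
    def default(cls) -> "Params":
        return cls()

    def __getitem__(self, name: str) -> float:
        return float(self.vector[PARAM_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.vector[PARAM_INDEX[name]] = float(value)

    def copy(self) -> "Params":
        return Params(self.vector.copy())

    def update(self, overrides: dict[str, float]) -> "Params":
        """Return a copy with ``overrides`` applied (unknown names raise)."""
        out = self.copy()
        for k, v in overrides.items():
            if k not in PARAM_INDEX:
                raise KeyError(f"unknown parameter {k!r}")
            out[k] = v
        return out

    def to_dict(self) -> dict[str, float]:
        return {n: float(self.vector[i]) for i, n in enumerate(PARAM_NAMES)}

    def validate(self) -> None:
        """Sanity checks on invariants every simulation relies on."""
        errors = []
        if self["temperature"] <= 0:
            errors.append("temperature must be > 0")
        for ion in ("na_o", "na_i", "k_o", "k_i", "cl_o", "cl_i", "ca_o"):
            if self[ion] <= 0:
                errors.append(f"concentration {ion} must be > 0")
        for gname in ("g_cal", "g_cat", "g_na", "g_h", "g_k1", "g_k2",
                      "g_ka", "g_bk", "g_kb", "g_cl", "g_ns", "g_ns_leak"):
            if self[gname] < 0:
                errors.append(f"conductance {gname} must be >= 0")
        for tname in ("cal_tau_f1", "k2_tauk2", "ftau_base"):
            if self[tname] <= 0:
                errors.append(f"time constant {tname} must be > 0")
        if not 0 < self["alpha_free"] <= 1:
            errors.append("alpha_free must be in (0, 1]")
        if self["av_ratio"] <= 0:
            errors.append("av_ratio must be > 0")
        for w in ("cal_wf", "k1_w_r1", "k2_w_k1", "bk_ab_frac"):
            if not 0 <= self[w] <= 1:
                errors.append(f"weight {w} must be in [0, 1]")
        if errors:
            raise ValueError("invalid parameter registry: " +
                             "; ".join(errors))


def initial_state_vector() -> np.ndarray:
    """Default initial values as a flat state vector."""
    return np.array([INITIAL_STATE[n] for n in STATE_NAMES])


def set_initial_state(values: dict[str, float]) -> None:
    for k, v in values.items():
        if k not in STATE_INDEX:
            raise KeyError(f"unknown state variable {k!r}")
        INITIAL_STATE[k] = float(v)
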