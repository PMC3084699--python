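"""The 14 electrogenic membrane components of the uterine myocyte model.

Inward currents: L- and T-type Ca, fast Na, hyperpolarization-activated.
Outward/K currents: two slowly inactivating voltage-gated K currents, the
A-type transient K current, two BK components (alpha-only and alpha+beta
subunit channels), a linear background K current.  Anionic and exchange
components: Ca-activated Cl, non-selective cation, Na-K pump, Na-Ca
exchanger.

Every component is evaluated as a current density in pA/pF (positive
outward).  The scalar ``eval_*`` functions here are thin, validated
wrappers over the compiled kernel, so library users, the ODE right-hand
side and the tests all exercise one set of equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._layout import (COMPONENT_INDEX, COMPONENTS, NCOMP, NSTATES,
                      STATE_INDEX)
from .biophys import IonicMilieu, PhysicalContext, hill
from .parameters import Params

__all__ = [
    "COMPONENTS", "CurrentSpec", "PumpExchangerSpec", "default_components",
    "eval_ical", "eval_icat", "eval_ina", "eval_ih", "eval_ik1", "eval_ik2",
    "eval_ika", "eval_ikca", "eval_ikb", "eval_iclca", "eval_inscc",
    "eval_inak", "eval_incx", "total_current", "component_mask",
    "cdi_factor", "mg_inhibition", "cation_saturation", "ncx_allosteric",
]


@dataclass(frozen=True)
class CurrentSpec:
    """Descriptive record of one electrogenic component."""

    component: str
    g_max: float                      # nS/pF (or pA/pF scale for pumps)
    reversal: str                     # "fixed:<mV>" | "nernst:<ion>" | "ghk"
    gates: tuple = ()                 # state-vector names of its gates
    modulators: tuple = ()            # e.g. ("ca_inactivation", "mg_block")


@dataclass(frozen=True)
class PumpExchangerSpec:
    """Parameters of the electrogenic pump/exchanger pair."""

    inak_max: float
    nak_km_k: float
    nak_km_na: float
    nak_q10: float
    ncx_vmax: float
    ncx_km: dict = field(default_factory=dict)
    ncx_ksat: float = 0.27
    ncx_gamma: float = 0.35
    ncx_km_allo: float = 3.0e-4
    ncx_n_allo: float = 2.0
    stoichiometry: tuple = (3, 1)     # Na : Ca per cycle


def default_components(params: Params | None = None) -> dict[str, CurrentSpec]:
    """Registry of the 14 default components."""
    p = params or Params.default()
    return {
        "ical": CurrentSpec("ical", p["g_cal"], f"fixed:{p['e_cal']}",
                            ("d", "f1", "f2"), ("ca_inactivation",)),
        "icat": CurrentSpec("icat", p["g_cat"], f"fixed:{p['e_cat']}",
                            ("b", "g")),
        "ina": CurrentSpec("ina", p["g_na"], "nernst:na", ("m", "h")),
        "ih": CurrentSpec("ih", p["g_h"], "ghk:na,k", ("y",)),
        "ik1": CurrentSpec("ik1", p["g_k1"], "nernst:k", ("q", "r1", "r2")),
        "ik2": CurrentSpec("ik2", p["g_k2"], "nernst:k", ("p", "k1", "k2")),
        "ika": CurrentSpec("ika", p["g_ka"], "nernst:k", ("s", "x")),
        "ibka": CurrentSpec("ibka", p["g_bk"] * (1 - p["bk_ab_frac"]),
                            "nernst:k", ("xa",), ("ca_vhalf",)),
        "ibkab": CurrentSpec("ibkab", p["g_bk"] * p["bk_ab_frac"],
                             "nernst:k", ("xab",), ("ca_vhalf",)),
        "ikb": CurrentSpec("ikb", p["g_kb"], "nernst:k"),
        "iclca": CurrentSpec("iclca", p["g_cl"], "nernst:cl", ("c",),
                             ("ca_activation",)),
        "inscc": CurrentSpec("inscc", p["g_ns"], "ghk:na,k,ca", (),
                             ("mg_block", "cation_saturation", "leak")),
        "inak": CurrentSpec("inak", p["inak_max"], "fixed:nan"),
        "incx": CurrentSpec("incx", p["ncx_vmax"], "fixed:nan", (),
                            ("allosteric_ca",)),
    }


def pump_exchanger_spec(params: Params | None = None) -> PumpExchangerSpec:
    p = params or Params.default()
    return PumpExchangerSpec(
        inak_max=p["inak_max"], nak_km_k=p["nak_km_k"],
        nak_km_na=p["nak_km_na"], nak_q10=p["nak_q10"],
        ncx_vmax=p["ncx_vmax"],
        ncx_km={"cai": p["ncx_km_cai"], "cao": p["ncx_km_cao"],
                "nai": p["ncx_km_nai"], "nao": p["ncx_km_nao"]},
        ncx_ksat=p["ncx_ksat"], ncx_gamma=p["ncx_gamma"],
        ncx_km_allo=p["ncx_km_allo"], ncx_n_allo=p["ncx_n_allo"])


# ---------------------------------------------------------------------------
# modulation factors (exposed for analysis; same math as the kernels)
# ---------------------------------------------------------------------------
def cdi_factor(ca_i, params: Params | None = None):
    """Ca-dependent inactivation factor of the L-type current (Hill n=4)."""
    p = params or Params.default()
    return hill(ca_i, p["km_cdi"], p["n_cdi"], "inhibiting")


def mg_inhibition(mg_o, params: Params | None = None):
    """Extracellular Mg inhibition of the non-selective cation conductance."""
    p = params or Params.default()
    return hill(mg_o, p["ns_km_mg"], p["ns_n_mg"], "inhibiting")


def cation_saturation(cation_o, params: Params | None = None):
    """Dependence of the NSCC conductance on external permeant cations."""
    p = params or Params.default()
    return hill(cation_o, p["ns_km_cat"], p["ns_n_cat"], "activating")


def ncx_allosteric(ca_i, params: Params | None = None):
    """Allosteric Ca_i activation of the Na-Ca exchanger."""
    p = params or Params.default()
    return hill(ca_i, p["ncx_km_allo"], p["ncx_n_allo"], "activating")


# ---------------------------------------------------------------------------
# per-component evaluation through the compiled kernel
# ---------------------------------------------------------------------------
def _check_gates(*gates):
    for g in gates:
        if not 0.0 <= g <= 1.0:
            raise ValueError(f"gate value {g} outside [0, 1]")


def _eval(component: str, v: float, ca_i: float,
          gate_values: dict[str, float], params: Params | None) -> float:
    p = params or Params.default()
    y = np.zeros(NSTATES)
    y[STATE_INDEX["v"]] = v
    y[STATE_INDEX["ca_i"]] = ca_i
    for name, val in gate_values.items():
        y[STATE_INDEX[name]] = val
    d = K.derived_from_params(p.vector)
    out = np.empty(NCOMP)
    K.eval_currents(y, p.vector, d, out)
    return float(out[COMPONENT_INDEX[component]])


def eval_ical(v, d, f1, f2, ca_i, params: Params | None = None) -> float:
    """L-type Ca current with weighted fast/slow and Ca inactivation."""
    _check_gates(d, f1, f2)
    return _eval("ical", v, ca_i, {"d": d, "f1": f1, "f2": f2}, params)


def eval_icat(v, b, g, params: Params | None = None) -> float:
    _check_gates(b, g)
    return _eval("icat", v, 1e-4, {"b": b, "g": g}, params)


def eval_ina(v, m, h, params: Params | None = None) -> float:
    _check_gates(m, h)
    return _eval("ina", v, 1e-4, {"m": m, "h": h}, params)


def eval_ih(v, y, params: Params | None = None) -> float:
    _check_gates(y)
    return _eval("ih", v, 1e-4, {"y": y}, params)


def eval_ik1(v, q, r1, r2, params: Params | None = None) -> float:
    _check_gates(q, r1, r2)
    return _eval("ik1", v, 1e-4, {"q": q, "r1": r1, "r2": r2}, params)


def eval_ik2(v, p_gate, k1, k2, params: Params | None = None) -> float:
    _check_gates(p_gate, k1, k2)
    return _eval("ik2", v, 1e-4, {"p": p_gate, "k1": k1, "k2": k2}, params)


def eval_ika(v, s, x, params: Params | None = None) -> float:
    _check_gates(s, x)
    return _eval("ika", v, 1e-4, {"s": s, "x": x}, params)


def eval_ikca(v, xa, xab, ca_i, params: Params | None = None) -> float:
    """Total BK current: alpha-only plus alpha+beta components."""
    _check_gates(xa, xab)
    if ca_i <= 0:
        raise ValueError("ca_i must be positive")
    gates = {"xa": xa, "xab": xab}
    return (_eval("ibka", v, ca_i, gates, params)
            + _eval("ibkab", v, ca_i, gates, params))


def eval_ikb(v, params: Params | None = None) -> float:
    return _eval("ikb", v, 1e-4, {}, params)


def eval_iclca(v, c, ca_i, params: Params | None = None) -> float:
    _check_gates(c)
    if ca_i <= 0:
        raise ValueError("ca_i must be positive")
    return _eval("iclca", v, ca_i, {"c": c}, params)


def eval_inscc(v, params: Params | None = None,
               milieu: IonicMilieu | None = None) -> float:
    p = (params or Params.default()).copy()
    if milieu is not None:
        for name in ("na_o", "na_i", "k_o", "k_i", "ca_o", "mg_o"):
            p[name] = getattr(milieu, name)
    return _eval("inscc", v, 1e-4, {}, p)


def eval_inak(v, params: Params | None = None,
              milieu: IonicMilieu | None = None) -> float:
    p = (params or Params.default()).copy()
    if milieu is not None:
        p["na_i"] = milieu.na_i
        p["k_o"] = milieu.k_o
    return _eval("inak", v, 1e-4, {}, p)


def eval_incx(v, ca_i, params: Params | None = None,
              milieu: IonicMilieu | None = None) -> tuple[float, float]:
    """Exchanger current (pA/pF) and the linked Ca flux (mM/ms).

    Positive current = reverse mode (Ca entry); the flux shares its sign
    with dCa/dt: one Ca ion crosses per elementary charge.
    """
    if ca_i <= 0:
        raise ValueError("ca_i must be positive")
    p = (params or Params.default()).copy()
    if milieu is not None:
        p["na_o"], p["na_i"], p["ca_o"] = milieu.na_o, milieu.na_i, milieu.ca_o
    i_ncx = _eval("incx", v, ca_i, {}, p)
    d = K.derived_from_params(p.vector)
    return i_ncx, float(d[K.D_JNCX_FACTOR] * i_ncx)


def ncx_reversal(params: Params | None = None, ca_i: float = 1.16e-4,
                 ctx: PhysicalContext | None = None) -> float:
    """Exchanger reversal potential 3*E_Na - 2*E_Ca (mV)."""
    p = params or Params.default()
    ctx = ctx or PhysicalContext(temperature=p["temperature"])
    m = IonicMilieu(na_o=p["na_o"], na_i=p["na_i"], ca_o=p["ca_o"],
                    ca_i=ca_i)
    from .biophys import nernst_potential
    return (3 * nernst_potential("na", m, ctx)
            - 2 * nernst_potential("ca", m, ctx))


def component_mask(disabled: tuple[str, ...] = (),
                   enabled: tuple[str, ...] | None = None) -> np.ndarray:
    """0/1 mask over the 14 components (enable-list takes precedence)."""
    for name in (enabled or ()) + tuple(disabled):
        if name not in COMPONENT_INDEX:
            raise KeyError(f"unknown component {name!r}")
    if enabled is not None:
        mask = np.zeros(NCOMP)
        for name in enabled:
            mask[COMPONENT_INDEX[name]] = 1.0
    else:
        mask = np.ones(NCOMP)
        for name in disabled:
            mask[COMPONENT_INDEX[name]] = 0.0
    return mask


def total_current(state: np.ndarray, params: Params | None = None,
                  mask: np.ndarray | None = None
                  ) -> tuple[float, dict[str, float]]:
    """Summed membrane current density and the per-component breakdown."""
    p = params or Params.default()
    y = np.asarray(state, dtype=float)
    if y.shape != (NSTATES,):
        raise ValueError(f"state vector must have length {NSTATES}")
    d = K.derived_from_params(p.vector)
    out = np.empty(NCOMP)
    K.eval_currents(y, p.vector, d, out)
    if mask is not None:
        out = out * mask
    breakdown = {name: float(out[i]) for i, name in enumerate(COMPONENTS)}
    return float(out.sum()), breakdown
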