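"""Intracellular Ca2+ balance and Ca-dependent phasic force.

The cytosolic free-Ca pool is fed by the membrane Ca channels (L-type,
T-type and the Ca fraction of the non-selective cation current) and
drained by the Na-Ca exchanger and the plasma-membrane Ca ATPase; no
SR/store or explicit buffer state is modelled — the free fraction
``alpha`` absorbs buffering.  Force is a single first-order activation
variable relaxing toward a Hill function of Ca with a Ca-dependent time
constant, which is what gives phasic contraction its lag behind the Ca
transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biophys import hill
from .parameters import Params

__all__ = [
    "CellGeometry", "ForceParams", "jca_mem", "jpmca", "ca_derivative",
    "force_ss", "force_tau", "force_derivative",
]

Z_CA = 2


@dataclass(frozen=True)
class CellGeometry:
    """Membrane/volume coupling constants for current -> flux conversion."""

    cm: float = 1.0           # uF/cm^2
    av_ratio: float = 7500.0  # surface-to-volume ratio, 1/cm
    alpha_free: float = 0.015  # free fraction of Ca influx

    def __post_init__(self):
        if self.av_ratio <= 0:
            raise ValueError("surface-to-volume ratio must be positive")
        if not 0 < self.alpha_free <= 1:
            raise ValueError("free-Ca fraction must be in (0, 1]")

    @classmethod
    def from_params(cls, p: Params) -> "CellGeometry":
        return cls(cm=p["cm"], av_ratio=p["av_ratio"],
                   alpha_free=p["alpha_free"])


@dataclass(frozen=True)
class ForceParams:
    km: float = 4.0e-4
    n: float = 3.0
    tau_base: float = 40.0
    tau_amp: float = 900.0
    tau_km: float = 3.5e-4
    tau_n: float = 2.0

    @classmethod
    def from_params(cls, p: Params) -> "ForceParams":
        return cls(km=p["force_km"], n=p["force_n"],
                   tau_base=p["ftau_base"], tau_amp=p["ftau_amp"],
                   tau_km=p["ftau_km"], tau_n=p["ftau_n"])


def jca_mem(i_ca_total, geom: CellGeometry | None = None,
            faraday: float = 96485.33212):
    """Free-Ca flux (mM/ms) from the total membrane Ca current (pA/pF).

    Sign convention: an inward (negative) Ca current raises Ca_i, so the
    flux is  -alpha * AV * Cm * I / (z_Ca * F)  with the 1e-3 factor
    collecting the pA/pF-and-cm unit bookkeeping.
    """
    geom = geom or CellGeometry()
    factor = 1.0e-3 * geom.alpha_free * geom.av_ratio * geom.cm / (
        Z_CA * faraday)
    return -factor * np.asarray(i_ca_total, dtype=float)


def jpmca(ca_i, params: Params | None = None):
    """PMCA extrusion flux (mM/ms, always >= 0): activating Hill, n = 2."""
    p = params or Params.default()
    ca = np.asarray(ca_i, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca_i must be non-negative")
    return p["jpmca_max"] * hill(ca, p["km_pmca"], p["n_pmca"], "activating")


def ca_derivative(j_mem, j_ncx, j_pmca):
    """dCa/dt (mM/ms): membrane influx + signed NCX flux - PMCA extrusion."""
    return j_mem + j_ncx - j_pmca


def force_ss(ca_i, fp: ForceParams | None = None):
    """Steady-state normalized force (0..1), nondecreasing in Ca."""
    fp = fp or ForceParams()
    return hill(ca_i, fp.km, fp.n, "activating")


def force_tau(ca_i, fp: ForceParams | None = None):
    """Force activation time constant (ms); slower at low Ca."""
    fp = fp or ForceParams()
    return fp.tau_base + fp.tau_amp * hill(ca_i, fp.tau_km, fp.tau_n,
                                           "inhibiting")


def force_derivative(f, ca_i, fp: ForceParams | None = None):
    """First-order relaxation of force toward its Ca-dependent target."""
    fp = fp or ForceParams()
    return (force_ss(ca_i, fp) - f) / force_tau(ca_i, fp)
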