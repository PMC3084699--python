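"""Dimension-aware biophysical primitives.

Reversal potentials, sigmoid steady states, Hill saturation, first-order
gate kinetics and Q10 temperature scaling — the vocabulary every membrane
current in the model is written in.

Unit conventions (project-wide): potentials in mV, time in ms,
concentrations in mM, temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhysicalContext", "IonicMilieu", "GateSpec",
    "nernst_potential", "ghk_reversal", "boltzmann", "hill",
    "gate_derivative", "q10_scale",
]

DEFAULT_VALENCES = {"na": 1, "k": 1, "ca": 2, "cl": -1, "mg": 2, "cs": 1}


@dataclass(frozen=True)
class PhysicalContext:
    """Thermodynamic constants shared by every current.

    ``rt_f`` evaluates to ~26.6 mV at 308.15 K (35 C) with R in
    mJ/(mol K) and F in C/mol, so that RT/F is directly in mV.
    """

    temperature: float = 308.15
    gas_constant: float = 8314.462618
    faraday: float = 96485.33212
    valences: dict = field(default_factory=lambda: dict(DEFAULT_VALENCES))

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def rt_f(self) -> float:
        """Thermal voltage RT/F in mV."""
        return self.gas_constant * self.temperature / self.faraday


@dataclass
class IonicMilieu:
    """Intra-/extracellular concentrations (mM); Ca_i is the dynamic one."""

    na_o: float = 130.0
    na_i: float = 4.0
    k_o: float = 6.0
    k_i: float = 140.0
    cl_o: float = 130.0
    cl_i: float = 46.0
    ca_o: float = 2.5
    ca_i: float = 1.16e-4
    mg_o: float = 0.5

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"concentration {name} must be positive")

    def concentrations(self, species: str) -> tuple[float, float]:
        species = species.lower()
        try:
            return (getattr(self, f"{species}_i"),
                    getattr(self, f"{species}_o"))
        except AttributeError:
            raise KeyError(f"unknown ion species {species!r}") from None


@dataclass(frozen=True)
class GateSpec:
    """First-order Hodgkin-Huxley gate: Boltzmann steady state, tau, power.

    ``slope`` > 0 describes activation, < 0 inactivation.  The optional
    pedestal is the non-inactivating fraction of the steady state.
    """

    name: str
    v_half: float
    slope: float
    exponent: int = 1
    pedestal: float = 0.0

    def steady_state(self, v):
        y = boltzmann(v, self.v_half, self.slope)
        return self.pedestal + (1.0 - self.pedestal) * y


def nernst_potential(species: str, milieu: IonicMilieu,
                     ctx: PhysicalContext | None = None) -> float:
    """Equilibrium potential (RT/zF) ln([out]/[in]) in mV."""
    ctx = ctx or PhysicalContext()
    c_in, c_out = milieu.concentrations(species)
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive")
    z = ctx.valences[species.lower()]
    return ctx.rt_f / z * math.log(c_out / c_in)


def _ghk_flux_sum(v: float, entries, rt_f: float) -> float:
    total = 0.0
    for perm, z, c_in, c_out in entries:
        u = z * v / rt_f
        if abs(u) < 1e-9:
            total += perm * z * (c_in - c_out)
        else:
            e = math.exp(-min(max(u, -700.0), 700.0))
            total += perm * z * u * (c_in - c_out * e) / (1.0 - e)
    return total


def ghk_reversal(permeabilities: dict[str, float], milieu: IonicMilieu,
                 ctx: PhysicalContext | None = None,
                 extra_species: dict[str, tuple[float, float, int]] | None
                 = None) -> float:
    """Zero-current potential of a multi-ion GHK conductance (mV).

    ``permeabilities`` maps ion id -> relative permeability; species with
    zero permeability are ignored.  Mixed valences are handled by solving
    the constant-field current equation numerically, which reduces exactly
    to the Nernst potential when a single species is permeant.
    ``extra_species`` allows non-milieu ions as (c_in, c_out, z) — used by
    the clamp-fitting variant of the non-selective cation current, which
    includes Cs+/NMDG terms excluded from the whole-cell model.
    """
    ctx = ctx or PhysicalContext()
    entries = []
    for species, perm in permeabilities.items():
        if perm < 0:
            raise ValueError("permeabilities must be non-negative")
        if perm == 0:
            continue
        if extra_species and species in extra_species:
            c_in, c_out, z = extra_species[species]
        else:
            c_in, c_out = milieu.concentrations(species)
            z = ctx.valences[species.lower()]
        entries.append((perm, z, c_in, c_out))
    if not entries:
        raise ValueError("at least one species must have permeability > 0")
    rt_f = ctx.rt_f
    f = lambda v: _ghk_flux_sum(v, entries, rt_f)
    lo, hi = -400.0, 400.0
    if f(lo) * f(hi) > 0:  # pragma: no cover - physically unreachable
        raise ValueError("GHK reversal not bracketed in [-400, 400] mV")
    return brentq(f, lo, hi, xtol=1e-12)


def boltzmann(v, v_half, slope):
    """Logistic steady state 1/(1+exp((v_half-v)/slope)).

    Positive slope gives an activation curve (rises with V), negative
    slope an inactivation curve.  Evaluated as a tanh to avoid overflow
    at extreme potentials.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return 0.5 * (1.0 + np.tanh((np.asarray(v, dtype=float) - v_half)
                                / (2.0 * slope)))


def hill(x, k_half, n, direction: str = "activating"):
    """Hill saturation x^n/(k^n+x^n) (activating) or its complement.

    Evaluated in log space so large exponents cannot overflow.
    """
    if k_half <= 0:
        raise ValueError("k_half must be positive")
    if n <= 0:
        raise ValueError("Hill coefficient must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    if direction not in ("activating", "inhibiting"):
        raise ValueError("direction must be 'activating' or 'inhibiting'")
    with np.errstate(divide="ignore"):
        r = n * (np.log(x) - math.log(k_half))   # log((x/k)^n)
    if direction == "activating":
        r = -r
    # 1/(1+exp(r)); r=+inf at x=0 activating -> 0, -inf inhibiting -> 1
    out = np.where(np.isneginf(r), 1.0,
                   np.where(np.isposinf(r), 0.0,
                            1.0 / (1.0 + np.exp(np.clip(r, -700, 700)))))
    return out if out.ndim else float(out)


def gate_derivative(y, y_inf, tau):
    """First-order relaxation rate (y_inf - y)/tau in 1/ms."""
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("time constant must be positive")
    return (np.asarray(y_inf, dtype=float) - y) / tau


def q10_scale(value_at_ref, q10, t_ref, t_sim, kind: str = "rate"):
    """Temperature-scale a rate (or a time constant, inversely).

    rate:  value * q10**((t_sim - t_ref)/10)
    tau:   value * q10**(-(t_sim - t_ref)/10)
    """
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    if kind not in ("rate", "tau"):
        raise ValueError("kind must be 'rate' or 'tau'")
    expo = (t_sim - t_ref) / 10.0
    if kind == "tau":
        expo = -expo
    return value_at_ref * q10 ** expo
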