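"""Registry serialization, trajectory I/O and analytic test fixtures.

The parameter registry is a plain JSON document with two sections:
``constants`` (symbol -> {value, unit, source}) and ``initial_values``
(state variable -> value).  Unknown symbols, missing symbols, bad units
and invariant violations are rejected with named diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ._layout import PARAM_NAMES, STATE_NAMES
from .model import CellState
from .parameters import PARAM_TABLE, Params

__all__ = ["load_registry", "save_registry", "default_registry_path",
           "FixtureSpec", "make_fixture", "RegistryError"]


class RegistryError(ValueError):
    pass


def default_registry_path():
    """Path to the packaged default registry JSON."""
    return resources.files("usmcsim").joinpath("params/default.json")


def save_registry(path, params: Params | None = None,
                  initial_state: CellState | None = None) -> None:
    p = params or Params.default()
    y0 = initial_state or CellState.default()
    doc = {
        "format": "usmcsim-registry-v1",
        "constants": {
            name: {"value": p[name], "unit": PARAM_TABLE[name][1],
                   "source": PARAM_TABLE[name][2]}
            for name in PARAM_NAMES},
        "initial_values": y0.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_registry(path=None) -> tuple[Params, CellState]:
    """Load and fully validate a registry file (default: packaged one)."""
    if path is None:
        text = default_registry_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise RegistryError(f"registry is not valid JSON: {err}") from None
    if doc.get("format") != "usmcsim-registry-v1":
        raise RegistryError("unrecognized registry format tag")
    constants = doc.get("constants", {})
    unknown = sorted(set(constants) - set(PARAM_NAMES))
    missing = sorted(set(PARAM_NAMES) - set(constants))
    if unknown:
        raise RegistryError(f"unknown symbols: {', '.join(unknown)}")
    if missing:
        raise RegistryError(f"missing symbols: {', '.join(missing)}")
    p = Params.default()
    for name, rec in constants.items():
        if not isinstance(rec, dict) or "value" not in rec:
            raise RegistryError(f"symbol {name!r} lacks a value record")
        unit = rec.get("unit", PARAM_TABLE[name][1])
        if unit != PARAM_TABLE[name][1]:
            raise RegistryError(
                f"unit mismatch for {name!r}: got {unit!r}, "
                f"expected {PARAM_TABLE[name][1]!r}")
        p[name] = float(rec["value"])
    try:
        p.validate()
    except ValueError as err:
        raise RegistryError(str(err)) from None
    iv = doc.get("initial_values", {})
    unknown = sorted(set(iv) - set(STATE_NAMES))
    if unknown:
        raise RegistryError(f"unknown state variables: {', '.join(unknown)}")
    y0 = CellState.from_dict({k: float(v) for k, v in iv.items()})
    y0.validate()
    return p, y0


# ---------------------------------------------------------------------------
# analytic fixtures for the trace-analysis operations
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FixtureSpec:
    """Analytic trace with known ground truth, plus optional seeded noise.

    family: 'monoexp' (a, tau), 'biexp' (a1, tau1, a2, tau2),
    'alpha' (scale, t_peak), 'square_ap' (base, top, onset, width),
    'triangle_ap' (base, top, onset, rise, fall).
    """

    family: str
    params: tuple
    t_end: float = 500.0
    dt: float = 0.5
    noise: float = 0.0
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    """Return (t, y) for the analytic family; noise is seeded/reproducible."""
    t = np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt)
    f, prm = spec.family, spec.params
    if f == "monoexp":
        a, tau = prm
        y = a * np.exp(-t / tau)
    elif f == "biexp":
        a1, tau1, a2, tau2 = prm
        y = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    elif f == "alpha":
        scale, t_peak = prm
        y = scale * (t / t_peak) * np.exp(1.0 - t / t_peak)
    elif f == "square_ap":
        base, top, onset, width = prm
        y = np.where((t >= onset) & (t < onset + width), top, base)
    elif f == "triangle_ap":
        base, top, onset, rise, fall = prm
        up = base + (top - base) * (t - onset) / rise
        down = top - (top - base) * (t - onset - rise) / fall
        y = np.where(t < onset, base,
                     np.where(t < onset + rise, up,
                              np.where(t < onset + rise + fall, down, base)))
    else:
        raise ValueError(f"unknown fixture family {f!r}")
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise, size=y.shape)
    return t, y
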