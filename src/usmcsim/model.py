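"""Whole-cell ODE system: membrane potential, Ca2+ and force.

dV/dt   = -(I_total - I_stim)/C_m          (mV/ms, densities in pA/pF)
dCa/dt  = J_mem + J_NCX - J_PMCA           (mM/ms)
dy/dt   = (y_inf - y)/tau                  for each of the 19 gates
dF/dt   = (F_ss(Ca) - F)/tau_F(Ca)

Integration is fixed-step Euler or classical RK4 (the model is not stiff
at the default 0.02 ms step); trajectories are recorded on a decoupled
output stride.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from ._layout import (COMPONENTS, NCOMP, NSTATES, STATE_INDEX, STATE_NAMES)
from .parameters import Params, initial_state_vector

__all__ = ["CellState", "StimulusProtocol", "Trajectory", "rhs",
           "integrate", "find_equilibrium", "NumericalInstability"]

DEFAULT_DT = 0.02          # ms
DEFAULT_STRIDE_MS = 0.5    # ms between recorded samples

FLUX_NAMES = ("j_mem", "j_ncx", "j_pmca")

logger = logging.getLogger("usmcsim")


def params_digest(p: "Params") -> str:
    """Short content hash of the parameter vector, for run provenance."""
    return hashlib.sha256(p.vector.tobytes()).hexdigest()[:16]


class NumericalInstability(RuntimeError):
    pass


@dataclass
class CellState:
    """Named view of the 22-component dynamical state vector."""

    vector: np.ndarray = field(default_factory=initial_state_vector)

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (NSTATES,):
            raise ValueError(f"state vector must have length {NSTATES}")
        self.vector = v.copy()

    @classmethod
    def default(cls) -> "CellState":
        return cls()

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "CellState":
        y = initial_state_vector()
        for k, val in values.items():
            if k not in STATE_INDEX:
                raise KeyError(f"unknown state variable {k!r}")
            y[STATE_INDEX[k]] = val
        return cls(y)

    def __getitem__(self, name: str) -> float:
        return float(self.vector[STATE_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.vector[STATE_INDEX[name]] = float(value)

    def to_dict(self) -> dict[str, float]:
        return {n: float(self.vector[i]) for i, n in enumerate(STATE_NAMES)}

    def validate(self) -> None:
        if self["ca_i"] <= 0:
            raise ValueError("Ca_i must be positive")
        gates = self.vector[2:]
        if np.any(gates < -1e-9) or np.any(gates[:-1] > 1 + 1e-9):
            raise ValueError("gate values outside [0, 1]")


@dataclass
class StimulusProtocol:
    """Injected-current waveform: square pulses and/or a sustained clamp.

    Pulses are (onset ms, duration ms, amplitude pA/pF); a depolarizing
    stimulus has positive amplitude (it adds +amp/C_m to dV/dt).
    """

    pulses: tuple = ()
    clamp_amplitude: float = 0.0
    clamp_window: tuple[float, float] | None = None

    def __post_init__(self):
        spans = []
        for onset, dur, _amp in self.pulses:
            if dur <= 0:
                raise ValueError("pulse duration must be positive")
            spans.append((onset, onset + dur))
        spans.sort()
        for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("stimulus pulses must not overlap")

    @classmethod
    def single_pulse(cls, onset: float, duration: float,
                     amplitude: float) -> "StimulusProtocol":
        return cls(pulses=((onset, duration, amplitude),))

    @classmethod
    def current_clamp(cls, amplitude: float, start: float = 0.0,
                      stop: float = np.inf) -> "StimulusProtocol":
        return cls(clamp_amplitude=amplitude, clamp_window=(start, stop))

    def as_array(self) -> np.ndarray:
        rows = [list(p) for p in self.pulses]
        if self.clamp_amplitude != 0.0 and self.clamp_window is not None:
            start, stop = self.clamp_window
            rows.append([start, min(stop, 1e12) - start,
                         self.clamp_amplitude])
        if not rows:
            return np.zeros((0, 3))
        return np.asarray(rows, dtype=float)

    def amplitude_at(self, t: float) -> float:
        arr = self.as_array()
        return float(sum(a for o, d, a in arr if o <= t < o + d))


class Trajectory:
    """Uniformly sampled record of a simulation.

    Attributes
    ----------
    t : (n,) time grid in ms
    states : DataFrame with one column per state variable
    currents : DataFrame with one pA/pF column per component
    fluxes : DataFrame with the three Ca fluxes (mM/ms)
    meta : dict of run metadata (dt, method, protocol, ...)
    """

    def __init__(self, t, states, currents, fluxes, meta=None):
        self.t = np.asarray(t)
        self.states = pd.DataFrame(states, columns=STATE_NAMES)
        self.currents = pd.DataFrame(currents, columns=COMPONENTS)
        self.fluxes = pd.DataFrame(fluxes, columns=FLUX_NAMES)
        self.meta = dict(meta or {})

    def __len__(self):
        return len(self.t)

    @property
    def v(self):
        return self.states["v"].to_numpy()

    @property
    def ca(self):
        return self.states["ca_i"].to_numpy()

    @property
    def force(self):
        return self.states["w"].to_numpy()

    def final_state(self) -> CellState:
        return CellState(self.states.iloc[-1].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat(
            [pd.Series(self.t, name="t"), self.states,
             self.currents, self.fluxes], axis=1)
        return df

    def write_csv(self, path, sidecar: bool = True) -> None:
        """CSV trace plus a JSON metadata sidecar sufficient to re-run."""
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(self.meta, fh, indent=1, default=str)


def rhs(t: float, state: CellState | np.ndarray, params: Params | None = None,
        stimulus: StimulusProtocol | None = None,
        mask: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the full state vector (per ms)."""
    p = params or Params.default()
    y = state.vector if isinstance(state, CellState) else np.asarray(
        state, dtype=float)
    pulses = (stimulus or StimulusProtocol()).as_array()
    m = np.ones(NCOMP) if mask is None else np.asarray(mask, dtype=float)
    d = K.derived_from_params(p.vector)
    dy = np.empty(NSTATES)
    icomp = np.empty(NCOMP)
    yinf = np.empty(K.NGATES)
    tau = np.empty(K.NGATES)
    K.rhs(t, y, p.vector, d, m, pulses, dy, icomp, yinf, tau, False, False)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise NumericalInstability(
            f"non-finite derivative in state(s): {', '.join(bad)}")
    return dy


def integrate(y0: CellState | np.ndarray, t_span: float | tuple[float, float],
              dt: float = DEFAULT_DT, method: str = "rk4",
              params: Params | None = None,
              stimulus: StimulusProtocol | None = None,
              mask: np.ndarray | None = None,
              record_every: float = DEFAULT_STRIDE_MS) -> Trajectory:
    """Fixed-step integration of the whole-cell model.

    ``t_span`` is either a duration or (t0, t1) in ms.  The trajectory is
    recorded every ``record_every`` ms (rounded to a whole number of
    steps).  Deterministic: identical inputs give identical output.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("euler", "rk4"):
        raise ValueError("method must be 'euler' or 'rk4'")
    t0, t1 = (0.0, t_span) if np.isscalar(t_span) else t_span
    if t1 <= t0:
        raise ValueError("empty time span")
    p = params or Params.default()
    y = (y0.vector if isinstance(y0, CellState)
         else np.asarray(y0, dtype=float)).copy()
    pulses = (stimulus or StimulusProtocol()).as_array()
    m = np.ones(NCOMP) if mask is None else np.asarray(mask, dtype=float)
    d = K.derived_from_params(p.vector)
    stride = max(1, int(round(record_every / dt)))
    t_rec, y_rec, i_rec, j_rec, flag, excursion = K.integrate_kernel(
        y, p.vector, d, m, pulses, t0, t1 - t0, dt, method == "rk4",
        stride, np.zeros((0, 2)), False, False)
    if excursion > 1e-9:
        logger.warning("gate excursion of %.3g clipped to [0, 1] during "
                       "integration", excursion)
    if flag == K.FLAG_UNSTABLE:
        raise NumericalInstability(
            f"|V| exceeded 500 mV at t ~ {t_rec[-1] if len(t_rec) else t0} ms"
            " - integration aborted")
    if flag == K.FLAG_NONFINITE:
        raise NumericalInstability("non-finite state encountered")
    meta = {"dt": dt, "method": method, "t0": t0, "t1": t1,
            "record_every": stride * dt, "params_sha256": params_digest(p),
            "stimulus": pulses.tolist(), "mask": m.tolist()}
    return Trajectory(t_rec, y_rec, i_rec, j_rec, meta)


def find_equilibrium(params: Params | None = None,
                     y_guess: CellState | None = None,
                     tol: float = 1e-8,
                     relax_ms: float = 300_000.0,
                     mask: np.ndarray | None = None,
                     refine: bool = True) -> CellState:
    """Unstimulated fixed point of the model.

    Long relaxation (Euler at a coarse step is adequate: the slow K
    inactivation gates set the approach) followed by a Newton refinement
    of the algebraic system rhs(y) = 0.  ``tol`` bounds the residual in
    scaled units (mV/ms for V, nM/ms for Ca, 1/ms for gates).
    """
    from scipy.optimize import root

    p = params or Params.default()
    y = (y_guess or CellState.default()).vector.copy()
    traj = integrate(y, relax_ms, dt=0.05, method="euler", params=p,
                     mask=mask, record_every=relax_ms / 10)
    y = traj.states.iloc[-1].to_numpy().copy()

    scale = np.ones(NSTATES)
    scale[STATE_INDEX["ca_i"]] = 1e-6   # report Ca residual per nM
    none_stim = StimulusProtocol()

    def residual(yv):
        return rhs(0.0, yv, p, none_stim, mask) / scale

    if refine:
        sol = root(residual, y, method="hybr", options={"xtol": 1e-12})
        if sol.success and sol.x[STATE_INDEX["ca_i"]] > 0:
            y = sol.x
    res = np.abs(residual(y))
    if res.max() > tol:
        worst = {STATE_NAMES[i]: float(res[i])
                 for i in np.argsort(res)[-3:][::-1]}
        raise NumericalInstability(
            f"equilibrium residual {res.max():.3g} exceeds tol {tol:g}; "
            f"worst: {worst}")
    return CellState(y)
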