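"""Voltage-clamp engine, trace analysis and scenario presets.

The clamp engine drives the gating/Ca subsystem with a prescribed command
potential and records the isolated component currents; the analysis
helpers extract I-V relationships, exponential inactivation time
constants, activation time-to-peak and action-potential metrics; the
scenario registry bundles parameter overrides + stimulus protocols that
reproduce the canonical uterine AP configurations (single spike, burst,
burst on a depolarized baseline, mixed burst-plateau, plateau, the
estradiol modification, and the excitation-contraction coupling runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels as K
from ._layout import COMPONENT_INDEX, NCOMP, STATE_INDEX
from .currents import component_mask
from .model import (CellState, NumericalInstability, StimulusProtocol,
                    Trajectory, find_equilibrium, integrate, DEFAULT_DT)
from .parameters import Params

__all__ = [
    "VoltageClampProtocol", "ClampResult", "IVCurve", "APMetrics",
    "run_voltage_clamp", "peak_iv", "fit_exponential_decay", "time_to_peak",
    "ap_metrics", "threshold_search", "count_spikes", "classify_ap",
    "scenario", "SCENARIOS", "FitError", "NoThreshold",
]


logger = logging.getLogger("usmcsim")


class FitError(RuntimeError):
    pass


class NoThreshold(RuntimeError):
    """No regenerative AP up to the maximum tested stimulus amplitude."""


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------
@dataclass
class VoltageClampProtocol:
    """Step protocol: hold, optional conditioning phase, test steps, tail.

    ``isolate`` lists the enabled components (empty tuple = all 14).
    """

    holding: float = -80.0
    steps: tuple = ()                   # test potentials, mV
    step_duration: float = 500.0        # ms
    conditioning: tuple | None = None   # (V, duration) before the test step
    tail_duration: float = 0.0          # back at holding after the step
    hold_duration: float = 200.0        # settling time pre-step
    isolate: tuple = ()
    clamp_ca: bool = False
    ca_level: float = 1.16e-4
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.step_duration <= 0 or self.hold_duration < 0:
            raise ValueError("durations must be positive")
        if not self.steps:
            raise ValueError("protocol needs at least one test step")


@dataclass
class ClampResult:
    protocol: VoltageClampProtocol
    steps: np.ndarray                 # test potentials
    trajectories: list                # one Trajectory per step
    step_start: float                 # ms, onset of the test step
    step_end: float                   # ms, end of the test step

    def component_trace(self, traj_index: int, component: str | None = None):
        """(t, i) of the summed isolated current for one step."""
        traj = self.trajectories[traj_index]
        if component is not None:
            i = traj.currents[component].to_numpy()
        else:
            names = self.protocol.isolate or traj.currents.columns
            i = traj.currents[list(names)].sum(axis=1).to_numpy()
        return traj.t, i


def run_voltage_clamp(protocol: VoltageClampProtocol,
                      params: Params | None = None) -> ClampResult:
    """Simulate the protocol; V is prescribed, gates and Ca evolve.

    Gates start at their steady state for the holding potential and then
    settle for ``hold_duration`` ms, so the current at step onset is
    continuous with its pre-step value.
    """
    p = params or Params.default()
    if protocol.isolate:
        mask = component_mask(enabled=tuple(protocol.isolate))
    else:
        mask = component_mask()
    d = K.derived_from_params(p.vector)

    y0 = CellState.default().vector.copy()
    y0[STATE_INDEX["v"]] = protocol.holding
    y0[STATE_INDEX["ca_i"]] = protocol.ca_level
    y0[2:-1] = K.steady_gates(protocol.holding, protocol.ca_level,
                              p.vector)[:-1]

    t_cond = protocol.conditioning[1] if protocol.conditioning else 0.0
    step_start = protocol.hold_duration + t_cond
    step_end = step_start + protocol.step_duration
    total = step_end + protocol.tail_duration

    trajs = []
    for v_step in protocol.steps:
        rows = [[0.0, protocol.holding]]
        if protocol.conditioning:
            rows.append([protocol.hold_duration, protocol.conditioning[0]])
        rows.append([step_start, v_step])
        if protocol.tail_duration > 0:
            rows.append([step_end, protocol.holding])
        vsched = np.asarray(rows, dtype=float)
        logger.info("clamp: hold %.1f mV -> step %.1f mV (%.0f ms)",
                    protocol.holding, v_step, protocol.step_duration)
        t_rec, y_rec, i_rec, j_rec, flag, _exc = K.integrate_kernel(
            y0.copy(), p.vector, d, mask, np.zeros((0, 3)), 0.0, total,
            protocol.dt, True, max(1, int(round(0.5 / protocol.dt))),
            vsched, True, protocol.clamp_ca)
        if flag != K.FLAG_OK:
            raise NumericalInstability(f"clamp step to {v_step} mV diverged")
        trajs.append(Trajectory(t_rec, y_rec, i_rec, j_rec,
                                {"clamp_step": v_step}))
    return ClampResult(protocol, np.asarray(protocol.steps, dtype=float),
                       trajs, step_start, step_end)


# ---------------------------------------------------------------------------
# trace analysis
# ---------------------------------------------------------------------------
@dataclass
class IVCurve:
    voltages: np.ndarray
    values: np.ndarray
    mode: str = "peak"
    normalization_ref: float | None = None

    def normalized(self, ref_voltage: float | None = None) -> "IVCurve":
        ref = self.normalization_ref if ref_voltage is None else ref_voltage
        if ref is None:
            raise ValueError("no normalization reference given")
        idx = int(np.argmin(np.abs(self.voltages - ref)))
        ref_val = self.values[idx]
        if ref_val == 0:
            raise ZeroDivisionError("reference current is zero")
        return IVCurve(self.voltages, self.values / abs(ref_val), self.mode,
                       ref)


def _signed_extremum(y: np.ndarray) -> int:
    return int(np.argmax(np.abs(y)))


def peak_iv(result: ClampResult, mode: str = "peak",
            normalization_ref: float | None = None,
            component: str | None = None) -> IVCurve:
    """Extract peak / end-of-step / tail-peak values per test step."""
    if mode not in ("peak", "end", "tail"):
        raise ValueError("mode must be peak|end|tail")
    values = []
    for k in range(len(result.steps)):
        t, i = result.component_trace(k, component)
        in_step = (t >= result.step_start) & (t < result.step_end)
        if mode == "tail":
            win = t >= result.step_end
            if not np.any(win):
                raise ValueError("protocol has no tail period")
        else:
            win = in_step
        seg = i[win]
        if mode == "end":
            values.append(seg[-1])
        else:
            values.append(seg[_signed_extremum(seg)])
    curve = IVCurve(result.steps.copy(), np.asarray(values), mode,
                    normalization_ref)
    return curve.normalized() if normalization_ref is not None else curve


def fit_exponential_decay(t, y, n_components: int = 1):
    """Least-squares mono/bi-exponential fit of a fully decaying trace.

    The fit starts at the signed extremum of the trace and assumes
    complete decay (no additive constant).  Initialization: log-linear
    regression on the terminal third seeds the slow component; peeling
    its contribution seeds the fast one.  Returns (amplitudes, taus)
    with taus sorted ascending.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    ipk = _signed_extremum(y)
    ts, ys = t[ipk:] - t[ipk], y[ipk:]
    sign = np.sign(ys[0]) or 1.0
    ys = ys * sign
    if len(ts) < 8 or ys[0] <= 0:
        raise FitError("trace too short to fit")
    tail_mean = np.mean(ys[-max(3, len(ys) // 10):])
    if tail_mean > 0.95 * ys[0]:
        raise FitError("trace does not decay after its peak")

    # slow-component seed: log-linear fit on the terminal third
    third = ys[2 * len(ys) // 3:]
    tt = ts[2 * len(ts) // 3:]
    pos = third > max(ys[0] * 1e-12, 0.0)
    if pos.sum() >= 2 and np.all(third[pos] > 0):
        slope, logb = np.polyfit(tt[pos], np.log(third[pos]), 1)
        tau_slow = -1.0 / slope if slope < 0 else ts[-1]
        a_slow = np.exp(logb)
    else:
        tau_slow, a_slow = ts[-1] / 3, ys[0] / 2
    tau_slow = min(max(tau_slow, ts[1]), ts[-1] * 10)

    if n_components == 1:
        p0 = [ys[0], tau_slow]
        fun = lambda tt, a, tau: a * np.exp(-tt / np.abs(tau))
    else:
        peel = ys - a_slow * np.exp(-ts / tau_slow)
        head = peel[: max(4, len(ts) // 5)]
        if head[0] > 0:
            a_fast = head[0]
            below = np.flatnonzero(head < a_fast / np.e)
            tau_fast = ts[below[0]] if len(below) else tau_slow / 10
        else:
            a_fast, tau_fast = ys[0] * 0.3, tau_slow / 10
        tau_fast = max(tau_fast, ts[1])
        p0 = [a_fast, tau_fast, max(a_slow, ys[0] * 1e-3), tau_slow]
        fun = (lambda tt, a1, tau1, a2, tau2:
               a1 * np.exp(-tt / np.abs(tau1))
               + a2 * np.exp(-tt / np.abs(tau2)))
    try:
        popt, _ = curve_fit(fun, ts, ys, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"exponential fit failed: {err}") from None
    popt = np.abs(popt)
    amps, taus = popt[0::2] * sign, popt[1::2]
    order = np.argsort(taus)
    return amps[order], taus[order]


def time_to_peak(t, y):
    """Time from trace start to its extremum.

    Returns (t_peak, has_peak); a monotone trace peaks at the last sample
    and is flagged has_peak=False.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = int(np.argmax(np.abs(y - y[0])))
    return float(t[idx] - t[0]), idx != len(y) - 1


@dataclass
class APMetrics:
    rmp: float                       # mV
    peak: float                      # mV
    max_dvdt: float                  # V/s
    apd: float                       # ms, at `apd_level`
    apd_level: float                 # mV
    n_spikes: int
    v_threshold: float | None = None
    i_threshold: float | None = None

    @property
    def has_ap(self) -> bool:
        return self.n_spikes > 0


def count_spikes(t, v, detect_level: float = 0.0) -> int:
    """Number of upward crossings of the detection level."""
    v = np.asarray(v, dtype=float)
    above = v >= detect_level
    return int(np.count_nonzero(above[1:] & ~above[:-1]))


def ap_metrics(t, v, stimulus: StimulusProtocol | None = None,
               apd_fraction: float = 0.5,
               detect_level: float = 0.0) -> APMetrics:
    """Resting potential, overshoot, max dV/dt and duration of an AP.

    APD is measured at ``apd_fraction`` repolarization between RMP and
    peak (time spent above that level around the absolute peak).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    arr = stimulus.as_array() if stimulus else np.zeros((0, 3))
    # resting window: everything before the first stimulus, or the first
    # 10% of the record when no protocol is supplied
    t_on = arr[:, 0].min() if len(arr) else t[0] + 0.1 * (t[-1] - t[0])
    pre = v[t < t_on]
    rmp = float(pre.mean()) if len(pre) else float(v[0])
    peak = float(v.max())
    dvdt = np.diff(v) / np.diff(t)          # mV/ms == V/s
    # the maximum rate of rise is a property of the regenerative upstroke:
    # samples with the stimulus pulse active are excluded
    if len(arr):
        tm = 0.5 * (t[1:] + t[:-1])
        active = np.zeros_like(tm, dtype=bool)
        for onset, dur, _amp in arr:
            if dur <= 50.0:      # brief pulses only; sustained clamps stay
                active |= (tm >= onset - 1e-9) & (tm < onset + dur + 1e-9)
        if not np.all(active):
            dvdt = dvdt[~active]
    n = count_spikes(t, v, detect_level)
    level = rmp + apd_fraction * (peak - rmp)
    above = np.flatnonzero(v >= level)
    if len(above) and peak > rmp:
        apd = float(t[above[-1]] - t[above[0]])
    else:
        apd = 0.0
    return APMetrics(rmp=rmp, peak=peak, max_dvdt=float(dvdt.max()),
                     apd=apd, apd_level=level, n_spikes=n)


def threshold_search(params: Params | None = None, pulse_width: float = 2.0,
                     y0: CellState | None = None, amp_max: float = 40.0,
                     resolution: float = 0.01, detect_level: float = 0.0,
                     duration: float = 600.0, onset: float = 50.0,
                     dt: float = DEFAULT_DT):
    """Bisection on brief-pulse amplitude for the all-or-none AP threshold.

    Returns (v_threshold, i_threshold): the smallest amplitude whose
    response crosses ``detect_level`` (pA/pF), and the maximum
    pre-upstroke V of the just-subthreshold trace (mV).  Raises
    :class:`NoThreshold` if even ``amp_max`` does not elicit an AP.
    """
    p = params or Params.default()
    start = y0 or find_equilibrium(p)

    def peak_v(amp):
        stim = StimulusProtocol.single_pulse(onset, pulse_width, amp)
        traj = integrate(start, duration, dt=dt, params=p, stimulus=stim)
        return traj, float(traj.v[traj.t >= onset].max())

    _, pk_hi = peak_v(amp_max)
    if pk_hi < detect_level:
        raise NoThreshold(
            f"no AP up to {amp_max} pA/pF with {pulse_width} ms pulse")
    lo, hi = 0.0, amp_max
    traj_lo = None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        traj, pk = peak_v(mid)
        if pk >= detect_level:
            hi = mid
        else:
            lo, traj_lo = mid, traj
    if traj_lo is None:
        traj_lo, _ = peak_v(lo)
    v_threshold = float(traj_lo.v[traj_lo.t >= onset].max())
    return v_threshold, hi


def classify_ap(t, v, rmp: float, detect_level: float = 0.0) -> str:
    """Rough AP classification: none | spike | bursting | plateau | mixed.

    The initial 30% of the record is treated as onset transient; the
    class is judged on the remainder, so an early spike or two riding on
    a maintained depolarization still classifies as plateau.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    n_total = count_spikes(t, v, detect_level)
    cut = t[0] + 0.3 * (t[-1] - t[0])
    late = t >= cut
    n_late = count_spikes(t[late], v[late], detect_level)
    depol = rmp + 15.0
    frac_elevated = float(np.count_nonzero(v[late] > depol)) / max(
        1, np.count_nonzero(late))
    if n_late >= 2:
        return "mixed" if frac_elevated > 0.9 else "bursting"
    if frac_elevated > 0.6:
        return "plateau"
    if n_total >= 2:
        return "bursting"
    return "spike" if n_total == 1 else "none"


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------
@dataclass
class ScenarioPreset:
    """Named bundle of overrides + protocol reproducing one experiment."""

    name: str
    description: str
    overrides: dict = field(default_factory=dict)
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)
    duration: float = 2000.0
    dt: float = DEFAULT_DT
    method: str = "rk4"
    param_steps: tuple = ()            # ((t_switch_ms, {overrides}), ...)
    start_at_equilibrium: bool = True

    def with_overrides(self, extra: dict) -> "ScenarioPreset":
        merged = dict(self.overrides)
        merged.update(extra)
        return ScenarioPreset(self.name, self.description, merged,
                              self.stimulus, self.duration, self.dt,
                              self.method, self.param_steps,
                              self.start_at_equilibrium)


def _total_k_scaled(factor: float) -> dict:
    """Scale every K-carrying conductance by ``factor``."""
    base = Params.default()
    return {g: base[g] * factor
            for g in ("g_k1", "g_k2", "g_ka", "g_bk", "g_kb")}


def _estradiol_overrides() -> dict:
    """Left-shift + steepen L-type inactivation, reduce total K by 30%."""
    base = Params.default()
    ov = _total_k_scaled(0.7)
    ov["cal_vh_f"] = base["cal_vh_f"] - 15.0
    ov["cal_k_f"] = 5.0
    return ov


SCENARIOS: dict[str, ScenarioPreset] = {}


def _register(preset: ScenarioPreset):
    SCENARIOS[preset.name] = preset
    return preset


_register(ScenarioPreset(
    "spike",
    "Single spike AP with its Ca transient and phasic force twitch",
    stimulus=StimulusProtocol.single_pulse(250.0, 2.0, 20.0),
    duration=3000.0))

_register(ScenarioPreset(
    "four_spikes",
    "Four consecutive stimulated spikes: four APs, four Ca transients, "
    "four phasic force transients",
    stimulus=StimulusProtocol(pulses=(
        (250.0, 2.0, 20.0), (2750.0, 2.0, 20.0),
        (5250.0, 2.0, 20.0), (7750.0, 2.0, 20.0))),
    duration=10000.0))

_register(ScenarioPreset(
    "bursting",
    "Bursting AP at resting baseline under a sustained current clamp",
    stimulus=StimulusProtocol.current_clamp(2.5, 250.0, 5250.0),
    duration=6000.0))

_register(ScenarioPreset(
    "bursting_depolarized",
    "Bursting AP on a depolarized baseline: sustained clamp with a "
    "flattened voltage-gated K1 inactivation (larger slope factor)",
    overrides={"k1_k_r": 12.0},
    stimulus=StimulusProtocol.current_clamp(2.5, 250.0, 5250.0),
    duration=6000.0))

_register(ScenarioPreset(
    "mixed_bursting_plateau",
    "Initial repetitive spikes settling into a plateau: Na-K pump "
    "density stepped down mid-run",
    stimulus=StimulusProtocol.current_clamp(2.5, 250.0, 10250.0),
    param_steps=((5250.0, {"inak_max": 1.0}),),
    duration=11000.0))

_register(ScenarioPreset(
    "plateau",
    "Plateau-type AP under a sustained current clamp below the\n    bursting range",
    stimulus=StimulusProtocol.current_clamp(1.8, 250.0, 10250.0),
    duration=11000.0))

_register(ScenarioPreset(
    "estradiol",
    "Estradiol modification: converts the depolarized-baseline burst "
    "into a plateau AP under the identical current clamp",
    overrides=dict(_estradiol_overrides(), **{"k1_k_r": 12.0}),
    stimulus=StimulusProtocol.current_clamp(2.5, 250.0, 10250.0),
    duration=11000.0))


def scenario(name: str, overrides: dict | None = None,
             duration: float | None = None):
    """Run a named preset; returns (Trajectory, metrics dict)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"available: {sorted(SCENARIOS)}")
    preset = SCENARIOS[name]
    logger.info("scenario %r: %s", name, preset.description)
    if overrides:
        preset = preset.with_overrides(overrides)
    if duration is not None:
        preset = ScenarioPreset(preset.name, preset.description,
                                preset.overrides, preset.stimulus, duration,
                                preset.dt, preset.method, preset.param_steps,
                                preset.start_at_equilibrium)
    p = Params.default().update(preset.overrides)
    y0 = (find_equilibrium(p) if preset.start_at_equilibrium
          else CellState.default())

    segments = []
    switches = sorted(preset.param_steps, key=lambda s: s[0])
    t0 = 0.0
    y = y0
    pcur = p
    for t_switch, ov in list(switches) + [(preset.duration, None)]:
        if t_switch > t0:
            traj = integrate(y, (t0, t_switch), dt=preset.dt,
                             method=preset.method, params=pcur,
                             stimulus=preset.stimulus)
            segments.append(traj)
            y = traj.final_state()
            t0 = t_switch
        if ov is not None:
            pcur = pcur.update(ov)
    if len(segments) == 1:
        traj = segments[0]
    else:
        t = np.concatenate([s.t if i == 0 else s.t[1:]
                            for i, s in enumerate(segments)])
        sta = np.vstack([s.states.to_numpy() if i == 0
                         else s.states.to_numpy()[1:]
                         for i, s in enumerate(segments)])
        cur = np.vstack([s.currents.to_numpy() if i == 0
                         else s.currents.to_numpy()[1:]
                         for i, s in enumerate(segments)])
        flx = np.vstack([s.fluxes.to_numpy() if i == 0
                         else s.fluxes.to_numpy()[1:]
                         for i, s in enumerate(segments)])
        traj = Trajectory(t, sta, cur, flx, {"scenario": name})
    traj.meta.update({"scenario": name, "overrides": preset.overrides,
                      "description": preset.description})
    m = ap_metrics(traj.t, traj.v, preset.stimulus)
    metrics = {"rmp": m.rmp, "peak": m.peak, "max_dvdt": m.max_dvdt,
               "apd": m.apd, "n_spikes": m.n_spikes,
               "class": classify_ap(traj.t, traj.v, m.rmp),
               "ca_peak": float(traj.ca.max()),
               "force_peak": float(traj.force.max())}
    return traj, metrics
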