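"""Single-cell atrial action-potential model in the Hodgkin-Huxley formalism.

The model is a minimal six-current atrial myocyte: fast sodium (I_Na),
L-type calcium (I_CaL), rapid and slow delayed-rectifier potassium
(I_Kr, I_Ks), inward-rectifier potassium (I_K1) and a linear leak.  Each
current takes the classical form ``g_x * s_x * (gates) * (V - E_x)`` with
first-order Hodgkin-Huxley gating kinetics
``dx/dt = (x_inf(V) - x) / tau_x(V)``.  The three dimensionless scale
factors ``s_Kr``, ``s_Ks`` and ``s_CaL`` are the handles later calibrated
per patient against ECG-derived repolarization targets.

Rate constants are tuned so that at 1 Hz pacing the baseline action
potential has APD90 near 280 ms and a resting potential near -80 mV,
values typical of human atrial working myocardium.  All constants live in
:class:`CellParams` and can be overridden or loaded from YAML/JSON.

Integration is explicit 4th-order Runge-Kutta (default dt = 0.02 ms) with
an optional Rush-Larsen variant (exponential gate update, forward-Euler
voltage step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "CellParams",
    "APTrace",
    "APMetrics",
    "simulate_ap",
    "ap_metrics",
    "scale_conductances",
    "stimulus_threshold",
    "NumericalInstabilityError",
    "NoCaptureError",
]

N_STATES = 7  # V, m, h, d, f, xr, xs


class NumericalInstabilityError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


class NoCaptureError(ValueError):
    """Raised when a beat window contains no detectable upstroke."""


@dataclass(frozen=True)
class CellParams:
    """Maximal conductances (mS/cm^2), scale factors, reversal potentials (mV).

    ``s_Kr``, ``s_Ks``, ``s_CaL`` multiply the corresponding maximal
    conductance; they default to 1 (population baseline).
    """

    g_Na: float = 11.0
    g_CaL: float = 0.50
    g_Kr: float = 0.08
    g_Ks: float = 0.12
    g_K1: float = 0.22
    g_leak: float = 0.028
    s_Kr: float = 1.0
    s_Ks: float = 1.0
    s_CaL: float = 1.0
    E_Na: float = 60.0
    E_K: float = -90.0
    E_Ca: float = 62.0
    E_leak: float = -30.0
    C_m: float = 1.0
    # stimulus: rectangular pulse (uA/uF), duration ms
    stim_amplitude: float = 30.0
    stim_duration_ms: float = 2.0
    v_init: float = -80.0

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_CaL", "g_Kr", "g_Ks", "g_K1", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("s_Kr", "s_Ks", "s_CaL"):
            if getattr(self, name) < 0:
                raise ValueError(f"scale factor {name} must be >= 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")

    def to_vector(self) -> np.ndarray:
        """Pack constants into the flat float64 vector the kernels consume."""
        return np.array(
            [
                self.C_m,
                self.g_Na,
                self.g_CaL * self.s_CaL,
                self.g_Kr * self.s_Kr,
                self.g_Ks * self.s_Ks,
                self.g_K1,
                self.g_leak,
                self.E_Na,
                self.E_Ca,
                self.E_K,
                self.E_leak,
            ],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            import yaml

            p.write_text(yaml.safe_dump(self.to_dict()))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CellParams":
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            import yaml

            return cls.from_dict(yaml.safe_load(p.read_text()))
        return cls.from_dict(json.loads(p.read_text()))


@dataclass(frozen=True)
class APTrace:
    """Membrane-potential trace on a uniform time grid (ms, mV)."""

    time: np.ndarray
    v: np.ndarray
    stimulus_times: np.ndarray
    dt_ms: float
    cycle_length_ms: float

    def save_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.time, self.v])
        np.savetxt(path, arr, delimiter=",", header="time_ms,v_mv", comments="")


@dataclass(frozen=True)
class APMetrics:
    apd90_ms: float
    v_rest_mv: float
    v_peak_mv: float
    dvdt_max_mv_per_ms: float


@njit(cache=True)
def _gate_inf_tau(v):
    """Steady states and time constants of the six gates at potential v."""
    m_inf = 1.0 / (1.0 + np.exp(-(v + 40.0) / 6.0))
    tau_m = 0.15
    h_inf = 1.0 / (1.0 + np.exp((v + 70.0) / 6.0))
    tau_h = 1.0 + 9.0 / (1.0 + np.exp((v + 50.0) / 8.0))
    d_inf = 1.0 / (1.0 + np.exp(-(v + 10.0) / 6.0))
    tau_d = 2.0
    f_inf = 1.0 / (1.0 + np.exp((v + 28.0) / 6.0))
    tau_f = 260.0
    xr_inf = 1.0 / (1.0 + np.exp(-(v + 15.0) / 8.0))
    tau_xr = 60.0
    xs_inf = 1.0 / (1.0 + np.exp(-v / 14.0))
    tau_xs = 250.0
    return m_inf, tau_m, h_inf, tau_h, d_inf, tau_d, f_inf, tau_f, xr_inf, tau_xr, xs_inf, tau_xs


@njit(cache=True)
def _ionic_current(v, m, h, d, f, xr, xs, p):
    """Total ionic current (uA/uF) at one node; p is CellParams.to_vector()."""
    i_na = p[1] * m * m * m * h * (v - p[7])
    i_cal = p[2] * d * f * (v - p[8])
    i_kr = p[3] * xr * (v - p[9])
    i_ks = p[4] * xs * xs * (v - p[9])
    i_k1 = p[5] * (v - p[9]) / (1.0 + np.exp(0.1 * (v + 75.0)))
    i_leak = p[6] * (v - p[10])
    return i_na + i_cal + i_kr + i_ks + i_k1 + i_leak


@njit(cache=True)
def _deriv(state, p, istim, out):
    """Right-hand side for a vector of nodes; state shape (7, n)."""
    n = state.shape[1]
    for j in range(n):
        v = state[0, j]
        m = state[1, j]
        h = state[2, j]
        d = state[3, j]
        f = state[4, j]
        xr = state[5, j]
        xs = state[6, j]
        (m_inf, tau_m, h_inf, tau_h, d_inf, tau_d, f_inf, tau_f,
         xr_inf, tau_xr, xs_inf, tau_xs) = _gate_inf_tau(v)
        i_ion = _ionic_current(v, m, h, d, f, xr, xs, p)
        out[0, j] = (-i_ion + istim[j]) / p[0]
        out[1, j] = (m_inf - m) / tau_m
        out[2, j] = (h_inf - h) / tau_h
        out[3, j] = (d_inf - d) / tau_d
        out[4, j] = (f_inf - f) / tau_f
        out[5, j] = (xr_inf - xr) / tau_xr
        out[6, j] = (xs_inf - xs) / tau_xs


@njit(cache=True)
def _rk4_step(state, p, istim, dt, k1, k2, k3, k4, tmp):
    _deriv(state, p, istim, k1)
    tmp[:] = state + 0.5 * dt * k1
    _deriv(tmp, p, istim, k2)
    tmp[:] = state + 0.5 * dt * k2
    _deriv(tmp, p, istim, k3)
    tmp[:] = state + dt * k3
    _deriv(tmp, p, istim, k4)
    state += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def _rl_step(state, p, istim, dt):
    """Rush-Larsen: exponential gate update, forward Euler for V."""
    n = state.shape[1]
    for j in range(n):
        v = state[0, j]
        (m_inf, tau_m, h_inf, tau_h, d_inf, tau_d, f_inf, tau_f,
         xr_inf, tau_xr, xs_inf, tau_xs) = _gate_inf_tau(v)
        i_ion = _ionic_current(v, state[1, j], state[2, j], state[3, j],
                               state[4, j], state[5, j], state[6, j], p)
        state[0, j] = v + dt * (-i_ion + istim[j]) / p[0]
        state[1, j] = m_inf + (state[1, j] - m_inf) * np.exp(-dt / tau_m)
        state[2, j] = h_inf + (state[2, j] - h_inf) * np.exp(-dt / tau_h)
        state[3, j] = d_inf + (state[3, j] - d_inf) * np.exp(-dt / tau_d)
        state[4, j] = f_inf + (state[4, j] - f_inf) * np.exp(-dt / tau_f)
        state[5, j] = xr_inf + (state[5, j] - xr_inf) * np.exp(-dt / tau_xr)
        state[6, j] = xs_inf + (state[6, j] - xs_inf) * np.exp(-dt / tau_xs)


@njit(cache=True)
def _run_cell(p, cl_ms, n_beats, dt, stim_amp, stim_dur, v_init, use_rl):
    """Integrate one cell; returns (v_trace, ok, bad_step)."""
    n_steps = int(round(cl_ms * n_beats / dt))
    v_out = np.empty(n_steps + 1)
    state = np.empty((N_STATES, 1))
    state[0, 0] = v_init
    (m_inf, _, h_inf, _, d_inf, _, f_inf, _, xr_inf, _, xs_inf, _) = _gate_inf_tau(v_init)
    state[1, 0] = m_inf
    state[2, 0] = h_inf
    state[3, 0] = d_inf
    state[4, 0] = f_inf
    state[5, 0] = xr_inf
    state[6, 0] = xs_inf
    k1 = np.empty_like(state)
    k2 = np.empty_like(state)
    k3 = np.empty_like(state)
    k4 = np.empty_like(state)
    tmp = np.empty_like(state)
    istim = np.zeros(1)
    v_out[0] = v_init
    for i in range(n_steps):
        t = i * dt
        phase = t % cl_ms
        if phase < stim_dur:
            istim[0] = stim_amp
        else:
            istim[0] = 0.0
        if use_rl:
            _rl_step(state, p, istim, dt)
        else:
            _rk4_step(state, p, istim, dt, k1, k2, k3, k4, tmp)
        v_out[i + 1] = state[0, 0]
        if not np.isfinite(state[0, 0]):
            return v_out, False, i
    return v_out, True, -1


def simulate_ap(
    params: CellParams,
    cycle_length_ms: float = 1000.0,
    n_beats: int = 3,
    dt_ms: float = 0.02,
    method: str = "rk4",
    stimulate: bool = True,
) -> APTrace:
    """Paced action-potential simulation.

    Parameters
    ----------
    params
        Cell constants including conductance scale factors.
    cycle_length_ms
        Pacing cycle length (1000 ms = 1 Hz).
    n_beats
        Number of paced beats; the trace covers ``n_beats * cycle_length_ms``.
    dt_ms
        Fixed integration step.
    method
        ``"rk4"`` (default) or ``"rl"`` (Rush-Larsen).
    stimulate
        If False, no stimulus is applied (resting-stability runs).
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if method not in ("rk4", "rl"):
        raise ValueError(f"unknown method {method!r}")
    p = params.to_vector()
    amp = params.stim_amplitude if stimulate else 0.0
    v, ok, bad = _run_cell(
        p, float(cycle_length_ms), int(n_beats), float(dt_ms),
        amp, params.stim_duration_ms, params.v_init, method == "rl",
    )
    if not ok:
        raise NumericalInstabilityError(
            f"non-finite membrane potential at step {bad} (t = {bad * dt_ms:.3f} ms); "
            f"reduce dt_ms (currently {dt_ms} ms)"
        )
    time = np.arange(v.size) * dt_ms
    stim_times = (
        np.arange(n_beats) * cycle_length_ms if stimulate else np.empty(0)
    )
    return APTrace(time=time, v=v, stimulus_times=stim_times,
                   dt_ms=dt_ms, cycle_length_ms=cycle_length_ms)


def ap_metrics(trace: APTrace, beat_index: int = -1) -> APMetrics:
    """Summary metrics of one beat of a paced trace.

    APD90 runs from activation (maximum dV/dt) to 90 % repolarization toward
    the pre-stimulus diastolic potential, with linear interpolation at the
    crossing.
    """
    n_beats = len(trace.stimulus_times)
    if n_beats == 0:
        raise NoCaptureError("trace has no stimuli; no beat to analyse")
    if beat_index < 0:
        beat_index += n_beats
    if not 0 <= beat_index < n_beats:
        raise IndexError(f"beat_index {beat_index} outside 0..{n_beats - 1}")
    t0 = trace.stimulus_times[beat_index]
    t1 = t0 + trace.cycle_length_ms
    i0 = int(round(t0 / trace.dt_ms))
    i1 = min(int(round(t1 / trace.dt_ms)), trace.v.size - 1)
    return _beat_metrics(trace.v, trace.dt_ms, i0, i1)


def _beat_metrics(v: np.ndarray, dt: float, i0: int, i1: int) -> APMetrics:
    seg = v[i0:i1 + 1]
    if seg.size < 3:
        raise NoCaptureError("beat window too short")
    v_rest = seg[0]
    dvdt = np.diff(seg) / dt
    k_act = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[k_act])
    v_peak = float(np.max(seg))
    if dvdt_max < 5.0 or v_peak - v_rest < 30.0:
        raise NoCaptureError(
            f"no upstroke detected (max dV/dt = {dvdt_max:.2f} mV/ms, "
            f"amplitude = {v_peak - v_rest:.1f} mV)"
        )
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    k_peak = int(np.argmax(seg))
    below = np.nonzero(seg[k_peak:] <= v90)[0]
    if below.size == 0:
        raise NoCaptureError("no 90% repolarization within beat window")
    k_cross = k_peak + below[0]
    # linear interpolation between k_cross-1 and k_cross
    va, vb = seg[k_cross - 1], seg[k_cross]
    frac = (va - v90) / (va - vb) if va != vb else 0.0
    t_cross = (k_cross - 1 + frac) * dt
    apd90 = t_cross - k_act * dt
    return APMetrics(
        apd90_ms=float(apd90),
        v_rest_mv=float(v_rest),
        v_peak_mv=v_peak,
        dvdt_max_mv_per_ms=dvdt_max,
    )


def scale_conductances(params: CellParams, s_Kr: float | None = None,
                       s_Ks: float | None = None,
                       s_CaL: float | None = None) -> CellParams:
    """Return a copy of ``params`` with scale factors replaced (original untouched)."""
    updates = {}
    for name, val in (("s_Kr", s_Kr), ("s_Ks", s_Ks), ("s_CaL", s_CaL)):
        if val is not None:
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
            updates[name] = float(val)
    return replace(params, **updates)


def stimulus_threshold(params: CellParams, cycle_length_ms: float = 1000.0,
                       dt_ms: float = 0.02, lo: float = 0.0, hi: float = 80.0,
                       tol: float = 0.5) -> float:
    """Diastolic stimulus threshold (uA/uF) for a 2 ms pulse, by bisection.

    The conventional stimulus is 1.5x this value.
    """
    def captures(amp: float) -> bool:
        p = replace(params, stim_amplitude=amp)
        tr = simulate_ap(p, cycle_length_ms, n_beats=1, dt_ms=dt_ms)
        try:
            ap_metrics(tr, 0)
            return True
        except NoCaptureError:
            return False

    if not captures(hi):
        raise ValueError(f"no capture even at amplitude {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi
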