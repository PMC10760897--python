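"""Isolated-cell simulation drivers, cycle-length measurement and
limit-cycle state caching.

Single cells are integrated with the same forward-Euler kernels and lookup
tables the tissue solver uses, so an isolated run and an uncoupled tissue
node are bit-identical.  The default time step is 2.5 us, the value used for
the tissue equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .cells import courtemanche as _ra
from .cells import fabbri as _san
from .cells.modulation import CellParameterSet

DEFAULT_DT = 0.0025  # ms
ACTIVATION_THRESHOLD = -40.0  # mV, upward-crossing detection


@dataclass(frozen=True)
class PulseTrain:
    """Rectangular stimulus pulses: amplitude in mV/ms (= pA/pF)."""

    start: float = 50.0
    duration: float = 2.0
    amplitude: float = 20.0
    period: float = 1e12
    count: int = 1


@dataclass
class Trace:
    """Sampled membrane potential of one cell."""

    t: np.ndarray           # ms
    v: np.ndarray           # mV
    final_state: np.ndarray
    final_v: float

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.v]),
                   delimiter=",", header="t_ms,V_mV", comments="")


@njit(cache=True)
def _drive_san(v0, s, dt, nsteps, tab, cp, sna, sf, sk1, skach,
               p_start, p_dur, p_amp, p_period, p_count, rec_every, out):
    v = v0
    for k in range(nsteps):
        t = k * dt
        stim = 0.0
        if p_count > 0 and t >= p_start:
            ph = (t - p_start) % p_period
            idx = (t - p_start) // p_period
            if idx < p_count and ph < p_dur:
                stim = p_amp
        dv = _san.san_node_step(v, s, dt, tab, cp, sna, sf, sk1, skach)
        v += dt * (dv + stim)
        if not np.isfinite(v) or abs(v) > 150.0:
            return v, k
        if k % rec_every == rec_every - 1:
            out[k // rec_every] = v
    return v, -1


@njit(cache=True)
def _drive_ra(v0, s, dt, nsteps, tab, sna,
              p_start, p_dur, p_amp, p_period, p_count, rec_every, out):
    v = v0
    for k in range(nsteps):
        t = k * dt
        stim = 0.0
        if p_count > 0 and t >= p_start:
            ph = (t - p_start) % p_period
            idx = (t - p_start) // p_period
            if idx < p_count and ph < p_dur:
                stim = p_amp
        dv = _ra.ra_node_step(v, s, dt, tab, sna)
        v += dt * (dv + stim)
        if not np.isfinite(v) or abs(v) > 150.0:
            return v, k
        if k % rec_every == rec_every - 1:
            out[k // rec_every] = v
    return v, -1


def run_single_cell(params: CellParameterSet, duration: float,
                    dt: float = DEFAULT_DT, stimulus: PulseTrain | None = None,
                    record_interval: float = 1.0,
                    initial: tuple[float, np.ndarray] | None = None) -> Trace:
    """Forward-Euler trajectory of one cell; returns the sampled V(t).

    ``initial`` is an optional (V, state) pair; by default the model's
    cold-start state is used (production tissue runs use cached limit-cycle
    states instead, see :func:`limit_cycle_state`).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    nsteps = int(round(duration / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    out = np.zeros(nsteps // rec_every)
    p = stimulus or PulseTrain(count=0)

    if params.model_kind == "SAN":
        tab = _san.build_tables(params.ach_nM)
        cp = _san.cell_params(params.ach_nM, params.override_dict() or None)
        if initial is None:
            v0, s = -60.0, _san.initial_state()
        else:
            v0, s = initial[0], initial[1].copy()
        v, bad = _drive_san(v0, s, dt, nsteps, tab, cp,
                            params.scale_na, params.scale_f, params.scale_k1,
                            params.scale_kach, p.start, p.duration, p.amplitude,
                            p.period, p.count, rec_every, out)
    else:
        tab = _ra.build_tables(params.ach_nM)
        if initial is None:
            v0, s = _ra.initial_state()
            s = s.copy()
        else:
            v0, s = initial[0], initial[1].copy()
        v, bad = _drive_ra(v0, s, dt, nsteps, tab, params.scale_na,
                           p.start, p.duration, p.amplitude,
                           p.period, p.count, rec_every, out)
    if bad >= 0:
        raise RuntimeError(
            f"numerical blow-up at step {bad} (t = {bad * dt:.4f} ms), V = {v:.1f} mV")
    t = (np.arange(out.size) + 1.0) * rec_every * dt
    return Trace(t=t, v=out, final_state=s, final_v=v)


def measure_cycle_length(trace: Trace | np.ndarray,
                         threshold: float = ACTIVATION_THRESHOLD,
                         discard_fraction: float = 0.3) -> float | None:
    """Mean firing interval from upward threshold crossings.

    The first ``discard_fraction`` of the trace is discarded as transient;
    the mean interval over the remaining beats is returned, or ``None``
    ("no activity") if fewer than two crossings remain.
    """
    if isinstance(trace, Trace):
        t, v = trace.t, trace.v
    else:
        v = np.asarray(trace)
        t = np.arange(v.size, dtype=float)
    i0 = int(v.size * discard_fraction)
    vv = v[i0:]
    ups = np.where((vv[:-1] < threshold) & (vv[1:] >= threshold))[0]
    if ups.size < 2:
        return None
    return float(np.diff(t[i0:][ups]).mean())


_LIMIT_CYCLE_CACHE: dict = {}


def limit_cycle_state(params: CellParameterSet, settle_ms: float = 40000.0,
                      dt: float = DEFAULT_DT) -> tuple[float, np.ndarray]:
    """(V, state) of the cell after a long settling run.

    For automatic cells this is a point on the limit cycle shortly after a
    repolarisation; for quiescent cells it is the resting state.  Results
    are cached per parameter set within the process.
    """
    key = (params.model_kind, params.scale_na, params.scale_f, params.scale_k1,
           params.scale_kach, params.ach_nM, params.overrides, settle_ms, dt)
    hit = _LIMIT_CYCLE_CACHE.get(key)
    if hit is not None:
        return hit[0], hit[1].copy()
    tr = run_single_cell(params, settle_ms, dt=dt, record_interval=1.0)
    _LIMIT_CYCLE_CACHE[key] = (tr.final_v, tr.final_state.copy())
    return tr.final_v, tr.final_state.copy()


def primed_state(params: CellParameterSet, lead_ms: float = 120.0,
                 settle_ms: float = 40000.0,
                 dt: float = DEFAULT_DT) -> tuple[float, np.ndarray]:
    """Limit-cycle state advanced to ``lead_ms`` before the next upstroke.

    Lets tissue runs begin shortly before a beat instead of at an arbitrary
    phase, shortening the lead-in transient.  Quiescent cells return their
    resting state unchanged.
    """
    key = ("primed", params.model_kind, params.scale_na, params.scale_f,
           params.scale_k1, params.scale_kach, params.ach_nM, params.overrides,
           lead_ms, settle_ms, dt)
    hit = _LIMIT_CYCLE_CACHE.get(key)
    if hit is not None:
        return hit[0], hit[1].copy()
    v0, s0 = limit_cycle_state(params, settle_ms=settle_ms, dt=dt)
    # sample (V, state) every ms over up to three further cycles
    horizon = 3000.0
    nsteps = int(horizon / dt)
    rec = int(1.0 / dt)
    n_snap = nsteps // rec
    snaps_v = np.zeros(n_snap)
    snaps_s = np.zeros((n_snap, s0.size))
    v, s = v0, s0.copy()
    if params.model_kind == "SAN":
        tab = _san.build_tables(params.ach_nM)
        cp = _san.cell_params(params.ach_nM, params.override_dict() or None)
        for k in range(n_snap):
            for _ in range(rec):
                dv = _san.san_node_step(v, s, dt, tab, cp, params.scale_na,
                                        params.scale_f, params.scale_k1,
                                        params.scale_kach)
                v += dt * dv
            snaps_v[k] = v
            snaps_s[k] = s
    else:
        tab = _ra.build_tables(params.ach_nM)
        for k in range(n_snap):
            for _ in range(rec):
                dv = _ra.ra_node_step(v, s, dt, tab, params.scale_na)
                v += dt * dv
            snaps_v[k] = v
            snaps_s[k] = s
    ups = np.where((snaps_v[:-1] < ACTIVATION_THRESHOLD)
                   & (snaps_v[1:] >= ACTIVATION_THRESHOLD))[0]
    if ups.size == 0:
        out = (v0, s0)
    else:
        k = max(int(ups[-1] + 1 - lead_ms), 0)
        out = (float(snaps_v[k]), snaps_s[k].copy())
    _LIMIT_CYCLE_CACHE[key] = (out[0], out[1].copy())
    return out[0], out[1].copy()
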