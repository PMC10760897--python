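"""Monodomain reaction-diffusion solver on the labelled grid.

The tissue equation is dV/dt = div(D grad V) - I_ion/Cm + I_stim with a
rank-2 diffusivity tensor per node, D(theta) = R diag(D_long, D_trans) R^T.
Space is discretised with a face-flux finite-difference stencil (harmonic
mean interface diffusivities; centred cross-derivative terms when the local
tensor is not axis-aligned); time with forward Euler, the same integrator
used for the single-cell equations.  The insulating wall is treated exactly
as specified for the tissue model: wall nodes keep a constant potential of
-62.5 mV (re-clamped every step) *and* carry a vanishing diffusivity, so
only a negligible electrotonic load leaks across the border.

The assembled stencil has exactly zero row sums, so any uniform potential
field is a fixed point of the diffusion operator (machine precision).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from .cells import courtemanche as _ra
from .cells import fabbri as _san
from .cells.modulation import CellParameterSet
from .geometry import DiffusivityField, TissueGeometry
from .regions import Region, RegionalScalingTable, SAN_MODEL_REGIONS, default_scaling_table
from .singlecell import limit_cycle_state, primed_state

WALL_POTENTIAL = -62.5  # mV, mean of SAN and RA resting potentials
V_ABORT = 100.0         # |V| beyond this aborts with a diagnostic


@dataclass(frozen=True)
class Stimulus:
    """Rectangular current pulses on a rectangular patch (mm coordinates)."""

    x_mm: float
    y_mm: float
    size_mm: float = 0.4
    start: float = 0.0
    duration: float = 2.0
    amplitude: float = 40.0  # mV/ms (= pA/pF)
    period: float = 1e12
    count: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    duration: float            # ms
    dt: float = 0.01           # ms (tissue default; single cells use 0.0025)
    record_interval: float = 2.0
    stimuli: tuple[Stimulus, ...] = ()
    ach_nM: float = 0.0
    base_d_ra: float = 0.1     # mm^2/ms
    anisotropy_ratio: float = 10.0
    settle_single_cell_ms: float = 40000.0
    prime_ms: float | None = None  # start this many ms before the next upstroke


@dataclass
class Recording:
    """Sampled V over time x active nodes, plus metadata."""

    times: np.ndarray          # ms, frame times
    frames: np.ndarray         # float32 (n_frames, n_active)
    active_rows: np.ndarray
    active_cols: np.ndarray
    shape: tuple[int, int]
    dt: float
    meta: dict = field(default_factory=dict)

    def frame_grid(self, i: int, fill: float = np.nan) -> np.ndarray:
        g = np.full(self.shape, fill, np.float32)
        g[self.active_rows, self.active_cols] = self.frames[i]
        return g

    def trace_at(self, row: int, col: int) -> np.ndarray:
        idx = np.where((self.active_rows == row) & (self.active_cols == col))[0]
        if idx.size == 0:
            raise KeyError(f"node ({row},{col}) is not active")
        return self.frames[:, idx[0]].astype(np.float64)

    def node_traces(self, mask: np.ndarray) -> np.ndarray:
        sel = mask[self.active_rows, self.active_cols]
        return self.frames[:, sel]

    def content_hash(self) -> str:
        return hashlib.sha256(self.frames.tobytes()).hexdigest()

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f["times"] = self.times
            f["frames"] = self.frames
            f["active_rows"] = self.active_rows
            f["active_cols"] = self.active_cols
            f.attrs["shape"] = self.shape
            f.attrs["dt"] = self.dt
            for k, v in self.meta.items():
                f.attrs[k] = v


def assemble_stencil(dfield: DiffusivityField, dx: float,
                     active: np.ndarray | None = None,
                     include_diagonal: bool = True) -> sparse.csr_matrix:
    """Sparse operator approximating div(D grad V) on active nodes.

    With ``include_diagonal=False`` only the neighbour weights are
    returned; the solver applies them in difference form,
    sum_j w_ij (V_j - V_i), which preserves uniform fields exactly.

    ``active`` selects the nodes carried by the operator (default: any node
    with nonzero diffusivity); fluxes across faces to inactive or
    zero-diffusivity nodes vanish (no-flux), as do fluxes across the domain
    boundary.  Row sums are identically zero.
    """
    dl, dt_, ang = dfield.d_long, dfield.d_trans, dfield.fiber_angle
    ny, nx = dl.shape
    dxx = dl * np.cos(ang) ** 2 + dt_ * np.sin(ang) ** 2
    dyy = dl * np.sin(ang) ** 2 + dt_ * np.cos(ang) ** 2
    dxy = (dl - dt_) * np.sin(ang) * np.cos(ang)

    if active is None:
        active = dl > 0
    idx = -np.ones((ny, nx), np.int64)
    rows_a, cols_a = np.where(active)
    idx[rows_a, cols_a] = np.arange(rows_a.size)
    n = rows_a.size
    inv_h2 = 1.0 / dx ** 2

    entries_r, entries_c, entries_v = [], [], []

    def harm(a, b):
        s = a + b
        out = np.zeros_like(a)
        ok = (a > 0) & (b > 0)
        out[ok] = 2.0 * a[ok] * b[ok] / s[ok]
        return out

    # axis fluxes (E/W use Dxx, N/S use Dyy)
    for drow, dcol, dten in ((0, 1, dxx), (0, -1, dxx), (1, 0, dyy), (-1, 0, dyy)):
        nb_r = rows_a + drow
        nb_c = cols_a + dcol
        ok = (nb_r >= 0) & (nb_r < ny) & (nb_c >= 0) & (nb_c < nx)
        ok2 = ok.copy()
        ok2[ok] = active[nb_r[ok], nb_c[ok]]
        r0, c0 = rows_a[ok2], cols_a[ok2]
        r1, c1 = r0 + drow, c0 + dcol
        w = harm(dten[r0, c0], dten[r1, c1]) * inv_h2
        keep = w > 0
        entries_r.append(idx[r0, c0][keep])
        entries_c.append(idx[r1, c1][keep])
        entries_v.append(w[keep])

    # cross-derivative terms (vanish for axis-aligned fibers)
    if np.any(np.abs(dxy) > 1e-15):
        inv_4h2 = inv_h2 / 4.0
        for sr in (-1, 1):
            for sc in (-1, 1):
                nb_r = rows_a + sr
                nb_c = cols_a + sc
                ok = (nb_r >= 0) & (nb_r < ny) & (nb_c >= 0) & (nb_c < nx)
                ok2 = ok.copy()
                ok2[ok] = active[nb_r[ok], nb_c[ok]]
                r0, c0 = rows_a[ok2], cols_a[ok2]
                r1, c1 = r0 + sr, c0 + sc
                # d/dx(Dxy dV/dy) + d/dy(Dxy dV/dx), centred product average
                w = sr * sc * (dxy[r0, c1] + dxy[r1, c0]) * inv_4h2
                keep = np.abs(w) > 0
                entries_r.append(idx[r0, c0][keep])
                entries_c.append(idx[r1, c1][keep])
                entries_v.append(w[keep])

    rows = (np.concatenate(entries_r) if entries_r else np.zeros(0, np.int64))
    cols = (np.concatenate(entries_c) if entries_c else np.zeros(0, np.int64))
    vals = (np.concatenate(entries_v) if entries_v else np.zeros(0))
    off = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if not include_diagonal:
        return off
    if vals.size == 0:
        return off
    diag = -np.asarray(off.sum(axis=1)).ravel()
    return (off + sparse.diags(diag)).tocsr()


def diffusion_term(v_grid: np.ndarray, dfield: DiffusivityField, dx: float) -> np.ndarray:
    """div(D grad V) on the full grid (zero at inactive nodes).

    Evaluated in difference form (sum_j w_ij (V_j - V_i)), so uniform
    potentials map to exactly zero."""
    if not np.all(np.isfinite(v_grid[dfield.d_long > 0])):
        bad = np.argwhere(~np.isfinite(v_grid) & (dfield.d_long > 0))[0]
        raise ValueError(f"non-finite potential at node {tuple(bad)}")
    off = assemble_stencil(dfield, dx, include_diagonal=False).tocoo()
    rows, cols = np.where(dfield.d_long > 0)
    v = v_grid[rows, cols]
    contrib = off.data * (v[off.col] - v[off.row])
    out = np.zeros_like(v_grid, dtype=float)
    out[rows, cols] = np.bincount(off.row, weights=contrib, minlength=v.size)
    return out


@njit(cache=True)
def _run_loop(v, indptr, indices, data, dt, nsteps,
              san_pos, san_states, san_sna, san_sf, san_sk1, san_skach,
              san_tab, san_cp,
              ra_pos, ra_states, ra_sna, ra_tab,
              wall_pos, wall_v,
              stim_ptr, stim_nodes, stim_params,
              rec_every, frames, probe_pos, probes,
              check_every):
    n = v.size
    diff = np.zeros(n)
    nstim = stim_ptr.size - 1
    frame_i = 0
    for k in range(nsteps):
        t = k * dt
        # diffusion in difference form: exact on uniform fields
        for i in range(n):
            acc = 0.0
            vi = v[i]
            for jj in range(indptr[i], indptr[i + 1]):
                acc += data[jj] * (v[indices[jj]] - vi)
            diff[i] = acc
        # ionic updates
        for j in range(san_pos.size):
            p = san_pos[j]
            dv = _san.san_node_step(v[p], san_states[j], dt, san_tab, san_cp,
                                    san_sna[j], san_sf[j], san_sk1[j], san_skach[j])
            diff[p] += dv
        for j in range(ra_pos.size):
            p = ra_pos[j]
            dv = _ra.ra_node_step(v[p], ra_states[j], dt, ra_tab, ra_sna[j])
            diff[p] += dv
        # stimuli
        for sidx in range(nstim):
            start = stim_params[sidx, 0]
            dur = stim_params[sidx, 1]
            period = stim_params[sidx, 2]
            count = stim_params[sidx, 3]
            amp = stim_params[sidx, 4]
            if t >= start:
                ph = (t - start) % period
                rep = (t - start) // period
                if rep < count and ph < dur:
                    for jj in range(stim_ptr[sidx], stim_ptr[sidx + 1]):
                        diff[stim_nodes[jj]] += amp
        # explicit update + wall clamp
        for i in range(n):
            v[i] += dt * diff[i]
        for j in range(wall_pos.size):
            v[wall_pos[j]] = wall_v
        # recording
        if k % rec_every == rec_every - 1:
            for i in range(n):
                frames[frame_i, i] = v[i]
            for j in range(probe_pos.size):
                probes[frame_i, j] = v[probe_pos[j]]
            frame_i += 1
        if k % check_every == 0:
            for i in range(n):
                if not np.isfinite(v[i]) or abs(v[i]) > V_ABORT:
                    return k, i
    return -1, -1


def simulate(geom: TissueGeometry, config: SimulationConfig,
             scaling_table: RegionalScalingTable | None = None,
             dfield: DiffusivityField | None = None,
             ra_na_scale: float = 1.0,
             san_overrides: dict | None = None,
             initial_ach_nM: float = 0.0,
             probes: list[tuple[int, int]] | None = None) -> Recording:
    """End-to-end tissue run.

    Each region's cells start from that region's isolated-cell limit-cycle
    (SAN compartments) or resting (SACP / RA) state at ``initial_ach_nM``
    (default: drug-free), computed once and cached; the dose in
    ``config.ach_nM`` then acts from t = 0, as in an acute administration.
    """
    from .geometry import build_diffusivity_field

    table = scaling_table or default_scaling_table()
    if dfield is None:
        dfield = build_diffusivity_field(geom, config.base_d_ra,
                                         anisotropy_ratio=config.anisotropy_ratio)
    dmax = max(dfield.d_long.max(), 1e-30)
    if config.dt > geom.dx ** 2 / (4.0 * dmax):
        raise ValueError(
            f"unstable: dt={config.dt} exceeds dx^2/(4 Dmax)="
            f"{geom.dx ** 2 / (4 * dmax):.3g} ms")

    active = geom.conductive | geom.mask(Region.WALL)
    rows_a, cols_a = np.where(active)
    pos_of = -np.ones(geom.shape, np.int64)
    pos_of[rows_a, cols_a] = np.arange(rows_a.size)
    labels_a = geom.labels[rows_a, cols_a]

    L = assemble_stencil(dfield, geom.dx, active=active, include_diagonal=False)

    # per-node scale arrays and initial states
    san_sel = np.isin(labels_a, [int(r) for r in SAN_MODEL_REGIONS])
    ra_sel = labels_a == int(Region.RA)
    wall_sel = labels_a == int(Region.WALL)
    san_pos = np.where(san_sel)[0]
    ra_pos = np.where(ra_sel)[0]
    wall_pos = np.where(wall_sel)[0]

    v0 = np.full(rows_a.size, WALL_POTENTIAL)
    san_states = np.zeros((san_pos.size, _san.N_STATES))
    nscale = {r: table[r] for r in SAN_MODEL_REGIONS}
    san_sna = np.zeros(san_pos.size)
    san_sf = np.zeros(san_pos.size)
    san_sk1 = np.zeros(san_pos.size)
    san_skach = np.zeros(san_pos.size)
    ov = tuple(sorted((san_overrides or {}).items()))
    for r in SAN_MODEL_REGIONS:
        sc = nscale[r]
        params = CellParameterSet(model_kind="SAN", scale_na=sc.i_na, scale_f=sc.i_f,
                                  scale_k1=sc.i_k1, scale_kach=sc.i_kach,
                                  ach_nM=initial_ach_nM, overrides=ov)
        if config.prime_ms is not None:
            v_r, s_r = primed_state(params, lead_ms=config.prime_ms,
                                    settle_ms=config.settle_single_cell_ms)
        else:
            v_r, s_r = limit_cycle_state(params, settle_ms=config.settle_single_cell_ms)
        sel = labels_a[san_pos] == int(r)
        san_states[sel] = s_r
        v0[san_pos[sel]] = v_r
        san_sna[sel] = sc.i_na
        san_sf[sel] = sc.i_f
        san_sk1[sel] = sc.i_k1
        san_skach[sel] = sc.i_kach

    ra_params = CellParameterSet(model_kind="RA", scale_na=ra_na_scale,
                                 ach_nM=initial_ach_nM)
    v_ra, s_ra = limit_cycle_state(ra_params, settle_ms=5000.0)
    ra_states = np.tile(s_ra, (ra_pos.size, 1))
    v0[ra_pos] = v_ra
    ra_sna = np.full(ra_pos.size, ra_na_scale)

    san_tab = _san.build_tables(config.ach_nM)
    san_cp = _san.cell_params(config.ach_nM, dict(ov) or None)
    ra_tab = _ra.build_tables(config.ach_nM)

    # stimuli -> node lists
    stim_ptr = [0]
    stim_nodes = []
    stim_params = np.zeros((len(config.stimuli), 5))
    for i, st in enumerate(config.stimuli):
        r0 = int((st.y_mm - st.size_mm / 2) / geom.dx)
        r1 = int(np.ceil((st.y_mm + st.size_mm / 2) / geom.dx))
        c0 = int((st.x_mm - st.size_mm / 2) / geom.dx)
        c1 = int(np.ceil((st.x_mm + st.size_mm / 2) / geom.dx))
        patch = pos_of[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1].ravel()
        patch = patch[patch >= 0]
        stim_nodes.append(patch)
        stim_ptr.append(stim_ptr[-1] + patch.size)
        stim_params[i] = (st.start, st.duration, st.period, st.count, st.amplitude)
    stim_nodes = (np.concatenate(stim_nodes) if stim_nodes
                  else np.zeros(0, np.int64))
    stim_ptr = np.asarray(stim_ptr, np.int64)

    nsteps = int(round(config.duration / config.dt))
    rec_every = max(1, int(round(config.record_interval / config.dt)))
    n_frames = nsteps // rec_every
    frames = np.zeros((n_frames, rows_a.size), np.float32)
    probe_pos = np.asarray([pos_of[r, c] for r, c in (probes or [])], np.int64)
    probe_arr = np.zeros((n_frames, probe_pos.size))

    bad_step, bad_node = _run_loop(
        v0, L.indptr, L.indices, L.data, config.dt, nsteps,
        san_pos, san_states, san_sna, san_sf, san_sk1, san_skach,
        san_tab, san_cp,
        ra_pos, ra_states, ra_sna, ra_tab,
        wall_pos, WALL_POTENTIAL,
        stim_ptr, stim_nodes, stim_params,
        rec_every, frames, probe_pos, probe_arr,
        max(1, int(round(1.0 / config.dt))))
    if bad_step >= 0:
        r, c = rows_a[bad_node], cols_a[bad_node]
        raise RuntimeError(
            f"instability at t={bad_step * config.dt:.3f} ms, node ({r},{c}), "
            f"label {Region(geom.labels[r, c]).name}")

    times = (np.arange(n_frames) + 1.0) * rec_every * config.dt
    meta = dict(ach_nM=config.ach_nM, dt=config.dt, dx=geom.dx,
                base_d_ra=config.base_d_ra,
                geometry_hash=hashlib.sha256(geom.labels.tobytes()).hexdigest()[:16])
    rec = Recording(times=times, frames=frames, active_rows=rows_a,
                    active_cols=cols_a, shape=geom.shape, dt=config.dt, meta=meta)
    rec.meta["probes"] = probe_arr if probe_pos.size else None
    return rec
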