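"""Monodomain solver: stencil exactness, single-cell decoupling, planar
conduction, stimulus handling, determinism and stability guards."""

import numpy as np
import pytest

from sancomplex.analysis import activation_times
from sancomplex.cells.modulation import CellParameterSet
from sancomplex.geometry import (DiffusivityField, GeometryConfig, TissueGeometry,
                                 build_synthetic_complex)
from sancomplex.protocols import geometry_preset
from sancomplex.regions import Region
from sancomplex.singlecell import limit_cycle_state, run_single_cell
from sancomplex.solver import (SimulationConfig, Stimulus, WALL_POTENTIAL,
                               assemble_stencil, diffusion_term, simulate)


def homogeneous_field(ny, nx, d, aniso=1.0, angle=0.0):
    dl = np.full((ny, nx), d)
    return DiffusivityField(d_long=dl, d_trans=dl / aniso,
                            fiber_angle=np.full((ny, nx), angle))


def ra_strip(length_mm, width_mm, dx):
    ny = max(3, int(round(width_mm / dx)))
    nx = int(round(length_mm / dx))
    labels = np.full((ny, nx), int(Region.RA), np.int8)
    return TissueGeometry(labels=labels, fiber_angle=np.zeros((ny, nx)), dx=dx)


def test_uniform_potential_is_fixed_point():
    df = homogeneous_field(20, 30, 0.1)
    out = diffusion_term(np.full((20, 30), -55.0), df, 0.1)
    assert np.all(out == 0.0)
    # rotated anisotropic tensor: zero to machine precision
    df2 = homogeneous_field(20, 30, 0.1, aniso=10.0, angle=0.6)
    out2 = diffusion_term(np.full((20, 30), -55.0), df2, 0.1)
    assert np.abs(out2).max() < 1e-10


def test_linear_ramp_interior_zero():
    df = homogeneous_field(20, 40, 0.1)
    v = 3.0 * np.arange(40)[None, :] * np.ones((20, 1))
    out = diffusion_term(v, df, 0.1)
    assert np.abs(out[1:-1, 1:-1]).max() == 0.0
    assert np.abs(out[:, [0, -1]]).max() > 0.0  # no-flux boundary correction


def test_gaussian_peak_follows_heat_kernel():
    """Free diffusion of a Gaussian: peak decays as s0^2/(s0^2 + 2 D t)."""
    n, dx, d = 81, 0.05, 0.05
    df = homogeneous_field(n, n, d)
    L = assemble_stencil(df, dx)
    x = (np.arange(n) - n // 2) * dx
    X, Y = np.meshgrid(x, x)
    s0 = 0.3
    v = np.exp(-(X ** 2 + Y ** 2) / (2 * s0 ** 2)).ravel()
    dt = 0.2 * dx * dx / (4 * d)
    t = 0.0
    while t < 4.0 - 1e-9:
        v = v + dt * (L @ v)
        t += dt
    expected = s0 ** 2 / (s0 ** 2 + 2 * d * t)
    assert v.max() == pytest.approx(expected, rel=0.01)


def test_nonfinite_input_rejected():
    df = homogeneous_field(5, 5, 0.1)
    v = np.zeros((5, 5))
    v[2, 2] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        diffusion_term(v, df, 0.1)


def test_uncoupled_tissue_matches_single_cell_exactly(scaling_table):
    """With D = 0 every node follows its isolated-cell trajectory bit for
    bit (same kernels, same step)."""
    ny = nx = 3
    labels = np.full((ny, nx), int(Region.SAN_CENTER), np.int8)
    geom = TissueGeometry(labels=labels, fiber_angle=np.zeros((ny, nx)), dx=0.1)
    df = DiffusivityField(d_long=np.zeros((ny, nx)), d_trans=np.zeros((ny, nx)),
                          fiber_angle=np.zeros((ny, nx)))
    dt = 0.01
    cfg = SimulationConfig(duration=400.0, dt=dt, record_interval=1.0,
                           settle_single_cell_ms=5000.0)
    rec = simulate(geom, cfg, scaling_table=scaling_table, dfield=df,
                   probes=[(1, 1)])
    probe = rec.meta["probes"][:, 0]

    params = CellParameterSet(model_kind="SAN")
    init = limit_cycle_state(params, settle_ms=5000.0, dt=0.0025)
    tr = run_single_cell(params, 400.0, dt=dt, record_interval=1.0, initial=init)
    assert np.array_equal(probe, tr.v)


def test_quiescent_atrial_sheet_stays_at_rest():
    geom = ra_strip(2.0, 1.0, 0.1)
    cfg = SimulationConfig(duration=1000.0, dt=0.01, base_d_ra=0.05)
    rec = simulate(geom, cfg)
    v = rec.frames.astype(np.float64)
    assert np.abs(v - v[0]).max() < 0.1


def test_stimulus_train_timing_and_capture():
    geom = ra_strip(4.0, 0.6, 0.1)
    stim = Stimulus(x_mm=0.3, y_mm=0.3, size_mm=0.4, start=20.0, duration=2.0,
                    amplitude=40.0, period=400.0, count=3)
    cfg = SimulationConfig(duration=1300.0, dt=0.01, base_d_ra=0.05,
                           stimuli=(stim,), record_interval=1.0)
    rec = simulate(geom, cfg, probes=[(3, 35)])
    v = rec.meta["probes"][:, 0]
    ups = np.where((v[:-1] < -40.0) & (v[1:] >= -40.0))[0]
    assert ups.size == 3, "each suprathreshold pulse elicits exactly one AP"
    periods = np.diff(rec.times[ups])
    assert np.allclose(periods, 400.0, atol=5.0)

    weak = Stimulus(x_mm=0.3, y_mm=0.3, size_mm=0.4, start=20.0, duration=2.0,
                    amplitude=2.0, period=400.0, count=3)
    rec2 = simulate(geom, SimulationConfig(duration=700.0, dt=0.01, base_d_ra=0.05,
                                           stimuli=(weak,), record_interval=1.0),
                    probes=[(3, 35)])
    v2 = rec2.meta["probes"][:, 0]
    assert np.all(v2 < -40.0), "a subthreshold pulse must not capture"


def _strip_cv(dx, d, duration=30.0, length=8.0):
    geom = ra_strip(length, 0.6, dx)
    dt = min(0.01, 0.8 * dx * dx / (4 * d))
    stim = Stimulus(x_mm=0.3, y_mm=0.3, size_mm=0.5, start=2.0, duration=2.0,
                    amplitude=60.0)
    cfg = SimulationConfig(duration=duration, dt=dt, base_d_ra=d,
                           stimuli=(stim,), record_interval=0.5)
    rec = simulate(geom, cfg)
    amap = activation_times(rec, (0.0, duration))
    row = geom.shape[0] // 2
    cols = np.arange(int(0.3 * geom.shape[1]), int(0.8 * geom.shape[1]))
    tt = amap.times[row, cols]
    assert np.all(np.isfinite(tt))
    slope = np.polyfit(cols * dx, tt, 1)[0]
    return 1.0 / slope


def test_planar_cv_scales_with_sqrt_d():
    cv_full = _strip_cv(0.04, 0.05)
    cv_quarter = _strip_cv(0.04, 0.0125, duration=60.0)
    assert cv_full / cv_quarter == pytest.approx(2.0, rel=0.10)


def test_repeated_runs_are_bit_identical():
    geom = ra_strip(3.0, 0.6, 0.1)
    stim = Stimulus(x_mm=0.3, y_mm=0.3, start=10.0, amplitude=40.0)
    cfg = SimulationConfig(duration=200.0, dt=0.01, base_d_ra=0.05, stimuli=(stim,))
    h1 = simulate(geom, cfg).content_hash()
    h2 = simulate(geom, cfg).content_hash()
    assert h1 == h2


def test_wall_nodes_stay_clamped():
    cfg = GeometryConfig(domain_mm=(6.0, 4.0), dx_mm=0.2, san_length_mm=4.0,
                         san_width_mm=1.0, septal_margin_mm=0.6,
                         sacps=(type(geometry_preset("desk").sacps[0])(
                             "only", 0.5, "head", 0.8, 0.6),))
    geom = build_synthetic_complex(cfg)
    rec = simulate(geom, SimulationConfig(duration=300.0, dt=0.01, base_d_ra=0.05))
    wall = rec.node_traces(geom.mask(Region.WALL))
    assert np.all(wall == np.float32(WALL_POTENTIAL))


def test_stability_guard_rejects_large_dt():
    geom = ra_strip(2.0, 0.6, 0.04)
    with pytest.raises(ValueError, match="unstable"):
        simulate(geom, SimulationConfig(duration=10.0, dt=0.05, base_d_ra=0.1))
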