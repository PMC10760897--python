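"""Activation analysis on constructed recordings: crossing detection,
maps, SACT/exit measurements and the outcome taxonomy."""

import numpy as np
import pytest

from sancomplex.analysis import (ActivationMap, CLASSES, activation_times,
                                 classify_outcome, conduction_velocity,
                                 exit_site, leading_pacemaker, sact)
from sancomplex.regions import Region, SAN_COMPARTMENTS
from sancomplex.solver import Recording, WALL_POTENTIAL

REST = -80.0
PLATEAU = 0.0


def waveform(dt_from_act):
    """Piecewise-linear AP surrogate: linear rise REST->PLATEAU centred on
    the activation instant (so -40 mV is crossed exactly then), 80 ms
    plateau, 20 ms linear repolarisation."""
    t = dt_from_act
    v = np.full_like(t, REST)
    rise = (t >= -2.0) & (t < 2.0)
    v[rise] = REST + (PLATEAU - REST) * (t[rise] + 2.0) / 4.0
    plat = (t >= 2.0) & (t < 82.0)
    v[plat] = PLATEAU
    fall = (t >= 82.0) & (t < 102.0)
    v[fall] = PLATEAU + (REST - PLATEAU) * (t[fall] - 82.0) / 20.0
    return v


def make_recording(geom, delay_maps, duration, frame_ms=2.0):
    """Recording whose nodes fire the surrogate AP at prescribed times.

    ``delay_maps``: list of full-grid activation-time arrays (NaN = node
    silent during that beat)."""
    active = geom.conductive | geom.mask(Region.WALL)
    rows, cols = np.where(active)
    times = (np.arange(int(duration / frame_ms)) + 1.0) * frame_ms
    frames = np.full((times.size, rows.size), REST, np.float32)
    for dm in delay_maps:
        acts = dm[rows, cols]
        ok = np.isfinite(acts)
        dt_mat = times[:, None] - acts[None, ok]
        frames[:, ok] = np.maximum(frames[:, ok], waveform(dt_mat))
    frames[:, geom.mask(Region.WALL)[rows, cols]] = WALL_POTENTIAL
    return Recording(times=times, frames=frames, active_rows=rows,
                     active_cols=cols, shape=geom.shape, dt=frame_ms)


def seeded_beat(geom, t0, seed_rc=None, exit_name="middle_lateral",
                sact_ms=75.0, san_speed=0.15, ra_speed=0.5,
                include_ra=True, sacp_names=None):
    """Full-grid delay map for one beat: a wave spreading from a SAN seed,
    plus the atrium activating from one pathway mouth after ``sact_ms``."""
    dm = np.full(geom.shape, np.nan)
    rr, cc = np.mgrid[0:geom.shape[0], 0:geom.shape[1]]
    san = geom.mask(*SAN_COMPARTMENTS)
    if seed_rc is None:
        pts = np.argwhere(geom.mask(Region.SAN_CENTER))
        seed_rc = tuple(pts[len(pts) // 2])
    dist = np.hypot(rr - seed_rc[0], cc - seed_rc[1]) * geom.dx
    dm[san] = t0 + dist[san] / san_speed
    if include_ra:
        d = geom.sacp_by_name(exit_name)
        mouth = (d.rows.min(), int(np.median(d.cols)))
        dra = np.hypot(rr - mouth[0], cc - mouth[1]) * geom.dx
        ra = geom.mask(Region.RA)
        dm[ra] = t0 + sact_ms + dra[ra] / ra_speed
        names = sacp_names if sacp_names is not None else [exit_name]
        for nm in names:
            dd = geom.sacp_by_name(nm)
            span = dd.rows.max() - dd.rows.min() + 1
            frac = (dd.rows.max() - dd.rows) / max(span - 1, 1)
            dm[dd.rows, dd.cols] = t0 + sact_ms - 10.0 + 10.0 * frac
    return dm, seed_rc


def test_activation_time_linear_interpolation(desk_geometry):
    g = desk_geometry
    dm = np.full(g.shape, np.nan)
    pts = np.argwhere(g.mask(Region.SAN_CENTER))
    r0, c0 = pts[0]
    dm[r0, c0] = 123.0
    rec = make_recording(g, [dm], duration=400.0)
    am = activation_times(rec, (0.0, 400.0))
    assert am.times[r0, c0] == pytest.approx(123.0, abs=1e-3)
    # every other node stayed flat and is flagged unactivated
    assert np.isnan(am.times[pts[5][0], pts[5][1]])


def test_frame_interval_guard(desk_geometry):
    g = desk_geometry
    rec = make_recording(g, [], duration=100.0, frame_ms=4.0)
    with pytest.raises(ValueError, match="frame interval"):
        activation_times(rec, (0.0, 100.0))


def test_plane_wave_gradient_matches_imposed_speed(desk_geometry):
    g = desk_geometry
    c = 0.4  # mm/ms
    dm = np.full(g.shape, np.nan)
    ra = g.mask(Region.RA)
    cc = np.mgrid[0:g.shape[0], 0:g.shape[1]][1]
    dm[ra] = 50.0 + cc[ra] * g.dx / c
    rec = make_recording(g, [dm], duration=300.0, frame_ms=1.0)
    am = activation_times(rec, (0.0, 300.0))
    interior = ra.copy()
    interior[:2] = interior[-2:] = False
    cv = conduction_velocity(am, interior, g.dx)
    assert cv == pytest.approx(c, rel=0.02)


def test_leading_pacemaker_and_tiebreak(desk_geometry):
    g = desk_geometry
    dm, seed = seeded_beat(g, 100.0, include_ra=False)
    rec = make_recording(g, [dm], duration=600.0)
    am = activation_times(rec, (0.0, 600.0))
    lead, comp = leading_pacemaker(am, g)
    assert comp == "SAN_CENTER"
    assert np.hypot(lead[0] - seed[0], lead[1] - seed[1]) <= 2.0

    # explicit tie: two nodes at the same minimal time, tie broken toward
    # the centroid of the early isochrone
    tt = np.full(g.shape, np.nan)
    pts = np.argwhere(g.mask(Region.SAN_CENTER))
    a, b = pts[10], pts[14]
    tt[a[0], a[1]] = tt[b[0], b[1]] = 5.0
    am2 = ActivationMap(times=tt, beat_index=0, threshold=-40.0, window=(0, 10))
    lead2, _ = leading_pacemaker(am2, g)
    assert lead2 in (tuple(a), tuple(b))


def test_sact_offsets(desk_geometry):
    g = desk_geometry
    for offset in (0.0, 75.0):
        dm, _ = seeded_beat(g, 100.0, sact_ms=offset, san_speed=1e9, ra_speed=1e9)
        rec = make_recording(g, [dm], duration=600.0)
        am = activation_times(rec, (0.0, 600.0))
        assert sact(am, g) == pytest.approx(offset, abs=0.5)


def test_exit_site_identifies_seeded_pathway(desk_geometry):
    g = desk_geometry
    for name in ("middle_lateral", "superior_lateral", "left_inferior"):
        dm, _ = seeded_beat(g, 100.0, exit_name=name)
        rec = make_recording(g, [dm], duration=700.0)
        am = activation_times(rec, (0.0, 700.0))
        assert exit_site(am, g) == name


def _beats(geom, n, period, **kw):
    out = []
    for k in range(n):
        dm, _ = seeded_beat(geom, 150.0 + k * period, **kw)
        out.append(dm)
    return out


def test_classifier_normal_and_shifts(desk_geometry):
    g = desk_geometry
    intrinsic = 930.0
    base_rec = make_recording(g, _beats(g, 3, 930.0), duration=3100.0)
    base = classify_outcome(base_rec, g, intrinsic)
    assert base.classification == "normal"
    assert base.scl_ms == pytest.approx(930.0, abs=5.0)
    assert base.leading_compartment == "SAN_CENTER"
    assert base.exit_sacp == "middle_lateral"

    tail_seed = tuple(np.argwhere(g.mask(Region.SAN_TAIL))[50])
    shift_rec = make_recording(
        g, _beats(g, 3, 930.0, seed_rc=tail_seed, exit_name="left_inferior"),
        duration=3100.0)
    rep = classify_outcome(shift_rec, g, intrinsic, baseline=base)
    assert rep.classification == "pacemaker_shift"
    assert rep.leading_compartment == "SAN_TAIL"

    sacp_rec = make_recording(
        g, _beats(g, 3, 930.0, exit_name="superior_lateral"), duration=3100.0)
    rep2 = classify_outcome(sacp_rec, g, intrinsic, baseline=base)
    assert rep2.classification == "sacp_shift"
    assert rep2.exit_sacp == "superior_lateral"


def test_classifier_exit_block_and_arrest(desk_geometry):
    g = desk_geometry
    block_rec = make_recording(g, _beats(g, 3, 930.0, include_ra=False),
                               duration=3100.0)
    rep = classify_outcome(block_rec, g, 930.0)
    assert rep.classification == "exit_block"
    assert rep.sact_ms is None

    silent = make_recording(g, [], duration=2200.0)
    assert classify_outcome(silent, g, 930.0).classification == "arrest"
    with pytest.raises(ValueError, match="two intrinsic"):
        classify_outcome(silent, g, 2000.0)


def test_classifier_macro_reentry_cycle_length(desk_geometry):
    """A sustained circulating wave through two non-adjacent pathways at a
    451 ms period is macro-reentry, and its cycle length is measured."""
    g = desk_geometry
    beats = _beats(g, 8, 451.0, exit_name="superior_lateral",
                   sacp_names=["superior_lateral", "inferior_lateral"])
    rec = make_recording(g, beats, duration=150.0 + 8 * 451.0 + 100.0)
    rep = classify_outcome(rec, g, 930.0)
    assert rep.classification == "macro_reentry"
    assert rep.details["reentry_cl"] == pytest.approx(451.0, abs=5.0)


def test_classifier_localized_reentry(desk_geometry):
    """Circulation confined to one adjacent pathway pair."""
    g = desk_geometry
    beats = _beats(g, 8, 400.0, exit_name="inferior_lateral",
                   sacp_names=["inferior_lateral", "left_inferior"])
    rec = make_recording(g, beats, duration=150.0 + 8 * 400.0 + 100.0)
    rep = classify_outcome(rec, g, 930.0)
    assert rep.classification == "localized_reentry"


def test_classification_exhaustive_on_random_recordings(desk_geometry, rng):
    """Any synthetic recording maps to exactly one of the seven classes."""
    g = desk_geometry
    for _ in range(12):
        n = int(rng.integers(0, 5))
        period = float(rng.uniform(300.0, 1200.0))
        include_ra = bool(rng.integers(0, 2))
        names = list(rng.choice([d.name for d in g.sacp_defs],
                                size=int(rng.integers(1, 4)), replace=False))
        pts = np.argwhere(g.mask(*SAN_COMPARTMENTS))
        seed = tuple(pts[int(rng.integers(0, len(pts)))])
        beats = _beats(g, n, period, seed_rc=seed, include_ra=include_ra,
                       exit_name=names[0], sacp_names=names)
        rec = make_recording(g, beats, duration=2100.0 + n * period)
        rep = classify_outcome(rec, g, 930.0)
        assert rep.classification in CLASSES


def test_sact_invariant_to_frame_interval(desk_geometry):
    g = desk_geometry
    vals = []
    for frame in (1.0, 2.0):
        dm, _ = seeded_beat(g, 100.0, sact_ms=75.0)
        rec = make_recording(g, [dm], duration=700.0, frame_ms=frame)
        am = activation_times(rec, (0.0, 700.0))
        vals.append(sact(am, g))
    assert abs(vals[0] - vals[1]) <= 0.5
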