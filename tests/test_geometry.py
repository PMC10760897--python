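"""Synthetic geometry builder: insulation topology, pathways, fibrosis,
diffusivity assignment and raster round-trips."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from sancomplex.geometry import (DEFAULT_SACPS, DiffusivityField, GeometryConfig,
                                 SACPSpec, add_fibrosis, block_sacps,
                                 build_diffusivity_field, build_synthetic_complex,
                                 load_geometry, remove_insulation, sacp_connectivity,
                                 save_geometry, WALL_DIFFUSIVITY_FRACTION)
from sancomplex.protocols import geometry_preset
from sancomplex.regions import Region, SAN_COMPARTMENTS


@pytest.fixture(scope="module")
def full_geom():
    return build_synthetic_complex(GeometryConfig())


def test_default_complex_structure(full_geom):
    g = full_geom
    assert len(g.sacp_defs) == 5
    sides = [d.side for d in g.sacp_defs]
    assert sides.count("head") == 3 and sides.count("tail") == 2
    # every SACP bridges band to atrium: touches a SAN label above and RA below
    for d in g.sacp_defs:
        r_top, r_bot = d.rows.max(), d.rows.min()
        cols = np.unique(d.cols)
        assert np.any(np.isin(g.labels[r_top + 1, cols],
                              [int(r) for r in SAN_COMPARTMENTS]))
        assert np.any(g.labels[r_bot - 1, cols] == int(Region.RA))
    assert sacp_connectivity(g)


def test_insulation_only_through_sacps(full_geom):
    """Blocking the pathways (or building none) fully isolates the SAN."""
    g0 = build_synthetic_complex(GeometryConfig(sacps=()))
    assert not sacp_connectivity(g0)
    gb = block_sacps(full_geom, [d.name for d in full_geom.sacp_defs])
    assert not sacp_connectivity(gb)


def test_blocking_two_head_sacps_leaves_three_bridges(full_geom):
    gb = block_sacps(full_geom, ["superior_lateral", "middle_superior"])
    assert sacp_connectivity(gb)
    open_names = {d.name for d in gb.sacp_defs
                  if np.any(gb.labels[d.rows, d.cols] == int(Region.SACP))}
    assert open_names == {"middle_lateral", "inferior_lateral", "left_inferior"}
    with pytest.raises(KeyError):
        block_sacps(full_geom, ["no_such_pathway"])


def test_fibrosis_fraction_and_determinism(full_geom):
    g0 = add_fibrosis(full_geom, 0.0, seed=7)
    assert np.array_equal(g0.labels, full_geom.labels)

    region_mask = full_geom.mask(*SAN_COMPARTMENTS, Region.SACP)
    n = int(region_mask.sum())
    g1 = add_fibrosis(full_geom, 20.0, seed=7)
    g2 = add_fibrosis(full_geom, 20.0, seed=7)
    assert np.array_equal(g1.labels, g2.labels)
    voids = int((g1.labels[region_mask] == int(Region.VOID)).sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.2)
    assert lo <= voids <= hi
    # wall and RA untouched
    assert np.array_equal(g1.mask(Region.WALL), full_geom.mask(Region.WALL))
    assert np.array_equal(g1.mask(Region.RA), full_geom.mask(Region.RA))

    g3 = add_fibrosis(full_geom, 100.0, regions=(Region.SACP,), seed=7)
    assert not np.any(g3.labels == int(Region.SACP))
    assert not sacp_connectivity(g3)
    with pytest.raises(ValueError):
        add_fibrosis(full_geom, 120.0)


def test_diffusivity_regional_ratios(full_geom):
    base = 0.05
    df = build_diffusivity_field(full_geom, base)
    pick = lambda r: df.d_long[full_geom.labels == int(r)][0]
    assert pick(Region.RA) == pytest.approx(base)
    assert pick(Region.SAN_CENTER) == pytest.approx(base * 7 / 50)
    assert pick(Region.SAN_HEAD) == pytest.approx(base * 10 / 50)
    assert pick(Region.SACP) == pytest.approx(base * 20 / 50)
    assert pick(Region.WALL) == pytest.approx(base * WALL_DIFFUSIVITY_FRACTION)
    assert np.all(df.d_long[full_geom.labels == int(Region.VOID)] == 0.0)
    assert np.allclose(df.d_trans[full_geom.conductive],
                       df.d_long[full_geom.conductive] / 10.0)

    iso = build_diffusivity_field(full_geom, base, anisotropy_ratio=1.0)
    assert np.array_equal(iso.d_long, iso.d_trans)

    with pytest.raises(ValueError):
        build_diffusivity_field(full_geom, -1.0)
    with pytest.raises(ValueError):
        build_diffusivity_field(full_geom, base, regional_ratios={Region.RA: 1.0})


def test_remove_insulation_opens_lateral_border(full_geom):
    gr = remove_insulation(full_geom)
    # direct contact between band and RA along the lateral side
    san_rows = np.where(gr.mask(*SAN_COMPARTMENTS).any(axis=1))[0]
    below = gr.labels[san_rows.min() - 1]
    assert np.any(below == int(Region.RA))
    # septal side still walled
    top = gr.labels[san_rows.max() + 1]
    assert np.all((top == int(Region.WALL)) | (top == int(Region.VOID))
                  | (top == int(Region.RA)))
    assert np.any(top == int(Region.WALL))


def test_save_load_round_trip(tmp_path, full_geom):
    p = tmp_path / "geo"
    save_geometry(full_geom, p)
    g2 = load_geometry(p)
    assert np.array_equal(g2.labels, full_geom.labels)
    assert np.allclose(g2.fiber_angle, full_geom.fiber_angle)
    assert g2.dx == full_geom.dx
    assert [d.name for d in g2.sacp_defs] == [d.name for d in full_geom.sacp_defs]

    # byte-for-byte determinism of the save
    p2 = tmp_path / "geo2"
    save_geometry(build_synthetic_complex(GeometryConfig()), p2)
    for suffix in (".labels.csv", ".fibers.csv", ".json"):
        assert p.with_suffix(suffix).read_bytes() == p2.with_suffix(suffix).read_bytes()


def test_load_rejects_undeclared_label(tmp_path, full_geom):
    import json
    p = tmp_path / "geo"
    save_geometry(full_geom, p)
    meta = json.loads(p.with_suffix(".json").read_text())
    del meta["legend"]["SACP"]
    p.with_suffix(".json").write_text(json.dumps(meta))
    with pytest.raises(ValueError, match="undeclared"):
        load_geometry(p)


@pytest.mark.parametrize("factor", [2.0, 4.0])
def test_builder_invariants_at_coarser_grids(factor):
    cfg = dataclasses.replace(geometry_preset("calibration"), dx_mm=0.04 * factor)
    g = build_synthetic_complex(cfg)
    assert len(g.sacp_defs) == 5
    assert sacp_connectivity(g)
    # wall stays >= 3 nodes thick by construction
    san_rows = np.where(g.mask(*SAN_COMPARTMENTS).any(axis=1))[0]
    r = san_rows.min()
    col = g.shape[1] // 2 - 20
    wall_below = 0
    rr = r - 1
    while rr >= 0 and g.labels[rr, col] == int(Region.WALL):
        wall_below += 1
        rr -= 1
    assert wall_below >= 3 or g.labels[r - 1, col] == int(Region.SACP)


def test_fiber_field_defaults_and_override():
    cfg = geometry_preset("desk")
    g = build_synthetic_complex(cfg)
    assert np.all(g.fiber_angle[g.mask(*SAN_COMPARTMENTS)] == 0.0)
    for d in g.sacp_defs:
        assert np.all(g.fiber_angle[d.rows, d.cols] == pytest.approx(np.pi / 2))
    cfg2 = dataclasses.replace(cfg, ra_fiber_angle=0.7)
    g2 = build_synthetic_complex(cfg2)
    assert np.all(g2.fiber_angle[g2.mask(Region.RA)] == pytest.approx(0.7))


def test_sacp_out_of_range_placement_rejected():
    bad = (SACPSpec("bad", 1.5, "tail"),)
    with pytest.raises(ValueError):
        build_synthetic_complex(dataclasses.replace(geometry_preset("desk"), sacps=bad))
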