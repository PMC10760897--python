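"""Reproducible experiment drivers for the SAN-complex studies.

Every driver is a pure function of its specification and seeds: it builds
the geometry, adjusts the regional channel table, runs the monodomain model
and classifies the outcome.  Reports carry the fully resolved configuration
for provenance.

Geometry presets
----------------
``full``         the reference complex (19.5 mm band, 40 um grid) - the
                 configuration the model is defined at; several seconds of
                 activity at this resolution is a long batch computation.
``calibration``  the same physical tissue on a 160 um grid with a trimmed
                 atrial margin; preserves SACT/SCL scales at ~4 % of the
                 node count.
``desk``         a reduced complex (8 mm band, 150 um grid) with the same
                 topology (compartments, five pathways, insulation); used
                 for the fast structural-logic studies and the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .analysis import OutcomeReport, classify_outcome
from .cells.modulation import dose_percent_to_ach
from .geometry import (DEFAULT_SACPS, GeometryConfig, SACPSpec, TissueGeometry,
                       add_fibrosis, block_sacps, build_diffusivity_field,
                       build_synthetic_complex, remove_insulation)
from .regions import (Region, RegionalScalingTable, SAN_COMPARTMENTS,
                      SAN_MODEL_REGIONS, default_scaling_table,
                      hf_remodeling_config)
from .solver import Recording, SimulationConfig, Stimulus, simulate

BASE_D_RA = 0.05  # mm^2/ms, calibrated once at baseline (see docs/methods.md)


def geometry_preset(name: str) -> GeometryConfig:
    if name == "full":
        return GeometryConfig()
    if name == "calibration":
        return GeometryConfig(domain_mm=(22.0, 8.0), dx_mm=0.16,
                              septal_margin_mm=0.64)
    if name == "desk":
        return GeometryConfig(
            domain_mm=(10.0, 5.0), dx_mm=0.15, san_length_mm=8.0,
            san_width_mm=1.2, septal_margin_mm=0.45,
            sacps=tuple(SACPSpec(s.name, s.x_fraction, s.side, 0.8, 0.45)
                        for s in DEFAULT_SACPS))
    raise KeyError(f"unknown geometry preset {name!r}")


@dataclass(frozen=True)
class PacingSpec:
    cycle_length: float = 500.0   # ms (2 Hz)
    n_stimuli: int = 8
    x_mm: float | None = None     # default: right superior RA corner
    y_mm: float | None = None
    amplitude: float = 60.0       # mV/ms, ~2x diastolic threshold
    duration: float = 2.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Complete description of one in-silico experiment."""

    name: str = "baseline"
    geometry: str = "desk"
    dose_pct: float = 0.0
    a1r: dict = field(default_factory=dict)        # compartment -> expression
    current_factors: dict = field(default_factory=dict)  # region -> {current: x}
    ra_na_factor: float = 1.0
    hf: bool = False
    hf_sacp_fibrosis: bool = True
    hf_ionic_only: bool = False
    remove_insulation: bool = False
    san_diffusivity_pct: float = 100.0
    blocked_sacps: tuple = ()
    fibrosis_pct: float = 0.0
    fibrosis_seed: int = 0
    pacing: PacingSpec | None = None
    duration: float = 3000.0
    dt: float = 0.01
    base_d_ra: float = BASE_D_RA
    record_interval: float = 2.0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["ach_nM"] = dose_percent_to_ach(self.dose_pct)
        return d


def build_protocol_inputs(spec: ProtocolSpec):
    """(geometry, scaling table, diffusivity field, RA INa factor) of a spec."""
    geom = build_synthetic_complex(geometry_preset(spec.geometry))
    table = default_scaling_table()

    for comp, expr in spec.a1r.items():
        region = Region[comp] if isinstance(comp, str) else Region(comp)
        table = table.with_scale(region, i_kach=float(expr))
    for reg, factors in spec.current_factors.items():
        region = Region[reg] if isinstance(reg, str) else Region(reg)
        sc = table[region]
        kw = {}
        for cur, fac in factors.items():
            key = {"i_na": "i_na", "i_f": "i_f", "i_k1": "i_k1",
                   "i_kach": "i_kach"}[cur]
            kw[key] = getattr(sc, key) * float(fac)
        table = table.with_scale(region, **kw)

    ra_na = spec.ra_na_factor
    if spec.hf:
        table, geom, ra_na_hf = hf_remodel(
            table, geom, with_sacp_fibrosis=spec.hf_sacp_fibrosis and not spec.hf_ionic_only,
            with_san_fibrosis=not spec.hf_ionic_only,
            seed=spec.fibrosis_seed)
        ra_na *= ra_na_hf
    if spec.fibrosis_pct > 0:
        geom = add_fibrosis(geom, spec.fibrosis_pct, seed=spec.fibrosis_seed)
    if spec.blocked_sacps:
        geom = block_sacps(geom, list(spec.blocked_sacps))
    if spec.remove_insulation:
        geom = remove_insulation(geom)

    dfield = build_diffusivity_field(geom, spec.base_d_ra)
    if spec.san_diffusivity_pct != 100.0:
        m = geom.mask(*SAN_MODEL_REGIONS)
        dfield.d_long[m] *= spec.san_diffusivity_pct / 100.0
        dfield.d_trans[m] *= spec.san_diffusivity_pct / 100.0
    return geom, table, dfield, ra_na


def run_protocol(spec: ProtocolSpec, intrinsic_scl: float = 930.0,
                 baseline: OutcomeReport | None = None,
                 return_recording: bool = False):
    """Execute one protocol and classify the outcome."""
    geom, table, dfield, ra_na = build_protocol_inputs(spec)

    stimuli = ()
    settle = 0.0
    if spec.pacing is not None:
        p = spec.pacing
        x = p.x_mm if p.x_mm is not None else 0.6
        y = p.y_mm if p.y_mm is not None else 0.6
        stimuli = (Stimulus(x_mm=x, y_mm=y, size_mm=0.4, start=100.0,
                            duration=p.duration, amplitude=p.amplitude,
                            period=p.cycle_length, count=p.n_stimuli),)
        settle = 100.0 + p.cycle_length * p.n_stimuli

    cfg = SimulationConfig(duration=spec.duration, dt=spec.dt,
                           record_interval=spec.record_interval,
                           stimuli=stimuli,
                           ach_nM=dose_percent_to_ach(spec.dose_pct),
                           base_d_ra=spec.base_d_ra)
    rec = simulate(geom, cfg, scaling_table=table, dfield=dfield,
                   ra_na_scale=ra_na)
    rep = classify_outcome(rec, geom, intrinsic_scl, baseline=baseline,
                           settle_ms=settle)
    rep.details["spec"] = spec.resolved()
    if return_recording:
        return rep, rec, geom
    return rep


def hf_remodel(table: RegionalScalingTable, geom: TissueGeometry,
               with_sacp_fibrosis: bool = True, with_san_fibrosis: bool = True,
               seed: int = 0):
    """Heart-failure remodeling: If and INa block in SAN and SACPs, a small
    atrial INa block, and random fibrosis in the SAN (and optionally SACP)
    regions.  Returns (table, geometry, RA INa factor)."""
    hf = hf_remodeling_config()
    fb = 1.0 - hf["i_f_block_san_sacp"]
    nb = 1.0 - hf["i_na_block_san_sacp"]
    for r in SAN_MODEL_REGIONS:
        sc = table[r]
        table = table.with_scale(r, i_f=sc.i_f * fb, i_na=sc.i_na * nb)
    regions = []
    if with_san_fibrosis:
        regions += list(SAN_COMPARTMENTS)
    if with_sacp_fibrosis:
        regions.append(Region.SACP)
    if regions:
        geom = add_fibrosis(geom, hf["fibrosis_fraction_pct"], regions=regions,
                            seed=seed)
    return table, geom, 1.0 - hf["i_na_block_ra"]


# ---------------------------------------------------------------------------
# studies

def adenosine_sweep(doses_pct, geometry: str = "desk", duration: float = 3000.0,
                    intrinsic_scl: float = 930.0,
                    baseline: OutcomeReport | None = None) -> list[OutcomeReport]:
    """One run per dose; all runs share drug-free initial states."""
    out = []
    base = baseline
    for d in doses_pct:
        rep = run_protocol(ProtocolSpec(name=f"ado_{d:g}pct", geometry=geometry,
                                        dose_pct=float(d), duration=duration),
                           intrinsic_scl=intrinsic_scl, baseline=base)
        if d == 0 and base is None:
            base = rep
        out.append(rep)
    return out


def a1r_heterogeneity_sweep(ratios, dose_pct: float = 20.0, vary: str = "both",
                            geometry: str = "desk", duration: float = 4000.0,
                            intrinsic_scl: float = 930.0,
                            baseline: OutcomeReport | None = None):
    """A1R-expression gradient studies at a fixed dose.

    ``vary='both'`` sets head = tail = ratio (relative to center 1.0);
    ``vary='tail'`` sweeps the tail with the head fixed at 0.1;
    ``vary='none'`` uses a homogeneous expression (ratio everywhere).
    """
    out = []
    for r in ratios:
        if vary == "both":
            a1r = {"SAN_HEAD": r, "SAN_TAIL": r, "SAN_CENTER": 1.0}
        elif vary == "tail":
            a1r = {"SAN_HEAD": 0.1, "SAN_TAIL": r, "SAN_CENTER": 1.0}
        elif vary == "none":
            a1r = {"SAN_HEAD": r, "SAN_TAIL": r, "SAN_CENTER": r, "SACP": r}
        else:
            raise ValueError("vary must be 'both', 'tail' or 'none'")
        rep = run_protocol(ProtocolSpec(name=f"a1r_{vary}_{r:g}",
                                        geometry=geometry, dose_pct=dose_pct,
                                        a1r=a1r, duration=duration),
                           intrinsic_scl=intrinsic_scl, baseline=baseline)
        out.append(rep)
    return out


def ina_if_sweep(current: str, regions, factors, geometry: str = "desk",
                 duration: float = 3000.0, intrinsic_scl: float = 930.0,
                 baseline: OutcomeReport | None = None):
    """Scale INa or If in the given regions by each factor."""
    if current not in ("i_na", "i_f"):
        raise ValueError("current must be 'i_na' or 'i_f'")
    out = []
    for f in factors:
        cf = {Region(r).name if not isinstance(r, str) else r: {current: float(f)}
              for r in regions}
        rep = run_protocol(ProtocolSpec(name=f"{current}_{f:g}",
                                        geometry=geometry, current_factors=cf,
                                        duration=duration),
                           intrinsic_scl=intrinsic_scl, baseline=baseline)
        out.append(rep)
    return out


def insulation_study(diffusivity_pcts, doses_pct, geometry: str = "desk",
                     duration: float = 3000.0, intrinsic_scl: float = 930.0,
                     baseline: OutcomeReport | None = None):
    """Runs without the lateral insulating border at reduced intranodal
    coupling, across doses.  Returns {(diff_pct, dose): report}."""
    out = {}
    for dp in diffusivity_pcts:
        for dose in doses_pct:
            rep = run_protocol(
                ProtocolSpec(name=f"noins_d{dp:g}_ado{dose:g}",
                             geometry=geometry, dose_pct=float(dose),
                             remove_insulation=True, san_diffusivity_pct=float(dp),
                             duration=duration),
                intrinsic_scl=intrinsic_scl, baseline=baseline)
            out[(dp, dose)] = rep
    return out


def ra_pacing_study(ina_block_factors, doses_pct, geometry: str = "desk",
                    pacing: PacingSpec = PacingSpec(),
                    observation_ms: float = 5000.0,
                    intrinsic_scl: float = 930.0,
                    baseline: OutcomeReport | None = None, hf: bool = False):
    """Atrial pacing followed by an observation window, over an
    (INa block x dose) grid; returns {(factor, dose): report}."""
    out = {}
    for f in ina_block_factors:
        for dose in doses_pct:
            dur = 100.0 + pacing.cycle_length * pacing.n_stimuli + observation_ms
            cf = {r.name: {"i_na": float(f)} for r in SAN_MODEL_REGIONS}
            rep = run_protocol(
                ProtocolSpec(name=f"pace_ina{f:g}_ado{dose:g}",
                             geometry=geometry, dose_pct=float(dose),
                             current_factors=cf, ra_na_factor=float(f),
                             pacing=pacing, duration=dur, hf=hf),
                intrinsic_scl=intrinsic_scl, baseline=baseline)
            out[(f, dose)] = rep
    return out
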