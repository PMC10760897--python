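"""Synthetic 2D geometry of the SAN pacemaker-conduction complex.

The builder emulates the planar ("shadow") projection of the 3D human SAN
used by the tissue model: an elongated SAN band (~19.5 mm long) subdivided
into head / center / tail compartments, wrapped in a 3-node insulating wall,
with discrete sinoatrial conduction pathways (SACPs) bridging the lateral
(crista-terminalis-facing) wall into the surrounding right atrium.  The
septal side of the band faces a non-conductive block zone.  Default spacing
is 40 um.  Random fibrosis converts conductive nodes into non-conductive
voids.

Axes: x runs along the SAN long axis (head at low x / superior, tail at high
x / inferior); y is the transverse axis with the RA below the band and the
septal block zone above.  Arrays are indexed [row=y, col=x] with row 0 at
the bottom (RA side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .regions import Region, SAN_COMPARTMENTS

WALL_THICKNESS_NODES = 3
#: regional gap-junction coupling, center : head/tail : SACP : RA
DIFFUSIVITY_RATIOS = {
    Region.SAN_CENTER: 7.0 / 50.0,
    Region.SAN_HEAD: 10.0 / 50.0,
    Region.SAN_TAIL: 10.0 / 50.0,
    Region.SACP: 20.0 / 50.0,
    Region.RA: 1.0,
}
WALL_DIFFUSIVITY_FRACTION = 1e-5  # 0.001% of the RA value


@dataclass(frozen=True)
class SACPSpec:
    """Placement of one conduction pathway along the lateral wall."""

    name: str
    x_fraction: float      # position along the SAN long axis, 0 = head end
    side: str = "head" or "tail"  # which half of the band it serves
    length_mm: float = 1.0  # bridge length from SAN edge into the RA
    width_mm: float = 0.4


#: the five pathways of the reference geometry: three serving the head half,
#: two the tail half.  Positions mimic the published complex (no coordinates
#: are printed there; fractions are this package's defaults).
DEFAULT_SACPS = (
    SACPSpec("superior_lateral", 0.08, "head"),
    SACPSpec("middle_superior", 0.25, "head"),
    SACPSpec("middle_lateral", 0.45, "head"),
    SACPSpec("inferior_lateral", 0.70, "tail"),
    SACPSpec("left_inferior", 0.90, "tail"),
)


@dataclass(frozen=True)
class GeometryConfig:
    domain_mm: tuple[float, float] = (20.0, 10.0)   # (x, y)
    dx_mm: float = 0.04
    san_length_mm: float = 19.5
    san_width_mm: float = 1.5
    septal_margin_mm: float = 1.0   # void strip above the septal wall
    compartment_fractions: tuple[float, float, float] = (0.325, 0.35, 0.325)
    sacps: tuple[SACPSpec, ...] = DEFAULT_SACPS
    ra_fiber_angle: float = 0.0
    funnel_rows: int = 0   # band rows above each SACP that take the bridge orientation
    sacp_penetration_rows: int = 0  # rows of transitional cells inside the band

    def scaled(self, factor: float) -> "GeometryConfig":
        """Same physical tissue at a coarser grid (dx multiplied)."""
        return GeometryConfig(domain_mm=self.domain_mm, dx_mm=self.dx_mm * factor,
                              san_length_mm=self.san_length_mm,
                              san_width_mm=self.san_width_mm,
                              septal_margin_mm=self.septal_margin_mm,
                              compartment_fractions=self.compartment_fractions,
                              sacps=self.sacps, ra_fiber_angle=self.ra_fiber_angle,
                              funnel_rows=self.funnel_rows,
                              sacp_penetration_rows=self.sacp_penetration_rows)


@dataclass
class SACPDef:
    id: int
    name: str
    side: str
    rows: np.ndarray
    cols: np.ndarray

    @property
    def nodes(self) -> np.ndarray:
        return np.column_stack([self.rows, self.cols])


@dataclass
class TissueGeometry:
    labels: np.ndarray           # int8 [ny, nx]
    fiber_angle: np.ndarray      # radians [ny, nx]
    dx: float                    # mm
    sacp_defs: list[SACPDef] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, *regions: Region) -> np.ndarray:
        m = np.zeros(self.labels.shape, bool)
        for r in regions:
            m |= self.labels == int(r)
        return m

    @property
    def conductive(self) -> np.ndarray:
        return self.mask(Region.RA, Region.SAN_HEAD, Region.SAN_CENTER,
                         Region.SAN_TAIL, Region.SACP)

    def sacp_by_name(self, name: str) -> SACPDef:
        for d in self.sacp_defs:
            if d.name == name:
                return d
        raise KeyError(f"no SACP named {name!r}")

    def copy(self) -> "TissueGeometry":
        return TissueGeometry(self.labels.copy(), self.fiber_angle.copy(), self.dx,
                              [SACPDef(d.id, d.name, d.side, d.rows.copy(), d.cols.copy())
                               for d in self.sacp_defs])


def build_synthetic_complex(config: GeometryConfig = GeometryConfig()) -> TissueGeometry:
    """Construct the labelled grid of the synthetic SAN-SACP-RA complex."""
    dx = config.dx_mm
    if dx <= 0:
        raise ValueError("dx must be positive")
    nx = int(round(config.domain_mm[0] / dx))
    ny = int(round(config.domain_mm[1] / dx))
    w = WALL_THICKNESS_NODES

    san_len = int(round(config.san_length_mm / dx))
    san_wid = max(2, int(round(config.san_width_mm / dx)))
    septal = int(round(config.septal_margin_mm / dx))

    # SAN band placed near the top (septal side up), centred in x
    top_row = ny - 1 - septal - w          # top row of the SAN band
    bot_row = top_row - san_wid + 1        # bottom row of the band
    col0 = (nx - san_len) // 2
    col1 = col0 + san_len - 1
    if bot_row - w < 1 or col0 - w < 0 or col1 + w >= nx:
        raise ValueError("domain too small for the requested SAN band")

    labels = np.full((ny, nx), int(Region.VOID), np.int8)
    # RA fills everything below the lateral wall, and flanks the band ends
    labels[:bot_row - w, :] = int(Region.RA)
    labels[bot_row - w:top_row + 1, :col0 - w] = int(Region.RA)
    labels[bot_row - w:top_row + 1, col1 + w + 1:] = int(Region.RA)

    # insulating wall ring around the band
    labels[bot_row - w:top_row + w + 1, col0 - w:col1 + w + 1] = int(Region.WALL)

    # compartments along the long axis
    f_head, f_center, f_tail = config.compartment_fractions
    if not np.isclose(f_head + f_center + f_tail, 1.0):
        raise ValueError("compartment fractions must sum to 1")
    n_head = int(round(f_head * san_len))
    n_center = int(round(f_center * san_len))
    band = labels[bot_row:top_row + 1, col0:col1 + 1]
    band[:, :n_head] = int(Region.SAN_HEAD)
    band[:, n_head:n_head + n_center] = int(Region.SAN_CENTER)
    band[:, n_head + n_center:] = int(Region.SAN_TAIL)

    # SACP bridges through the lateral (bottom) wall
    sacp_defs = []
    for i, spec in enumerate(sorted(config.sacps, key=lambda s: s.x_fraction)):
        if not 0.0 < spec.x_fraction < 1.0:
            raise ValueError(f"SACP {spec.name}: x_fraction must be in (0,1)")
        xc = col0 + int(round(spec.x_fraction * (san_len - 1)))
        half_w = max(1, int(round(spec.width_mm / dx / 2)))
        c_lo, c_hi = xc - half_w, xc + half_w
        n_len = max(w + 1, int(round(spec.length_mm / dx)))
        pen = min(config.sacp_penetration_rows, san_wid - 1)
        r_hi = bot_row - 1 + pen      # transitional cells reach into the band
        r_lo = bot_row - 1 - n_len + 1
        if r_lo < 1:
            raise ValueError(f"SACP {spec.name} cannot reach the RA")
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1),
                             indexing="ij")
        labels[rr, cc] = int(Region.SACP)
        sacp_defs.append(SACPDef(i, spec.name, spec.side,
                                 rr.ravel().copy(), cc.ravel().copy()))

    geom = TissueGeometry(labels=labels, fiber_angle=np.zeros((ny, nx)), dx=dx,
                          sacp_defs=sacp_defs)
    geom.fiber_angle = synthetic_fiber_field(geom, config)
    _check_insulation(geom)
    return geom


def synthetic_fiber_field(geom: TissueGeometry, config: GeometryConfig) -> np.ndarray:
    """Fiber angles: along the SAN long axis in the band, along the bridge
    direction inside SACPs, configurable in the RA.  Within the band,
    fibers funnel into each pathway: the band columns directly above a
    SACP take the bridge orientation, as transitional myofibers do at the
    SAN border."""
    ang = np.zeros(geom.shape)
    ang[geom.mask(Region.RA)] = config.ra_fiber_angle
    ang[geom.mask(*SAN_COMPARTMENTS)] = 0.0
    san = geom.mask(*SAN_COMPARTMENTS)
    band_rows = np.where(san.any(axis=1))[0]
    depth = np.zeros(geom.shape, bool)
    if band_rows.size and config.funnel_rows > 0:
        depth[band_rows[0]:band_rows[0] + config.funnel_rows, :] = True
    for d in geom.sacp_defs:
        ang[d.rows, d.cols] = np.pi / 2.0
        cols = np.unique(d.cols)
        funnel = np.zeros(geom.shape, bool)
        funnel[:, cols] = True
        ang[san & funnel & depth] = np.pi / 2.0
    return ang


def _check_insulation(geom: TissueGeometry) -> None:
    """SAN and RA must only connect through SACP nodes."""
    cond = geom.conductive & ~geom.mask(Region.SACP)
    lab, _ = ndimage.label(cond)
    san = geom.mask(*SAN_COMPARTMENTS)
    ra = geom.mask(Region.RA)
    san_comps = set(np.unique(lab[san])) - {0}
    ra_comps = set(np.unique(lab[ra])) - {0}
    if san_comps & ra_comps:
        raise ValueError("insulation violated: SAN connects to RA outside SACPs")


def sacp_connectivity(geom: TissueGeometry) -> bool:
    """True if any SAN node can reach the RA through the conductive mask."""
    lab, _ = ndimage.label(geom.conductive)
    san = geom.mask(*SAN_COMPARTMENTS)
    ra = geom.mask(Region.RA)
    return bool((set(np.unique(lab[san])) - {0}) & (set(np.unique(lab[ra])) - {0}))


def add_fibrosis(geom: TissueGeometry, fraction_pct: float,
                 regions=(Region.SAN_HEAD, Region.SAN_CENTER, Region.SAN_TAIL,
                          Region.SACP),
                 seed: int = 0) -> TissueGeometry:
    """Convert a random fraction of nodes in the given regions to voids.

    Fibrotic obstacles are independent per-node (Bernoulli) voids,
    reproducible under ``seed``; the wall and RA are untouched unless
    explicitly listed.
    """
    if not 0.0 <= fraction_pct <= 100.0:
        raise ValueError("fibrosis fraction must be in [0, 100] %")
    out = geom.copy()
    if fraction_pct == 0.0:
        return out
    rng = np.random.default_rng(seed)
    m = out.mask(*[Region(r) for r in regions])
    hit = rng.random(out.shape) < fraction_pct / 100.0
    out.labels[m & hit] = int(Region.VOID)
    return out


@dataclass
class DiffusivityField:
    d_long: np.ndarray   # mm^2/ms
    d_trans: np.ndarray  # mm^2/ms
    fiber_angle: np.ndarray


def build_diffusivity_field(geom: TissueGeometry, base_d_ra: float,
                            regional_ratios: dict | None = None,
                            anisotropy_ratio=10.0) -> DiffusivityField:
    """Per-node diffusivities from the regional coupling ratios.

    ``anisotropy_ratio`` is longitudinal:transverse (the fast axis lies
    along the fiber); a scalar applies everywhere, or a mapping
    ``{Region: ratio}`` assigns per-region values (pacemaker tissue has a
    meshier fiber arrangement, hence weaker anisotropy, than the atrial
    bundles).  The wall receives a vanishing diffusivity and voids none at
    all.
    """
    if base_d_ra <= 0:
        raise ValueError("base RA diffusivity must be positive")
    ratios = dict(DIFFUSIVITY_RATIOS if regional_ratios is None else regional_ratios)
    d_long = np.zeros(geom.shape)
    for region, ratio in ratios.items():
        d_long[geom.labels == int(region)] = ratio * base_d_ra
    d_long[geom.mask(Region.WALL)] = WALL_DIFFUSIVITY_FRACTION * base_d_ra
    known = set(int(r) for r in ratios) | {int(Region.WALL), int(Region.VOID)}
    present = set(np.unique(geom.labels).tolist())
    if present - known:
        raise ValueError(f"labels without a diffusivity ratio: {present - known}")
    if isinstance(anisotropy_ratio, dict):
        aniso = np.full(geom.shape, 10.0)
        for region, ratio in anisotropy_ratio.items():
            aniso[geom.labels == int(region)] = float(ratio)
    else:
        aniso = float(anisotropy_ratio)
    d_trans = d_long / aniso
    return DiffusivityField(d_long=d_long, d_trans=d_trans,
                            fiber_angle=geom.fiber_angle.copy())


def remove_insulation(geom: TissueGeometry) -> TissueGeometry:
    """Relabel the lateral (RA-facing) wall as RA; the septal block zone and
    the band-end walls are preserved."""
    out = geom.copy()
    san_rows = np.where(np.any(np.isin(out.labels,
                                       [int(r) for r in SAN_COMPARTMENTS]), axis=1))[0]
    bot_row = san_rows.min()
    wall = out.mask(Region.WALL)
    lateral = wall & (np.arange(out.shape[0])[:, None] < bot_row)
    out.labels[lateral] = int(Region.RA)
    return out


def block_sacps(geom: TissueGeometry, names_or_ids) -> TissueGeometry:
    """Relabel the named SACPs as insulating wall."""
    out = geom.copy()
    for ident in names_or_ids:
        d = out.sacp_by_name(ident) if isinstance(ident, str) else None
        if d is None:
            matches = [s for s in out.sacp_defs if s.id == ident]
            if not matches:
                raise KeyError(f"no SACP with id {ident}")
            d = matches[0]
        out.labels[d.rows, d.cols] = int(Region.WALL)
    return out


# ---------------------------------------------------------------------------
# persistence: CSV label raster + JSON sidecar

def save_geometry(geom: TissueGeometry, path: str | Path) -> None:
    """Write the label grid as a CSV raster with a JSON sidecar holding dx,
    the label legend, SACP definitions and the fiber-angle encoding."""
    path = Path(path)
    np.savetxt(path.with_suffix(".labels.csv"), geom.labels, fmt="%d", delimiter=",")
    np.savetxt(path.with_suffix(".fibers.csv"), geom.fiber_angle, fmt="%.6f",
               delimiter=",")
    meta = {
        "dx_mm": geom.dx,
        "legend": {r.name: int(r) for r in Region},
        "fiber_encoding": "radians, one value per node",
        "sacps": [dict(id=d.id, name=d.name, side=d.side,
                       rows=d.rows.tolist(), cols=d.cols.tolist())
                  for d in geom.sacp_defs],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_geometry(path: str | Path) -> TissueGeometry:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    labels = np.loadtxt(path.with_suffix(".labels.csv"), dtype=np.int8, delimiter=",",
                        ndmin=2)
    fibers = np.loadtxt(path.with_suffix(".fibers.csv"), delimiter=",", ndmin=2)
    if labels.shape != fibers.shape:
        raise ValueError("label and fiber rasters disagree in shape")
    legend = {v: k for k, v in meta["legend"].items()}
    for val in np.unique(labels):
        if int(val) not in legend:
            raise ValueError(f"raster contains undeclared label value {val}")
    defs = [SACPDef(d["id"], d["name"], d["side"],
                    np.asarray(d["rows"]), np.asarray(d["cols"]))
            for d in meta["sacps"]]
    return TissueGeometry(labels=labels, fiber_angle=fibers, dx=float(meta["dx_mm"]),
                          sacp_defs=defs)
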