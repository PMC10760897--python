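"""Tissue region labels and the regional channel-expression table.

The SAN pacemaker-conduction complex is compartmentalised: head, center and
tail pacemaker compartments, transitional-cell conduction pathways (SACPs),
the surrounding right atrium, the insulating border wall, and non-conductive
(void/fibrotic) nodes.  Ion-channel densities differ between compartments;
the defaults live in ``data/default_regional_scalings.json`` and are treated
as configuration, not code constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources
from pathlib import Path


class Region(IntEnum):
    VOID = 0
    RA = 1
    SAN_HEAD = 2
    SAN_CENTER = 3
    SAN_TAIL = 4
    SACP = 5
    WALL = 6


SAN_MODEL_REGIONS = (Region.SAN_HEAD, Region.SAN_CENTER, Region.SAN_TAIL, Region.SACP)
SAN_COMPARTMENTS = (Region.SAN_HEAD, Region.SAN_CENTER, Region.SAN_TAIL)
CONDUCTIVE_REGIONS = (Region.RA,) + SAN_MODEL_REGIONS


@dataclass(frozen=True)
class RegionScales:
    """Scale factors for one region's key currents (1.0 = center density)."""

    i_na: float = 1.0
    i_f: float = 1.0
    i_k1: float = 0.0
    i_kach: float = 1.0

    def __post_init__(self):
        for name in ("i_na", "i_f", "i_kach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} scale must be >= 0")
        if self.i_k1 < 0:
            raise ValueError("i_k1 scale must be >= 0")


@dataclass
class RegionalScalingTable:
    """Per-region current scalings for the whole complex."""

    scales: dict[Region, RegionScales] = field(default_factory=dict)
    version: int = 0

    def __getitem__(self, region: Region) -> RegionScales:
        return self.scales[Region(region)]

    def with_scale(self, region: Region, **kw) -> "RegionalScalingTable":
        """Return a copy with some factors of one region replaced."""
        new = dict(self.scales)
        new[Region(region)] = replace(new[Region(region)], **kw)
        return RegionalScalingTable(scales=new, version=self.version)

    def with_a1r(self, head: float = None, center: float = None,
                 tail: float = None, sacp: float = None) -> "RegionalScalingTable":
        """Copy with per-compartment A1R (IKACh) expression replaced."""
        out = self
        for region, val in ((Region.SAN_HEAD, head), (Region.SAN_CENTER, center),
                            (Region.SAN_TAIL, tail), (Region.SACP, sacp)):
            if val is not None:
                out = out.with_scale(region, i_kach=float(val))
        return out


def default_scaling_table() -> RegionalScalingTable:
    raw = json.loads(resources.files("sancomplex.data")
                     .joinpath("default_regional_scalings.json").read_text())
    scales = {Region[name]: RegionScales(**vals) for name, vals in raw["regions"].items()}
    return RegionalScalingTable(scales=scales, version=raw["version"])


def hf_remodeling_config() -> dict:
    raw = json.loads(resources.files("sancomplex.data")
                     .joinpath("default_regional_scalings.json").read_text())
    return raw["hf_remodeling"]


def load_scaling_table(path: str | Path) -> RegionalScalingTable:
    raw = json.loads(Path(path).read_text())
    scales = {Region[name]: RegionScales(**vals) for name, vals in raw["regions"].items()}
    return RegionalScalingTable(scales=scales, version=raw.get("version", 0))
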