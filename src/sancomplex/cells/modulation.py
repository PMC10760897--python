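"""Acetylcholine / adenosine dose handling.

The tissue model expresses agonist level as a percentage of the maximal
acetylcholine concentration (60 nM), the dose at which the insulated SAN
complex arrests; 100% of the dose corresponds to 60 nM and the map is
linear.  Adenosine acts through A1 receptors on the same GIRK current, so a
single concentration axis serves both agonists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

ACH_MAX_NM = 60.0  # nM at the 100% dose


def dose_percent_to_ach(dose_pct: float) -> float:
    """Map a dose in percent of maximum to an ACh concentration in nM."""
    if not 0.0 <= dose_pct <= 100.0:
        raise ValueError(f"dose must be in [0, 100] %, got {dose_pct}")
    return ACH_MAX_NM * dose_pct / 100.0


@dataclass(frozen=True)
class CellParameterSet:
    """Parameters of one cell model instance.

    ``model_kind`` selects the ionic model ('SAN' pacemaker or 'RA' atrial).
    Scale factors multiply the maximal densities of the named currents;
    ``ach_nM`` is the agonist concentration.  With all scales at 1 and
    ach_nM = 0 the parameters equal the baseline published model.
    """

    model_kind: str = "SAN"
    scale_na: float = 1.0
    scale_f: float = 1.0
    scale_k1: float = 0.0
    scale_kach: float = 1.0
    ach_nM: float = 0.0
    overrides: tuple = ()  # sorted (name, value) pairs for base-parameter overrides

    def __post_init__(self):
        if self.model_kind not in ("SAN", "RA"):
            raise ValueError("model_kind must be 'SAN' or 'RA'")
        for name in ("scale_na", "scale_f", "scale_kach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ach_nM < 0:
            raise ValueError("ach_nM must be >= 0")

    def override_dict(self) -> dict:
        return dict(self.overrides)

    def with_overrides(self, **kw) -> "CellParameterSet":
        d = dict(self.overrides)
        d.update(kw)
        return replace(self, overrides=tuple(sorted(d.items())))


def apply_ach(params: CellParameterSet, ach_nM: float) -> CellParameterSet:
    """Return parameters with the agonist concentration set.

    For SAN-model cells the concentration drives all four published agonist
    effects (IKACh activation, If activation shift, ICaL block, reduced SR
    uptake); RA cells receive only the IKACh effect.  The effects themselves
    are evaluated inside the respective cell models at run time.
    """
    if ach_nM < 0:
        raise ValueError("ach_nM must be >= 0")
    return replace(params, ach_nM=float(ach_nM))
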