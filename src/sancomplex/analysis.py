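"""Activation-map analysis and outcome classification.

Turns a tissue :class:`~sancomplex.solver.Recording` into the measurements
used to characterise SAN function: per-beat activation maps, sinus cycle
length (SCL), sinoatrial conduction time (SACT, delay from the leading
pacemaker to the earliest atrial activation), the leading-pacemaker
compartment, the preferential exit pathway, and a categorical outcome
(normal / pacemaker shift / exit-pathway shift / macro- or localized reentry
/ exit block / arrest).

Activation is defined as the first upward crossing of -40 mV (a standard
optical-mapping convention; configurable), located with sub-frame linear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TissueGeometry
from .regions import Region, SAN_COMPARTMENTS
from .solver import Recording

ACTIVATION_THRESHOLD = -40.0


@dataclass
class ActivationMap:
    """Per-node activation time (ms) for one beat; NaN = unactivated."""

    times: np.ndarray            # full-grid 2D, NaN where silent/inactive
    beat_index: int
    threshold: float
    window: tuple[float, float]  # (t0, t1) ms

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times)


@dataclass
class OutcomeReport:
    scl_ms: float | None
    sact_ms: float | None            # None = no atrial activation (exit block)
    leading_node: tuple[int, int] | None
    leading_compartment: str | None
    exit_sacp: str | None
    classification: str              # one of CLASSES
    beats: list = field(default_factory=list)
    details: dict = field(default_factory=dict)


CLASSES = ("normal", "pacemaker_shift", "sacp_shift", "macro_reentry",
           "localized_reentry", "exit_block", "arrest")


def _crossing_times(frames: np.ndarray, times: np.ndarray,
                    threshold: float) -> list[np.ndarray]:
    """Per-column upward crossing times with linear interpolation."""
    below = frames[:-1] < threshold
    above = frames[1:] >= threshold
    out = []
    for j in range(frames.shape[1]):
        k = np.where(below[:, j] & above[:, j])[0]
        if k.size == 0:
            out.append(np.empty(0))
            continue
        v0 = frames[k, j].astype(np.float64)
        v1 = frames[k + 1, j].astype(np.float64)
        frac = (threshold - v0) / (v1 - v0)
        out.append(times[k] + frac * (times[k + 1] - times[k]))
    return out


def activation_times(rec: Recording, window: tuple[float, float],
                     threshold: float = ACTIVATION_THRESHOLD,
                     beat_index: int = 0) -> ActivationMap:
    """First-activation map within a time window."""
    if np.diff(rec.times[:2])[0] > 2.0 + 1e-9:
        raise ValueError("frame interval must be <= 2 ms for activation maps")
    sel = (rec.times >= window[0]) & (rec.times <= window[1])
    fr = rec.frames[sel]
    tt = rec.times[sel]
    grid = np.full(rec.shape, np.nan)
    if fr.shape[0] >= 2:
        cross = _crossing_times(fr, tt, threshold)
        first = np.array([c[0] if c.size else np.nan for c in cross])
        grid[rec.active_rows, rec.active_cols] = first
    return ActivationMap(times=grid, beat_index=beat_index,
                         threshold=threshold, window=window)


def detect_beats(rec: Recording, geom: TissueGeometry,
                 threshold: float = ACTIVATION_THRESHOLD,
                 min_gap_ms: float = 120.0) -> list[tuple[float, float]]:
    """Beat windows from the SAN-compartment activity envelope.

    A beat spans from just before the first SAN crossing to the start of the
    next beat (or the recording end); beats are separated by quiescent gaps
    of at least ``min_gap_ms`` in the SAN envelope.
    """
    san = geom.mask(*SAN_COMPARTMENTS)
    tr = rec.node_traces(san)
    env = tr.max(axis=1)
    active = env >= threshold
    t = rec.times
    starts, ends = [], []
    in_beat = False
    last_active_t = None
    for i in range(t.size):
        if active[i] and not in_beat:
            in_beat = True
            starts.append(t[i])
        if active[i]:
            last_active_t = t[i]
        if in_beat and not active[i] and last_active_t is not None \
                and t[i] - last_active_t >= min_gap_ms:
            in_beat = False
            ends.append(t[i])
    if in_beat:
        ends.append(t[-1])
    pre = 10.0
    return [(max(s - pre, float(t[0])), e) for s, e in zip(starts, ends)]


def leading_pacemaker(amap: ActivationMap, geom: TissueGeometry):
    """Earliest-activating SAN node; ties resolved toward the centroid of
    the earliest 1-ms isochrone.  Returns ((row, col), compartment name)."""
    san = geom.mask(*SAN_COMPARTMENTS)
    tt = np.where(san, amap.times, np.nan)
    if not np.any(np.isfinite(tt)):
        return None, None
    tmin = np.nanmin(tt)
    early = np.argwhere(tt <= tmin + 1.0)
    cen = early.mean(axis=0)
    r, c = early[np.argmin(((early - cen) ** 2).sum(axis=1))]
    return (int(r), int(c)), Region(geom.labels[r, c]).name


def sact(amap: ActivationMap, geom: TissueGeometry) -> float | None:
    """Earliest RA activation minus leading-pacemaker activation, or None
    when the beat never reaches the atrium (exit block)."""
    lead, _ = leading_pacemaker(amap, geom)
    if lead is None:
        return None
    ra_times = np.where(geom.mask(Region.RA), amap.times, np.nan)
    if not np.any(np.isfinite(ra_times)):
        return None
    return float(np.nanmin(ra_times) - amap.times[lead])


def exit_site(amap: ActivationMap, geom: TissueGeometry) -> str | None:
    """SACP whose bridge is nearest the earliest-activating RA node."""
    ra_times = np.where(geom.mask(Region.RA), amap.times, np.nan)
    if not np.any(np.isfinite(ra_times)):
        return None
    r0, c0 = np.unravel_index(np.nanargmin(ra_times), ra_times.shape)
    best, best_d = None, np.inf
    for d in geom.sacp_defs:
        dist = np.min((d.rows - r0) ** 2 + (d.cols - c0) ** 2)
        if dist < best_d:
            best, best_d = d.name, dist
    return best


def _sacp_activation_series(rec: Recording, geom: TissueGeometry,
                            threshold: float) -> dict[str, np.ndarray]:
    out = {}
    for d in geom.sacp_defs:
        mask = np.zeros(rec.shape, bool)
        mask[d.rows, d.cols] = True
        tr = rec.node_traces(mask)
        if tr.shape[1] == 0:   # fully blocked/fibrotic pathway
            out[d.name] = np.empty(0)
            continue
        env = tr.max(axis=1)
        ups = np.where((env[:-1] < threshold) & (env[1:] >= threshold))[0]
        out[d.name] = rec.times[ups + 1]
    return out


def classify_outcome(rec: Recording, geom: TissueGeometry, intrinsic_scl: float,
                     baseline: OutcomeReport | None = None,
                     threshold: float = ACTIVATION_THRESHOLD,
                     settle_ms: float = 0.0) -> OutcomeReport:
    """Measure one recording and classify its outcome.

    Decision rules (applied in order, mutually exclusive):

    * ``arrest`` - no SAN activation for at least 2 x intrinsic SCL;
    * ``exit_block`` - SAN active but the atrium is never activated;
    * ``macro_reentry`` - sustained periodic activity at a cycle length
      clearly shorter than the intrinsic SCL (a self-sustained circulating
      wave outruns the pacemaker), engaging two or more conduction pathways
      in a repeating order;
    * ``localized_reentry`` - as above but confined to one adjacent pair of
      pathways;
    * ``pacemaker_shift`` / ``sacp_shift`` - leading compartment or
      preferential exit differs from the baseline report;
    * ``normal`` otherwise.

    ``settle_ms`` discards an initial transient (e.g. post-pacing) before
    the rules are applied.
    """
    t0 = float(rec.times[0]) + settle_ms
    window = (t0, float(rec.times[-1]))
    if window[1] - window[0] < 2 * intrinsic_scl:
        raise ValueError("recording shorter than two intrinsic cycles")

    sub = rec
    beats = [b for b in detect_beats(rec, geom, threshold) if b[1] > t0]
    beats = [(max(b[0], t0), b[1]) for b in beats]
    details: dict = {"n_beats": len(beats), "window": window}

    # per-beat measurements (discard the first beat if another follows)
    maps = [activation_times(sub, b, threshold, i) for i, b in enumerate(beats)]
    good = [m for m in maps if np.any(np.isfinite(
        np.where(geom.mask(*SAN_COMPARTMENTS), m.times, np.nan)))]
    if len(good) >= 3:
        good = good[1:]

    if not good:
        return OutcomeReport(None, None, None, None, None, "arrest",
                             beats=[], details=details)

    # SCL at the leading pacemaker of the last analysed beat
    lead, comp = leading_pacemaker(good[-1], geom)
    lead_tr = sub.trace_at(*lead)
    sel = sub.times >= t0
    ups = np.where((lead_tr[:-1] < threshold) & (lead_tr[1:] >= threshold)
                   & sel[1:])[0]
    scl = float(np.diff(sub.times[ups + 1]).mean()) if ups.size >= 2 else None
    last_act = sub.times[ups + 1][-1] if ups.size else t0
    if window[1] - last_act >= 2 * intrinsic_scl and ups.size <= 1:
        return OutcomeReport(None, None, None, None, None, "arrest",
                             beats=[], details=details)

    sacts = [sact(m, geom) for m in good]
    exits = [exit_site(m, geom) for m in good]
    details["sact_per_beat"] = sacts
    details["exit_per_beat"] = exits
    sact_last = sacts[-1]
    exit_last = exits[-1]

    if all(s is None for s in sacts):
        return OutcomeReport(scl, None, lead, comp, None, "exit_block",
                             beats=beats, details=details)

    # reentry: sustained activity with a cycle clearly unlike the intrinsic one
    series = _sacp_activation_series(sub, geom, threshold)
    series = {k: v[v >= t0] for k, v in series.items()}
    periodic = {}
    for name, times in series.items():
        if times.size >= 3:
            per = np.diff(times)
            if per.size and np.all(np.abs(per - per.mean()) < 0.2 * per.mean()):
                periodic[name] = per.mean()
    details["sacp_periods"] = {k: float(v) for k, v in periodic.items()}
    if len(periodic) >= 2:
        per = float(np.mean(list(periodic.values())))
        sustained = max((series[k][-1] for k in periodic), default=-np.inf) \
            >= window[1] - 1.5 * per
        if sustained and per < 0.8 * intrinsic_scl:
            names = sorted(periodic, key=lambda k: series[k][0])
            ids = sorted(geom.sacp_by_name(n).id for n in names)
            adjacent = len(ids) == 2 and ids[1] - ids[0] == 1
            cls = "localized_reentry" if adjacent else "macro_reentry"
            details["reentry_cl"] = per
            return OutcomeReport(per, sact_last, lead, comp, exit_last, cls,
                                 beats=beats, details=details)

    if baseline is not None:
        if comp != baseline.leading_compartment:
            return OutcomeReport(scl, sact_last, lead, comp, exit_last,
                                 "pacemaker_shift", beats=beats, details=details)
        if exit_last is not None and exit_last != baseline.exit_sacp:
            return OutcomeReport(scl, sact_last, lead, comp, exit_last,
                                 "sacp_shift", beats=beats, details=details)
    return OutcomeReport(scl, sact_last, lead, comp, exit_last, "normal",
                         beats=beats, details=details)


def conduction_velocity(amap: ActivationMap, mask: np.ndarray,
                        dx: float) -> float:
    """Mean propagation speed (mm/ms) from the activation-time gradient."""
    tt = np.where(mask, amap.times, np.nan)
    gy, gx = np.gradient(tt, dx)
    g = np.sqrt(gx ** 2 + gy ** 2)
    g = g[np.isfinite(g) & (g > 1e-9)]
    if g.size == 0:
        raise ValueError("no finite activation gradient in mask")
    return float(1.0 / np.median(g))


def isochrone_png(amap: ActivationMap, path, dx: float = 1.0) -> None:
    """Write an isochrone image of one activation map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(amap.times - np.nanmin(amap.times), origin="lower",
                   cmap="turbo", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    ax.set_title(f"beat {amap.beat_index}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
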