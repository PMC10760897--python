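# Methods

`sancomplex` models the human sinoatrial-node (SAN) pacemaker–conduction
complex as a 2D monodomain reaction–diffusion system: regionally
heterogeneous ionic cell models on a labelled grid, coupled by an
anisotropic diffusion operator, with an insulating border between the node
and the right atrium (RA) that is pierced only by discrete sinoatrial
conduction pathways (SACPs).  This note records the model, its parameters,
the numerical choices, and what the synthetic geometry does and does not
capture.

## Cell models

**SAN pacemaker cell.**  A Hodgkin–Huxley-type human SAN myocyte of the
modern human-SAN lineage: membrane currents If, INa, ICaL, ICaT, IKr, IKs,
Ito, IKur, IKACh, INaK, INaCa, plus a Ca²⁺ subsystem with a subsarcolemmal
space, myoplasm, junctional and network SR, RyR release gating
(activation/inactivation by subspace Ca²⁺, SR-load dependence), SERCA
uptake and troponin/calmodulin/calsequestrin buffering.  Intracellular Na⁺
(5 mM) and K⁺ (140 mM) are fixed.  Membrane capacitance is 57 pF.

The archived reference implementation of the published human SAN model was
not available offline, so the equations were implemented from the published
formulations of this lineage and the maximal conductances were then
calibrated **once** against the published human SAN action-potential
biomarkers.  The calibrated cell has, at its stable limit cycle (40 s
settling, dt = 2.5 µs):

* cycle length 813.8 ms (published ~814 ms),
* maximum diastolic potential −59.8 mV (published ~−59 mV),
* overshoot +25 mV — somewhat above the published ~+17 mV; this is the main
  residual waveform deviation and is documented rather than chased, because
  every tissue-level quantity this package validates depends on cycle
  lengths, dose responses and source–sink balance, not on the overshoot.

Convergence: halving dt from 2.5 µs to 1.25 µs changes the limit-cycle CL
by < 0.01 ms.

**Atrial myocyte.**  The standard human atrial (Courtemanche-type) model
with its published parameters and resting state; resting potential
−81.2 mV, APD90 ≈ 308 ms, amplitude ≈ 104 mV.  An
acetylcholine/adenosine-activated K⁺ current with algebraic dose activation
(EC50 = 30 nM, Hill 2.1) is added; it shortens APD90 monotonically with
dose (308 → 40 ms over 0–60 nM).

**Transitional (SACP) cells** are SAN-model cells with the SACP row of the
regional table (below); an inward-rectifier IK1 of the atrial form, scaled
by the table, makes them quiescent (rest ≈ −78 mV) yet excitable.

## Agonist convention

Adenosine and acetylcholine act through the same A1R/M2–GIRK axis, so a
single concentration axis is used.  The maximal dose is defined as the
concentration at which the insulated complex arrests — 60 nM — and doses
are expressed as percentages of it (linear map, 0.6 nM per %).  Four
effects are applied to SAN-model cells: IKACh activation (gated, opening
rate saturating with ~325 nM EC50), a negative shift of the If activation
curve (up to ~−11 mV), fractional ICaL block (up to 31%) and reduced SR
uptake (up to 70%).  RA cells receive only their IKACh.  The maximal IKACh
conductance was calibrated so the isolated center cell still fires at 48 nM
and stops at 60 nM, implementing the stated convention exactly; regional A1
receptor expression scales this conductance per node.

## Regional table

Channel-density scale factors relative to the center compartment
(`data/default_regional_scalings.json`; treated as configuration).  The
ratios are this package's own calibration to the stated constraints —
center slower than periphery (813 vs 798 ms) with *lower* INa and *higher*
If centrally, non-automatic transitional cells, A1R higher centrally
(10:1):

| region    | INa | If  | IK1 | A1R/IKACh |
|-----------|-----|-----|-----|-----------|
| center    | 1   | 1.0 | 0   | 1.0       |
| head/tail | 10  | 0.8 | 0   | 0.1       |
| SACP      | 40  | 0.2 | 0.3 | 0.1       |

Heart-failure remodeling applies 20% If and INa block in SAN and SACPs, 5%
INa block in the RA, and 20% random fibrosis in the SAN (optionally also
SACP) regions.

## Geometry

The synthetic builder emulates the planar projection of the histological
complex: a 19.5 × 1.5 mm SAN band (head/center/tail at fractions
0.325/0.35/0.325 of the long axis), a closed 3-node insulating wall, five
SACP bridges through the lateral wall (three serving the head half at
long-axis fractions 0.08/0.25/0.45, two the tail half at 0.70/0.90; bridge
length 1 mm, width 0.4 mm — positions are configuration, the published
source names the pathways but prints no coordinates), an RA sheet below and
flanking the band, and a septal void above (block zone).  Default spacing
40 µm.  Fibers run along the band axis, along each bridge, and
configurably in the RA.  Fibrosis is realized as independent per-node
voids under a seeded generator.

Presets: `full` (40 µm — the definition scale), `calibration` (the same
19.5 mm complex at 160 µm with a trimmed atrial margin, ~5500 nodes) and
`desk` (an 8 mm band at 150 µm, ~1700 nodes, same topology) for the fast
structural studies and the test suite.

## Tissue equation and numerics

dV/dt = ∇·(D∇V) − I_ion/Cm + I_stim with the per-node tensor
D(θ) = R diag(D_long, D_trans) Rᵀ.  Regional coupling follows the ratio
center : head/tail : SACP : RA = 7 : 10 : 20 : 50; anisotropy is 1:10
(transverse:longitudinal, fast axis along the fiber).  The wall carries
10⁻⁵ of the RA diffusivity *and* is re-clamped to −62.5 mV (the mean of
the SAN and RA resting potentials) every step — both published half-measures
applied together.

Space: face-flux finite differences with harmonic-mean interface
diffusivities (standard for discontinuous coefficients) and centred
cross-derivative terms when the tensor is not axis-aligned; the assembled
operator has exactly zero row sums, so uniform potentials are machine-
precision fixed points, and fluxes vanish into voids and across the domain
boundary.  Time: forward Euler for both the PDE and the ODEs (the method
the tissue model is defined with); a startup guard enforces
dt ≤ dx²/(4 Dmax).  Voltage-dependent gate kinetics are evaluated from
lookup tables on a 0.02 mV grid (linear interpolation); the identical
kernels serve single-cell and tissue runs, compiled with strict IEEE
semantics, so an uncoupled tissue node and an isolated cell follow
bit-identical trajectories and reruns are bit-reproducible.

Default steps: 2.5 µs for isolated cells (halving changes CL by < 1 ms);
10 µs for tissue runs at the 150–160 µm presets (halving changes tissue
SCL by well under 1 ms; the ionic kernels destabilise above ~12.5 µs, which
the solver reports as an instability abort).  Tissue runs start each
region's cells from that region's cached isolated limit-cycle (or resting)
state, optionally phase-advanced to ~150 ms before the next upstroke to
shorten the lead-in; the dose acts from t = 0, as in acute administration.

## Calibration of the base diffusivity

The absolute RA diffusivity is never printed by the source and was
calibrated once at baseline: base D_RA = 0.05 mm²/ms.  At this value the
insulated complex conducts through its pathways with full atrial capture
(at 0.1 mm²/ms the atrial sink overwhelms the node — exit block), the
planar RA conduction velocity is ~0.4 mm/ms along fiber, and the tissue
slows from the isolated 814 ms to SCL ≈ 860–960 ms, matching the reported
~930 ms loaded rhythm.  CV scales as √D and is grid-converged (< 3% change
from 40 to 20 µm).

## Measurements and outcome taxonomy

Activation is the first upward crossing of −40 mV (configurable; sub-frame
linear interpolation; frame interval ≤ 2 ms).  Per beat: activation map,
leading pacemaker (earliest SAN node, ties to the isochrone centroid),
SACT (earliest RA activation minus leading-pacemaker time), preferential
exit (pathway nearest the earliest RA node).  SCL is measured at the
leading pacemaker.  Outcomes are classified by ordered, mutually exclusive
rules: arrest (no SAN activation for ≥ 2 intrinsic cycles), exit block
(SAN active, atrium silent), macro-reentry (sustained periodic activity
clearly faster than the intrinsic rhythm engaging ≥ 2 pathways; adjacent
pairs only → localized reentry), pacemaker/exit shifts relative to a
baseline report, else normal.  Reentry detection uses ordered repeated
crossings at the pathway bridges rather than phase-singularity tracking —
simpler and directly testable on constructed recordings.

## What the model reproduces, and known limitations

Reproduced at the reduced scales (all computed by the test suite and the
acceptance script): regional single-cell cycle lengths (813.8/796.1 ms) and
their inversion by tissue loading (center leads); graded dose slowing with
tissue arrest at the maximal dose; the center→tail pacemaker shift under
dose with the default A1R gradient; no shift with homogeneous A1R; the
head-ward shift when A1R is higher in the tail (0.9:0.1) with the rhythm
slowing into the reported range; the head-ward shift after blocking two
head-side pathways (source–sink unloading); If reduction slowing the rhythm
without moving the exit; ionic-only heart-failure remodeling slowing the
rhythm and arresting at high dose.

Known limitations (measured, not hidden):

* **SACT runs long (~165–200 ms vs the reported ~75 ms).**  Dissection of
  the activation maps shows the excess is transverse conduction across the
  band against the 1:10 anisotropy (~86 ms over 1.4 mm) plus a ~36 ms
  source–sink delay at the pathway entrance; the bridges themselves conduct
  in ~11 ms.  The histology-derived fiber field of the original complex
  evidently provides transverse pathways that straight synthetic fibers do
  not; every synthetic remedy tried (fiber funnelling into the pathways,
  transitional-cell penetration, weaker intranodal anisotropy) tipped the
  model into baseline macro-reentry or arrest instead.
* The same bottleneck damps the electrotonic load when the lateral
  insulation is removed, so the uninsulated model is less dose-fragile than
  reported (it shifts rather than arrests at a 10% dose).
* At the desk scale the preferential exit is robustly the tail-end pathway
  and is insensitive to ±15% pathway INa (the reported exit *re-routing*
  needs the competing pathways closer to failure than this geometry puts
  them), and 20% pathway fibrosis slows (SACT +40%) but does not block the
  bridges at 0% dose.
* The desk-scale node, being smaller, is more dose-fragile than the
  full-size complex: tissue arrest occurs between the 50% and 84% doses
  rather than exactly at 100%.
* Passing tests on the synthetic geometry show the mechanisms operate —
  they do not certify quantitative fidelity to any specific heart.

## Problem sizes used by the test suite and acceptance script

Single-cell checks run at full fidelity (dt 2.5 µs, 50–60 s settling).
Tissue checks run on the `desk` preset (~1700 conductive nodes, dt 10 µs,
2.2–3.2 s windows, phase-primed starts); the acceptance script additionally
runs the `calibration` preset (the full 19.5 mm complex at 160 µm,
~5500 nodes) for the baseline SCL/SACT measurements.  These sizes are the
package's reduced study conditions; the geometry and solver accept the full
40 µm configuration unchanged.
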