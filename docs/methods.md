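# Methods

This note documents the models implemented in `microtem`, the defaults that
matter, the design choices made where the published workflow leaves the
algorithmic details open, and what the synthetic generators do and do not
emulate.

## Coordinate conventions and calibration

Pixel coordinates are 0-based with origin at the top-left of the
section-global canvas, x rightward, y downward; z is the 0-based section
index.  Physical coordinates are micrometres.  The default calibration is
4 nm/px laterally and 60 nm section thickness; the physical z of section
*i* is `i × thickness` (section centers are not offset by half a thickness —
the simplest consistent convention, and immaterial for all statistics
computed here).

## Tile montaging

Each tile carries a 2D rigid transform (angle θ, translation t).  The
objective is the weighted mean squared distance between mapped
correspondence points, over all tile pairs within a section and between
adjacent sections.  The optimizer combines two monotone phases:

1. **Guarded Gauss–Newton.**  The residual is linearised in all (θ_i, t_i)
   with the anchor tile fixed, and the global step is backtracked (halved up
   to 12 times) until the residual does not increase.  On well-conditioned
   grids this converges to machine precision in one or two steps.
2. **Procrustes sweeps.**  Each non-anchor tile is re-fit in closed form
   (weighted 2D Procrustes) against the current positions of its
   correspondence partners.  Each per-tile update minimises exactly the
   terms of the global objective that involve that tile, so the residual is
   non-increasing after every update — the recorded residual history is
   monotone by construction, and the test suite asserts it on every run.

Stopping: relative residual change below 1e-9, absolute residual below
1e-18 px², or 10,000 sweeps.  Gauge fixing is by anchoring one tile at its
initial transform; solutions obtained with different anchors agree up to a
single global rigid transform.

A tile whose correspondences have degenerate scatter (a single point) gets
a translation-only update; its rotation is left at the current value.

## Lens-deformation correction

The correction `C` maps observed (distorted) tile-local coordinates to
ideal coordinates.  It is a polynomial with only non-linear terms (total
degree 2 up to the configured degree, default 2) in coordinates relative to
the image center, which makes it identity at the center and leaves the
linear gauge to the per-placement rigid transforms.  Estimation alternates:

* given `C`, estimate one rigid transform per placement by solving the
  montage problem on the corrected correspondences;
* given the rigids, fit the shared polynomial coefficients by linear least
  squares (the residual is linear in the coefficients).

A rank check on the design matrix rejects degenerate inputs (too few or
collinear correspondences) with an explicit error.  On planted quadratic
distortions the alternation converges geometrically; with the default 100
outer iterations the recovered coefficients agree with the planted ones to
≪1 % and the corrected montage residual falls below a millipixel RMS
(reduction of several orders of magnitude).

## Moving Least Squares warps

For a query point v the warp solves a weighted best-fit transform with
weights `w_i = 1/|p_i − v|^(2α)` (α default 1).  The **affine** local model
uses the standard weighted normal equations; the **rigid** local model
(default for section warps, since preserving tile dimensions is the point
of as-rigid-as-possible registration) uses the weighted 2D Procrustes
rotation.  A query coinciding with a control point returns that control's
target directly; elsewhere the weights are finite and the warp is
continuous.  Both models interpolate the control points exactly and
reproduce any global transform of their model class; both properties are
asserted at 1e-9.  The published workflow does not state whether the
per-section local model is rigid or affine; both are provided, rigid being
the documented default assumption.

The 3D cross-modal transform uses the same MLS machinery with local 3D
affine models; it requires at least four non-coplanar fiducials.  The warp
has no closed-form inverse; where the inverse direction is needed
(rendering, reslicing) the approximation obtained by swapping control and
target points is used, which is exact for globally affine/rigid
configurations and accurate for the smooth, small deformations this
pipeline produces.

## Reslicing and overlap scoring

Reslicing samples the confocal volume by trilinear interpolation on
`n_subplanes = 5` planes spaced uniformly across the slab and averages
them.  The slab default is 50 nm, configurable; note that the physical TEM
sections are 60 nm — the source workflow itself uses both figures, and the
package asserts neither as correct.  Pixels whose every sub-plane sample
falls outside the volume are zero and flagged invalid; an entirely
out-of-volume slab raises a warning.

Overlap between two profiles on a common grid is reported three ways:
fraction of A inside B, fraction of B inside A, and Dice.  The directional
fraction of the confocal profile covered by the TEM profile is the number
quoted as "% overlap" in reports, because that is the direction a
registration-accuracy claim concerns; all three are always computed.

## Neurite classification

Diameter at a centerline point is twice the stored radius.  The class
bands, in µm of diameter: axiform 0.2–0.4; varicose thick (varicosity)
0.5–1.5, thin 0.15–0.4; globular >1.5; dendritiform <0.2.  The qualitative
criteria are operationalised as:

* **swelling** — a run of ≥2 consecutive points at or above the thick band
  (persistence guards against single-point radius noise);
* **even diameter** — coefficient of variation < 0.25;
* **straight** — tortuosity (path length / endpoint distance) < 1.2;
* **highly branched** — at most 5 µm of cable per branch point.

Decision order: globular → varicose → dendritiform → axiform →
unclassified, so the most specific criterion wins (a profile with a >1.5 µm
swelling is globular even though it also alternates bands).  All thresholds
live in `ClassRules` and are configurable.  The classifier is checked
against an independently written rule-by-rule oracle on 1,000 random
diameter profiles (exact agreement).

## Microvolume summaries

Only elements with in-volume length ≥ 1 µm are counted (the element-count
convention for dense reconstructions).  Axonal cable aggregates
axiform + varicose + globular; dendritic cable is dendritiform.  The mean
axonal/dendritic diameter is the equal-length equal-volume smooth-cylinder
diameter `d = 2√(V/πL)`, with V the sum of conical frustum volumes between
consecutive centerline points.  Densities are counts over the stated
volume; branch intervals are cable per branch point with an explicit
"no branches" sentinel (`None`) rather than an infinity.  A validation pass
checks the synapse-placement rule (presynaptic sites on thick swellings of
varicose/globular neurites) and reports violations without failing, since
real data contain rare exceptions.  Segments crossing the box can be cut at
the faces with `clip_to_box` (linear interpolation of position and radius).

## Synapse graph and motifs

The graph is a directed multigraph with one edge per (synapse,
postsynaptic-site) contact, so the edge count equals the total number of
postsynaptic contacts by construction.  Feed-forward detection enumerates
ordered triples (B, A, C) with edges B→A, B→C, A→C on the simple projection
of the graph (parallel contacts count once for motif membership).  The
dense-overlapping-regulon rule operationalises the qualitative definition:
an axon with ≥2 targets is emitted when at least half of its targets
receive input from ≥2 distinct axons; both thresholds are parameters.  Both
detectors are verified against brute-force enumeration on 100 random
graphs of up to 30 nodes.

Envelopes are axis-aligned bounding boxes inflated by the per-point radii
(a convex-hull variant was considered and rejected: boxes are what the
envelope framing draws, and they make the overlap fraction analytic).  The
overlap table strata are <10 %, 10–50 %, and >50 % of the axon envelope
volume; the pair universe is presynaptic-capable × dendritiform, and the
per-bin frequency counts pairs (not dendrites per axon — the published
counting is ambiguous; pair counting is the documented choice).

## Extrapolation and rounding

Hemisphere totals are density × volume (defaults 20,000 µm³ and 1,500
neurons per hemisphere); per-neuron averages are totals / neurons.
Reporting rounds per-neuron counts half-up to integers, per-neuron lengths
to one significant figure, and densities to one decimal — the conventions
under which 26.67 → 27 presynapses, 10.67 → 11 branches and 38.67 → 40 µm.
Unit-cube conversion scales a cable length by the cubed side ratio;
`cube_side_from_volume` handles non-cubic reference volumes.  The dendritic
cable extrapolation can be computed with the same functions but no
reference value is asserted for it: the available dendritic inputs
(420 µm per 85 µm³) scale to ≈4.9 mm per 10 µm cube, and published figures
for this quantity are internally inconsistent.

## Synthetic generators

**Mosaics.**  One band-limited noise world texture (Gaussian-filtered white
noise, σ = 2 px) is sampled through planted per-tile transforms: nominal
grid offsets (tile 128 px, 25 % overlap) plus uniform jitter (≤3 px) and
rotation (≤2°); the anchor tile is planted at identity so solver output is
directly comparable.  Correspondences are laid on a regular grid in the
overlap regions and are exact under the ground truth; optional Gaussian
noise (one draw per correspondence) models localisation error, making the
expected converged residual ≈2σ² per correspondence.  When a lens
distortion is planted, observed coordinates are the numerical inverse of
the planted correction, so the estimator's target is the planted
coefficient vector itself.  The lens-calibration set uses 9 heavily
overlapping placements of one scene with rotations ≤5° and shifts ≤10 px.

**Microvolumes.**  Segments are anisotropic random walks (step 0.25 µm).
Axonal classes (axiform, varicose, globular) are oriented within 20° of the
longitudinal z axis and *truncate* at the box faces — long axons pass
through a microvolume, so their in-volume fragment ends at a face.
Dendritiform walks have strong per-step direction jitter and reflect at the
walls, giving the tortuous, space-filling course of terminal dendrites.
Diameter profiles are drawn inside the class bands (axiform 0.25–0.35 µm
even caliber; varicose alternating thin runs 0.25–0.35 µm and thick runs
0.7–1.2 µm; globular swellings 1.6–2.0 µm; dendritiform 0.12–0.18 µm), and
every generated segment is re-checked with the classifier so planted class
counts are exact by construction.  Branch points are planted at one per
7.5 µm of axonal cable (Poisson) and one per 4.1 µm of dendritic cable.
Presynaptic sites sit only on swelling points of varicose/globular hosts;
postsynaptic contacts land only on dendritiform segments; fan-out is
uniform on {3, 4, 5} and can be constrained to an exact contact total.

The VNC-like fixture is an 85 µm³ box (5 × 5 × 3.4 µm) with exactly
39 varicose, 1 globular, 25 axiform and 105 dendritiform elements, 68
presynaptic sites distributed over the globular neurite and 24 varicose
hosts, and 256 postsynaptic contacts (ratio 256/68 ≈ 3.8).

**What the generators do not emulate:** photorealistic EM texture, section
loss and folds, the transient aggregation of dendritiform processes into
short-lived bundles (approximated only qualitatively), synaptic
conglomerates (confluent presynaptic sites), and the rare placement
exceptions (occasional postsynaptic sites on varicose side branches, single
presynaptic sites on axiform processes).  Tests passing on generated data
therefore validate the measurement and detection machinery, not the
biological realism of any particular density value.

## Problem sizes and numerical choices

The default validation runs use 3×3 single-section mosaics and a 5×5×3
synthetic stack (75 tiles, ~9,000 correspondences), a 9-placement lens set
with ~2,500 correspondences, the 85 µm³ VNC fixture, and one 1,000 µm³
microvolume for parameter-recovery checks — sizes chosen so the full suite
exercises every solver at meaningful scale while remaining quick to run.
Key tolerances: montage stop at relative 1e-9 / absolute 1e-18 px²;
MLS interpolation asserted at 1e-9; lens coefficients recovered within 1 %;
classification oracle agreement exact; generator parameter recovery within
10 % at 1,000 µm³.  Ties and degenerate inputs: coincident MLS queries
return the control target; zero-volume envelopes yield missing (NaN)
overlap; empty synapse sets yield NaN means; unbranched cable yields a
`None` branch interval.

## Known limitations

* The montage model is rigid-per-tile + per-section MLS; elastic
  (spring-mesh) registration is out of scope.
* MLS inverses are approximate (control/target swap); exact for global
  affine configurations only.
* Rendering is in-memory; no tile streaming or out-of-core composition.
* SWC files carry one centerline per file; full branching trees read from
  external SWC are linearised in file order, which is adequate for
  microvolume fragments but not for whole-arbor morphometry.
* Cross-modal registration quality is entirely determined by the
  user-picked fiducials; no automatic cross-modal feature detection is
  attempted.
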