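# microtem

Computational toolkit for serial-section transmission electron microscopy
(ssTEM) reconstruction of insect neuropile, and for the dense "microvolume"
analytics that such reconstructions enable: neurite classification,
morphometrics, polyadic synapse networks, and brain-wide extrapolation.

The package targets the reconstruction workflow used for small brains such
as the *Drosophila* first-instar larval brain: hundreds of 60 nm serial
sections imaged at ~4 nm/px as grids of overlapping camera tiles, montaged
and registered into a navigable volume; small sub-volumes (2×2×1.5 µm up to
5×5×5 µm) densely segmented so that every neurite fragment and synapse is
annotated; and the resulting per-µm³ statistics scaled up to the whole
hemisphere.

## What is implemented

**Registration** (`microtem.registration`)

* Polynomial lens-deformation correction estimated from heavily overlapping
  tile placements: the shared correction `C` and one rigid transform per
  placement are alternated until corrected correspondences are mutually
  consistent; `C` is identity-constrained at the image center.
* As-rigid-as-possible tile montaging: each tile gets a 2D rigid transform
  `T_i(x) = R(θ_i) x + t_i`, estimated simultaneously from all tile-to-tile
  SIFT (or planted) correspondences, within a section and with the
  neighboring sections.  An iterative optimizer relaxes the configuration
  until the mean squared correspondence distance
  `E = Σ_k w_k ‖T_a(p_k) − T_b(q_k)‖² / Σ_k w_k` is minimal; the residual is
  non-increasing at every iteration and one anchor tile fixes the gauge.
* Per-section non-linear warps by Moving Least Squares (MLS) with tile
  centers as control points: every query point `v` receives its own
  weighted best-fit rigid (or affine) transform with weights
  `w_i = 1/‖p_i − v‖^{2α}`, so the warp interpolates the control points
  exactly and reproduces any global transform of its model class.
* Mipmap pyramids (2×2 mean downsampling to 1×1) and section rendering with
  feathered-mean or last-writer compositing.

**Cross-modal registration** (`microtem.crossmodal`) — MLS over local 3D
affine models fit to user-picked fiducial pairs (e.g. axon-fascicle
intersections) registers a confocal stack onto the TEM stack; the confocal
volume is resliced as a thin slab (50 nm default) at any TEM section plane,
and profile agreement is scored by directional overlap fractions and Dice.

**Morphometry** (`microtem.morphometry`) — classifies neurite fragments
into the four generic classes seen in dense reconstructions (axiform,
varicose, globular, dendritiform) from diameter profiles, branch counts and
tortuosity, and computes microvolume summaries: cable length, the
equal-volume smooth-cylinder diameter `d = 2√(V/πL)`, branch intervals, and
presynapse densities.

**Connectivity** (`microtem.connectivity`) — builds the directed polyadic
synapse multigraph (one edge per postsynaptic contact), detects
feed-forward triads (B→A, B→C, A→C) and dense overlapping regulons, and
tabulates synaptic-contact frequency against axon/dendrite envelope
overlap.

**Extrapolation** (`microtem.extrapolation`) — scales per-µm³ densities to
hemisphere totals and per-neuron averages, and converts cable densities
between reference cubes for cross-species comparison.

**Synthetic data** (`microtem.synthetic_data`) — generates tile mosaics
with planted rigid transforms and lens distortion (plus exact
correspondences) and neurite microvolumes obeying the structural rules of
insect neuropile, including a deterministic VNC-like fixture (85 µm³, 170
elements, 68 presynaptic sites, 256 postsynaptic contacts).

## Worked example

```python
import numpy as np
from microtem import morphometry as mm
from microtem import connectivity as cn
from microtem import extrapolation as ex
from microtem import synthetic_data as syn

vnc = syn.vnc_fixture()
s = mm.summarize_microvolume(vnc.segments, vnc.synapses, vnc.spec.volume_um3)
print(s.class_counts)
print(round(s.presynapse_density_per_um3, 1), "presynaptic sites per µm³")
print(cn.polyadic_stats(vnc.synapses)["post_to_pre_ratio"])

est = ex.estimate_brain(ex.DensityTriple(2.0, 0.8, 2.9))
print(est.total_presynapses, est.presynapses_per_neuron_rounded)
```

prints

```
{'axiform': 25, 'varicose': 39, 'globular': 1, 'dendritiform': 105, 'unclassified': 0}
0.8 presynaptic sites per µm³
3.764705882352941
40000.0 27
```

The first two lines are the composition of the 85 µm³ ventral-nerve-cord
microvolume (170 neurite elements over 1 µm length; 68 presynaptic sites →
0.8/µm³).  The post:pre contact ratio of ≈3.8 rounds to four postsynaptic
sites per presynaptic site, the signature of polyadic synapses.  The last
line extrapolates the averaged densities (2 presynapses, 0.8 branch points,
2.9 µm cable per µm³) over a 20,000 µm³ hemisphere: 40,000 presynaptic
sites in total and 27 per neuron for 1,500 neurons.

A command-line interface mirrors the library:

```
microtem simulate volume --out-dir vol
microtem analyze --swc-dir vol/swc --synapses vol/synapses.csv --volume 125 --out summary.json
microtem montage --manifest M.csv --anchor s0_r0c0 --out sol.json
microtem extrapolate --out estimate.json
```

## Layout

```
src/microtem/
  core_model.py      imaging geometry, calibration, segmentation data model
  registration.py    lens model, montage solver, MLS warps, mipmaps, rendering
  crossmodal.py      fiducial MLS 3D-affine, reslicing, overlap scoring
  morphometry.py     neurite classification and microvolume statistics
  connectivity.py    synapse graph, motifs, envelope-overlap analysis
  extrapolation.py   hemisphere totals, per-neuron averages, unit cubes
  synthetic_data.py  mosaic and microvolume generators with ground truth
  io.py, cli.py      SWC/CSV/JSON readers-writers and the CLI
```

See `docs/methods.md` for the models, parameter defaults, and the
assumptions behind the synthetic generators.
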