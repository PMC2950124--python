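"""Ground-truth generators: tile mosaics and neurite microvolumes.

Two families of synthetic inputs close the loop on the analysis modules:

* **Mosaics** — grids of overlapping grayscale tiles cut from one filtered-
  noise "world" texture under planted per-tile rigid transforms and an
  optional planted polynomial lens distortion, together with exact point
  correspondences.  The montage solver and lens estimator can be validated
  against the planted ground truth.
* **Microvolumes** — boxes densely filled with neurite segments drawn as
  anisotropic random walks obeying the structural rules of insect neuropile:
  class-specific diameter bands, branch rates, axonal orientation bias along
  the longitudinal axis, presynaptic sites restricted to the swellings of
  varicose/globular neurites, postsynaptic contacts restricted to
  dendritiform neurites, and polyadic fan-out between three and five.

All randomness is driven by a single integer seed; identical spec + seed
produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .morphometry import ClassRules, NeuriteSegment, SynapseAnnotation, polyline_length
from .registration import Correspondence, PolynomialDistortion2D, RigidTransform2D

__all__ = [
    "MosaicSpec",
    "MosaicResult",
    "generate_texture",
    "generate_mosaic",
    "generate_lens_calibration_set",
    "MicrovolumeSpec",
    "MicrovolumeResult",
    "generate_microvolume",
    "vnc_fixture",
]


# ---------------------------------------------------------------------------
# Mosaics


@dataclass
class MosaicSpec:
    """Layout and randomness of a synthetic tile mosaic."""

    rows: int = 3
    cols: int = 3
    n_sections: int = 1
    tile_size: int = 128
    overlap: float = 0.25
    max_rotation_deg: float = 2.0
    max_jitter_px: float = 3.0
    noise_sigma: float = 0.0  # correspondence noise, px
    texture_sigma: float = 2.0
    distortion: Optional[PolynomialDistortion2D] = None
    corr_grid_step: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap < 0.9):
            raise ValueError("overlap must be in (0, 0.9)")
        if min(self.rows, self.cols, self.n_sections, self.tile_size) < 1:
            raise ValueError("grid dimensions and tile size must be positive")

    @property
    def step(self) -> float:
        return self.tile_size * (1.0 - self.overlap)


@dataclass
class MosaicResult:
    spec: MosaicSpec
    tiles: Dict[str, np.ndarray]
    true_transforms: Dict[str, RigidTransform2D]
    nominal_offsets: Dict[str, Tuple[float, float]]
    correspondences: List[Correspondence]
    anchor_tile: str = ""


def generate_texture(shape: Tuple[int, int], sigma: float = 2.0, seed: int = 0) -> np.ndarray:
    """Band-limited noise texture in [0, 255] (rich in matchable features)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), sigma)
    img -= img.min()
    if img.max() > 0:
        img *= 255.0 / img.max()
    return img


def _tile_id(section: int, row: int, col: int) -> str:
    return f"s{section}_r{row}c{col}"


def generate_mosaic(spec: MosaicSpec) -> MosaicResult:
    """Tiles + planted transforms + exact correspondence sets.

    The anchor tile (section 0, row 0, col 0) is planted at identity so
    solver output can be compared to ground truth without gauge alignment.
    Correspondences are exact under the planted transforms before the
    optional Gaussian noise ``noise_sigma`` is added.
    """
    from scipy.ndimage import map_coordinates

    rng = np.random.default_rng(spec.seed)
    size = spec.tile_size
    step = spec.step
    margin = int(size)  # slack for jitter and rotation
    world_h = int(np.ceil((spec.rows - 1) * step + size)) + 2 * margin
    world_w = int(np.ceil((spec.cols - 1) * step + size)) + 2 * margin
    world = generate_texture((world_h, world_w), spec.texture_sigma, spec.seed + 1)

    tiles: Dict[str, np.ndarray] = {}
    truth: Dict[str, RigidTransform2D] = {}
    nominal: Dict[str, Tuple[float, float]] = {}
    anchor = _tile_id(0, 0, 0)
    max_rot = np.deg2rad(spec.max_rotation_deg)

    for s in range(spec.n_sections):
        for r in range(spec.rows):
            for c in range(spec.cols):
                tid = _tile_id(s, r, c)
                nom = (margin + c * step, margin + r * step)
                nominal[tid] = nom
                if tid == anchor:
                    T = RigidTransform2D(0.0, np.array(nom, dtype=float))
                else:
                    ang = rng.uniform(-max_rot, max_rot)
                    jit = rng.uniform(-spec.max_jitter_px, spec.max_jitter_px, size=2)
                    T = RigidTransform2D(ang, np.array(nom, dtype=float) + jit)
                truth[tid] = T
                # observed pixel (x, y) shows the world at T(correct(x, y))
                gx, gy = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
                pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
                if spec.distortion is not None:
                    pts = spec.distortion.apply(pts)
                wpts = T.apply(pts)
                tiles[tid] = map_coordinates(
                    world, [wpts[:, 1], wpts[:, 0]], order=1, mode="nearest"
                ).reshape(size, size)

    # Neighbor pairs: 4-connected in-plane plus same-cell links to section +-1
    pairs: List[Tuple[str, str]] = []
    for s in range(spec.n_sections):
        for r in range(spec.rows):
            for c in range(spec.cols):
                if c + 1 < spec.cols:
                    pairs.append((_tile_id(s, r, c), _tile_id(s, r, c + 1)))
                if r + 1 < spec.rows:
                    pairs.append((_tile_id(s, r, c), _tile_id(s, r + 1, c)))
                if s + 1 < spec.n_sections:
                    pairs.append((_tile_id(s, r, c), _tile_id(s + 1, r, c)))

    corrs: List[Correspondence] = []
    g = np.arange(2.0, size - 2.0, spec.corr_grid_step)
    gx, gy = np.meshgrid(g, g)
    grid_obs = np.stack([gx.ravel(), gy.ravel()], axis=1)
    for ta, tb in pairs:
        ideal_a = (
            spec.distortion.apply(grid_obs) if spec.distortion is not None else grid_obs
        )
        world_pts = truth[ta].apply(ideal_a)
        ideal_b = truth[tb].inverse().apply(world_pts)
        obs_b = (
            spec.distortion.inverse_apply(ideal_b)
            if spec.distortion is not None
            else ideal_b
        )
        keep = (
            (obs_b[:, 0] >= 0) & (obs_b[:, 0] <= size - 1)
            & (obs_b[:, 1] >= 0) & (obs_b[:, 1] <= size - 1)
        )
        pa = grid_obs[keep]
        pb = obs_b[keep]
        if spec.noise_sigma > 0:
            # one localisation-error draw per correspondence
            pb = pb + rng.normal(0, spec.noise_sigma, pb.shape)
        for a, b in zip(pa, pb):
            corrs.append(Correspondence(ta, tb, (a[0], a[1]), (b[0], b[1])))

    return MosaicResult(
        spec=spec,
        tiles=tiles,
        true_transforms=truth,
        nominal_offsets=nominal,
        correspondences=corrs,
        anchor_tile=anchor,
    )


def generate_lens_calibration_set(
    distortion: PolynomialDistortion2D,
    image_size: int = 128,
    n_placements: int = 9,
    max_rotation_deg: float = 5.0,
    max_shift_px: float = 10.0,
    grid_step: int = 10,
    seed: int = 0,
) -> Tuple[List[Correspondence], Dict[str, RigidTransform2D]]:
    """Correspondences from heavily overlapping placements of one scene.

    ``distortion`` is the planted *correction* C: observed coordinates are
    generated as C^{-1}(ideal) so the estimator should recover C itself.
    Placement 0 is identity.  Returns (correspondences, placement rigids).
    """
    rng = np.random.default_rng(seed)
    rigids: Dict[str, RigidTransform2D] = {}
    for k in range(n_placements):
        if k == 0:
            rigids[f"p{k}"] = RigidTransform2D()
        else:
            ang = rng.uniform(-np.deg2rad(max_rotation_deg), np.deg2rad(max_rotation_deg))
            t = rng.uniform(-max_shift_px, max_shift_px, size=2)
            rigids[f"p{k}"] = RigidTransform2D(ang, t)

    g = np.arange(2.0, image_size - 2.0, grid_step)
    gx, gy = np.meshgrid(g, g)
    world = np.stack([gx.ravel(), gy.ravel()], axis=1)

    ids = sorted(rigids)
    corrs: List[Correspondence] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ia = rigids[ids[i]].inverse().apply(world)
            ib = rigids[ids[j]].inverse().apply(world)
            oa = distortion.inverse_apply(ia)
            ob = distortion.inverse_apply(ib)
            keep = np.all((oa >= 0) & (oa <= image_size - 1), axis=1)
            keep &= np.all((ob >= 0) & (ob <= image_size - 1), axis=1)
            for a, b in zip(oa[keep], ob[keep]):
                corrs.append(Correspondence(ids[i], ids[j], (a[0], a[1]), (b[0], b[1])))
    return corrs, rigids


# ---------------------------------------------------------------------------
# Microvolumes


@dataclass
class MicrovolumeSpec:
    """Composition of a synthetic dense microvolume.

    Per-class segment counts, mean segment lengths (µm), the number of
    planted presynaptic sites, and the polyadic fan-out range.  Axonal-class
    segments are oriented within ``axon_cone_deg`` of the longitudinal (z)
    axis; dendritiform segments take highly tortuous walks.  Branch rates
    are planted as one branch point per ``*_branch_interval_um`` of cable.
    """

    box_um: Tuple[float, float, float] = (5.0, 5.0, 5.0)
    counts: Dict[str, int] = field(
        default_factory=lambda: {
            "varicose": 10,
            "globular": 1,
            "axiform": 6,
            "dendritiform": 25,
        }
    )
    mean_length_um: Dict[str, float] = field(
        default_factory=lambda: {
            "varicose": 3.8,
            "globular": 3.8,
            "axiform": 3.8,
            "dendritiform": 4.0,
        }
    )
    n_presynaptic_sites: int = 20
    fanout_range: Tuple[int, int] = (3, 5)
    total_post_contacts: Optional[int] = None  # exact total; None = free
    n_varicose_with_synapses: Optional[int] = None
    axon_cone_deg: float = 20.0
    axonal_branch_interval_um: float = 7.5
    dendritic_branch_interval_um: float = 4.1
    step_um: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.fanout_range[0] < 1 or self.fanout_range[0] > self.fanout_range[1]:
            raise ValueError("invalid fan-out range")
        if min(self.box_um) <= 0:
            raise ValueError("box dimensions must be positive")
        # crude feasibility check: total requested cable vs box volume
        cable = sum(
            self.counts.get(k, 0) * self.mean_length_um.get(k, 0.0) for k in self.counts
        )
        vol = float(np.prod(self.box_um))
        if cable > 40.0 * vol:
            raise ValueError("box too small for the requested segment counts")

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.box_um))


@dataclass
class MicrovolumeResult:
    spec: MicrovolumeSpec
    segments: List[NeuriteSegment]
    synapses: List[SynapseAnnotation]
    truth: dict


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _axon_direction(rng: np.random.Generator, cone_deg: float) -> np.ndarray:
    """Unit vector within ``cone_deg`` of +z (longitudinal axis)."""
    cos_max = np.cos(np.deg2rad(cone_deg))
    cz = rng.uniform(cos_max, 1.0)
    phi = rng.uniform(0, 2 * np.pi)
    s = np.sqrt(1.0 - cz ** 2)
    d = np.array([s * np.cos(phi), s * np.sin(phi), cz])
    return d if rng.random() < 0.5 else -d


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    n_steps: int,
    step: float,
    jitter: float,
    box: np.ndarray,
    boundary: str = "reflect",
) -> np.ndarray:
    """Random walk with per-step angular jitter inside the box.

    ``boundary="reflect"`` bounces off the walls (tortuous dendritiform
    walks); ``boundary="truncate"`` stops at the first wall crossing
    (straight axonal processes pass through the microvolume, so their
    in-volume fragment ends at a box face).
    """
    pts = [start.copy()]
    d = direction / np.linalg.norm(direction)
    p = start.copy()
    for _ in range(n_steps):
        d = d + jitter * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        p = p + step * d
        if np.any(p < 0) or np.any(p > box):
            if boundary == "truncate":
                break
            for ax in range(3):
                if p[ax] < 0:
                    p[ax] = -p[ax]
                    d[ax] = -d[ax]
                elif p[ax] > box[ax]:
                    p[ax] = 2 * box[ax] - p[ax]
                    d[ax] = -d[ax]
        pts.append(p.copy())
    return np.array(pts)


def _varicose_radii(
    rng: np.random.Generator, n: int, thick_lo: float, thick_hi: float
) -> Tuple[np.ndarray, List[int]]:
    """Alternating thin/thick runs; returns radii and swelling point indices."""
    radii = np.empty(n)
    swell_idx: List[int] = []
    i = 0
    thick_phase = False
    while i < n:
        if thick_phase:
            run = int(rng.integers(2, 5))
            r = rng.uniform(thick_lo, thick_hi) / 2.0
        else:
            run = int(rng.integers(3, 7))
            r = rng.uniform(0.25, 0.35) / 2.0
        j = min(n, i + run)
        radii[i:j] = r
        if thick_phase:
            swell_idx.extend(range(i, j))
        thick_phase = not thick_phase
        i = j
    return radii, swell_idx


def _make_segment(
    rng: np.random.Generator, label: str, seg_id: str, spec: MicrovolumeSpec
) -> Tuple[NeuriteSegment, List[int]]:
    """One segment of the requested class, guaranteed to classify as such."""
    box = np.asarray(spec.box_um, dtype=float)
    rules = ClassRules()
    target_len = max(1.2, rng.normal(spec.mean_length_um[label], 0.3 * spec.mean_length_um[label]))
    n_steps = max(5, int(round(target_len / spec.step_um)))
    margin = 0.1
    start = rng.uniform(margin, box - margin)

    for _ in range(50):
        swell: List[int] = []
        if label == "dendritiform":
            pts = _walk(rng, start, _random_unit(rng), n_steps, spec.step_um, 0.9, box)
            radii = rng.uniform(0.12, 0.18, len(pts)) / 2.0
            L = polyline_length(pts)
            nb = max(1, int(round(L / spec.dendritic_branch_interval_um)))
            branch = tuple(
                sorted(rng.choice(np.arange(1, len(pts) - 1), size=min(nb, len(pts) - 2), replace=False))
            )
        elif label == "axiform":
            pts = _walk(
                rng, start, _axon_direction(rng, spec.axon_cone_deg), n_steps,
                spec.step_um, 0.02, box, boundary="truncate",
            )
            if len(pts) < 2:
                start = rng.uniform(margin, box - margin)
                continue
            base = rng.uniform(0.25, 0.35)
            radii = base * (1.0 + rng.uniform(-0.03, 0.03, len(pts))) / 2.0
            branch = ()
        else:  # varicose / globular
            pts = _walk(
                rng, start, _axon_direction(rng, spec.axon_cone_deg), n_steps,
                spec.step_um, 0.15, box, boundary="truncate",
            )
            if len(pts) < 5:
                start = rng.uniform(margin, box - margin)
                continue
            if label == "globular":
                radii, swell = _varicose_radii(rng, len(pts), 1.6, 2.0)
            else:
                radii, swell = _varicose_radii(rng, len(pts), 0.7, 1.2)
            L = polyline_length(pts)
            nb = int(rng.poisson(L / spec.axonal_branch_interval_um))
            interior = np.arange(1, len(pts) - 1)
            branch = tuple(
                sorted(rng.choice(interior, size=min(nb, len(interior)), replace=False))
            ) if nb > 0 else ()
        seg = NeuriteSegment(
            segment_id=seg_id, centerline=pts, radii=radii, branch_nodes=branch,
            class_label=label,
        )
        from .morphometry import classify_neurite

        if seg.length() >= 1.0 and classify_neurite(seg, rules) == label:
            return seg, swell
        start = rng.uniform(margin, box - margin)  # retry with a new draw
    raise RuntimeError(f"could not generate a valid {label} segment")


def _fanouts(
    rng: np.random.Generator, n: int, lo: int, hi: int, total: Optional[int]
) -> np.ndarray:
    f = rng.integers(lo, hi + 1, size=n)
    if total is not None:
        if not (n * lo <= total <= n * hi):
            raise ValueError("requested contact total incompatible with fan-out range")
        while f.sum() != total:
            i = int(rng.integers(0, n))
            if f.sum() > total and f[i] > lo:
                f[i] -= 1
            elif f.sum() < total and f[i] < hi:
                f[i] += 1
    return f


def generate_microvolume(spec: MicrovolumeSpec) -> MicrovolumeResult:
    """Segments + synapses + planted-truth summary for one microvolume.

    Presynaptic sites sit on the swellings of varicose/globular neurites
    only; postsynaptic contacts land on dendritiform neurites only; fan-out
    is drawn from ``spec.fanout_range`` (optionally constrained to an exact
    contact total).
    """
    rng = np.random.default_rng(spec.seed)
    segments: List[NeuriteSegment] = []
    swellings: Dict[str, List[int]] = {}
    order = ("varicose", "globular", "axiform", "dendritiform")
    for label in order:
        for k in range(spec.counts.get(label, 0)):
            seg, swell = _make_segment(rng, label, f"{label[:1]}{k}", spec)
            segments.append(seg)
            swellings[seg.segment_id] = swell

    varicose = [s for s in segments if s.class_label == "varicose"]
    globular = [s for s in segments if s.class_label == "globular"]
    dendritiform = [s for s in segments if s.class_label == "dendritiform"]

    synapses: List[SynapseAnnotation] = []
    n_pre = spec.n_presynaptic_sites
    if n_pre > 0:
        if not (varicose or globular):
            raise ValueError("presynaptic sites need varicose/globular hosts")
        if not dendritiform:
            raise ValueError("postsynaptic contacts need dendritiform targets")
        n_var_hosts = spec.n_varicose_with_synapses
        if n_var_hosts is None:
            n_var_hosts = len(varicose)
        hosts = list(globular) + list(
            rng.choice(varicose, size=min(n_var_hosts, len(varicose)), replace=False)
        ) if varicose else list(globular)
        # distribute sites over hosts, each host >= 1 site where possible
        alloc = np.zeros(len(hosts), dtype=int)
        if n_pre >= len(hosts):
            alloc += 1
            extra = n_pre - len(hosts)
        else:
            alloc[rng.choice(len(hosts), size=n_pre, replace=False)] = 1
            extra = 0
        for _ in range(extra):
            alloc[int(rng.integers(0, len(hosts)))] += 1
        fan = _fanouts(rng, n_pre, spec.fanout_range[0], spec.fanout_range[1],
                       spec.total_post_contacts)
        k = 0
        for host, n_sites in zip(hosts, alloc):
            swell = swellings.get(host.segment_id) or list(range(len(host.radii)))
            for _ in range(n_sites):
                pre_idx = int(rng.choice(swell))
                posts = []
                for _ in range(int(fan[k])):
                    d = dendritiform[int(rng.integers(0, len(dendritiform)))]
                    posts.append((d.segment_id, int(rng.integers(0, len(d.radii)))))
                synapses.append(
                    SynapseAnnotation(
                        synapse_id=f"syn{k}",
                        presynaptic=(host.segment_id, pre_idx),
                        postsynaptic=posts,
                    )
                )
                k += 1

    truth = {
        "volume_um3": spec.volume_um3,
        "counts": dict(spec.counts),
        "n_presynaptic_sites": len(synapses),
        "n_postsynaptic_contacts": sum(len(s.postsynaptic) for s in synapses),
        "presynapse_density_per_um3": len(synapses) / spec.volume_um3,
        "axonal_cable_um": sum(
            s.length() for s in segments if s.class_label in ("varicose", "globular", "axiform")
        ),
        "dendritic_cable_um": sum(
            s.length() for s in segments if s.class_label == "dendritiform"
        ),
    }
    return MicrovolumeResult(spec=spec, segments=segments, synapses=synapses, truth=truth)


def vnc_fixture(seed: int = 8520) -> MicrovolumeResult:
    """Deterministic VNC-like microvolume.

    An 85 µm³ box with exactly 39 varicose, 1 globular, 25 axiform and 105
    dendritiform segments (all over 1 µm length), 68 presynaptic sites
    hosted on the globular neurite and 24 of the varicose neurites, and 256
    postsynaptic contacts on dendritiform neurites (aggregate post:pre ratio
    256/68 ≈ 3.8).
    """
    spec = MicrovolumeSpec(
        box_um=(5.0, 5.0, 3.4),
        counts={"varicose": 39, "globular": 1, "axiform": 25, "dendritiform": 105},
        mean_length_um={
            "varicose": 3.8,
            "globular": 3.8,
            "axiform": 3.8,
            "dendritiform": 4.0,
        },
        n_presynaptic_sites=68,
        fanout_range=(3, 5),
        total_post_contacts=256,
        n_varicose_with_synapses=24,
        axon_cone_deg=20.0,
        axonal_branch_interval_um=7.5,
        dendritic_branch_interval_um=4.1,
        seed=seed,
    )
    return generate_microvolume(spec)
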