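"""Neurite classification and dense-microvolume statistics.

Dense reconstruction of small neuropile volumes distinguishes four generic
neurite classes:

* **axiform** — straight, unbranched processes of even diameter
  (0.2–0.4 µm), the long axons of fascicles;
* **varicose** — branched processes alternating thin stretches
  (0.15–0.4 µm) with presynapse-bearing swellings (varicosities,
  0.5–1.5 µm);
* **globular** — varicose-like processes whose swellings ("boutons")
  exceed 1.5 µm in diameter;
* **dendritiform** — highly branched, thin (<0.2 µm), tortuous fibers
  carrying the postsynaptic sites.

This module implements the classification rules and the standard microvolume
statistics: cable length, volume-equivalent cylinder diameter, branch
intervals, and synapse densities.  All geometry is in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "AXONAL_CLASSES",
    "CLASS_LABELS",
    "NeuriteSegment",
    "SynapseAnnotation",
    "ClassRules",
    "MicrovolumeSummary",
    "polyline_length",
    "cable_length",
    "mean_cylinder_diameter",
    "classify_neurite",
    "branch_interval",
    "presynapse_density",
    "summarize_microvolume",
    "clip_to_box",
]

CLASS_LABELS = ("axiform", "varicose", "globular", "dendritiform", "unclassified")
AXONAL_CLASSES = ("axiform", "varicose", "globular")


@dataclass
class NeuriteSegment:
    """A 3D centerline with per-point radii and synaptic/branch annotations."""

    segment_id: str
    centerline: np.ndarray  # (n, 3) µm
    radii: np.ndarray  # (n,) µm
    branch_nodes: Tuple[int, ...] = ()
    class_label: str = "unclassified"

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.centerline.shape[0] < 1 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be a non-empty (n, 3) array")
        if self.radii.shape[0] != self.centerline.shape[0]:
            raise ValueError("one radius per centerline point required")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be > 0")
        n = self.centerline.shape[0]
        if any(not (0 <= b < n) for b in self.branch_nodes):
            raise ValueError("branch node index out of range")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def diameters(self) -> np.ndarray:
        """Local diameters (2 x radius) along the centerline."""
        return 2.0 * self.radii

    def length(self) -> float:
        return polyline_length(self.centerline)

    def tortuosity(self) -> float:
        """Path length over endpoint distance (inf for closed/degenerate paths)."""
        L = self.length()
        chord = float(np.linalg.norm(self.centerline[-1] - self.centerline[0]))
        if chord == 0.0:
            return math.inf if L > 0 else 1.0
        return L / chord

    def n_branch_points(self) -> int:
        return len(self.branch_nodes)


@dataclass
class SynapseAnnotation:
    """A polyadic synapse: one presynaptic site, >=1 postsynaptic contacts."""

    synapse_id: str
    presynaptic: Tuple[str, int]  # (segment_id, centerline index)
    postsynaptic: List[Tuple[str, int]]
    has_t_bar: bool = True

    def __post_init__(self) -> None:
        if len(self.postsynaptic) < 1:
            raise ValueError("polyadic synapse needs >=1 postsynaptic entry")


@dataclass
class ClassRules:
    """Diameter bands and geometry thresholds for neurite classification.

    Diameter bands are in µm: the axiform band, the thick (varicosity) and
    thin bands of varicose neurites, the globular threshold, and the
    dendritiform thinness threshold.  ``cv_max`` bounds the coefficient of
    variation of diameter for an "even" caliber; ``tortuosity_max`` bounds
    path/chord ratio for a "straight" course;
    ``dendritiform_max_branch_interval`` is the branch interval (µm/branch)
    below which a thin neurite counts as highly branched.
    """

    axiform_band: Tuple[float, float] = (0.2, 0.4)
    varicose_thick: Tuple[float, float] = (0.5, 1.5)
    varicose_thin: Tuple[float, float] = (0.15, 0.4)
    globular_threshold: float = 1.5
    dendritiform_threshold: float = 0.2
    cv_max: float = 0.25
    tortuosity_max: float = 1.2
    swelling_min_run: int = 2
    dendritiform_max_branch_interval: float = 5.0

    def __post_init__(self) -> None:
        ok = (
            self.dendritiform_threshold <= self.axiform_band[0] < self.axiform_band[1]
            and self.axiform_band[1] <= self.varicose_thick[0] < self.varicose_thick[1]
            and self.varicose_thick[1] <= self.globular_threshold
            and self.varicose_thin[0] < self.varicose_thin[1] <= self.varicose_thick[0]
        )
        if not ok:
            raise ValueError("class-rule thresholds are inconsistently ordered")


def polyline_length(points: np.ndarray) -> float:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def cable_length(
    segments: Union[NeuriteSegment, Iterable[NeuriteSegment]],
    class_filter: Optional[Sequence[str]] = None,
) -> float:
    """Total centerline length (µm) of segments matching ``class_filter``.

    ``class_filter`` is a collection of class labels (``None`` keeps all);
    an empty selection sums to 0.
    """
    if isinstance(segments, NeuriteSegment):
        segments = [segments]
    allowed = set(class_filter) if class_filter is not None else None
    total = 0.0
    for s in segments:
        if allowed is None or s.class_label in allowed:
            total += s.length()
    return total


def mean_cylinder_diameter(segment: NeuriteSegment) -> float:
    """Diameter of the equal-length, equal-volume smooth cylinder.

    Segment volume is the sum of conical-frustum volumes between consecutive
    centerline points; ``d = 2 sqrt(V / (pi L))``.
    """
    L = segment.length()
    if L == 0.0:
        raise ValueError("zero-length centerline has no cylinder diameter")
    V = _frustum_volume(segment.centerline, segment.radii)
    return 2.0 * math.sqrt(V / (math.pi * L))


def _frustum_volume(centerline: np.ndarray, radii: np.ndarray) -> float:
    h = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    r1, r2 = radii[:-1], radii[1:]
    return float(np.sum(math.pi * h / 3.0 * (r1 ** 2 + r1 * r2 + r2 ** 2)))


def _has_swelling(diameters: np.ndarray, rules: ClassRules) -> bool:
    """A swelling is a run of >= swelling_min_run points in the thick band."""
    thick = diameters >= rules.varicose_thick[0]
    run = 0
    for t in thick:
        run = run + 1 if t else 0
        if run >= rules.swelling_min_run:
            return True
    return False


def classify_neurite(segment: NeuriteSegment, rules: Optional[ClassRules] = None) -> str:
    """Assign one of the four generic neurite classes.

    Decision order (most specific printed criterion first):

    1. *globular* if any local diameter exceeds the globular threshold;
    2. *varicose* if the profile alternates between the thick and thin bands
       with at least one persistent swelling;
    3. *dendritiform* if the median diameter is below the thinness threshold
       and the segment is either highly branched or highly tortuous;
    4. *axiform* if the caliber sits in the axiform band, is even
       (CV below ``cv_max``), unbranched, and the course is straight;
    5. otherwise *unclassified*.
    """
    if rules is None:
        rules = ClassRules()
    if segment.centerline.shape[0] < 2:
        raise ValueError("cannot classify a single-point segment")
    d = segment.diameters
    if np.any(d > rules.globular_threshold):
        return "globular"
    if _has_swelling(d, rules) and np.any(d <= rules.varicose_thin[1]):
        return "varicose"
    if float(np.median(d)) < rules.dendritiform_threshold:
        L = segment.length()
        nb = segment.n_branch_points()
        highly_branched = nb > 0 and L / nb <= rules.dendritiform_max_branch_interval
        if highly_branched or segment.tortuosity() > rules.tortuosity_max:
            return "dendritiform"
    mean_d = float(np.mean(d))
    cv = float(np.std(d) / mean_d) if mean_d > 0 else math.inf
    if (
        rules.axiform_band[0] <= mean_d <= rules.axiform_band[1]
        and cv < rules.cv_max
        and segment.n_branch_points() == 0
        and segment.tortuosity() < rules.tortuosity_max
    ):
        return "axiform"
    return "unclassified"


def branch_interval(cable_length_um: float, n_branch_points: int) -> Optional[float]:
    """Cable length per branch point (µm/branch); None when unbranched."""
    if cable_length_um < 0 or n_branch_points < 0:
        raise ValueError("inputs must be non-negative")
    if n_branch_points == 0:
        return None
    return cable_length_um / n_branch_points


def presynapse_density(n_presynaptic_sites: int, volume_um3: float) -> float:
    """Presynaptic sites per µm³."""
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    if n_presynaptic_sites < 0:
        raise ValueError("count must be non-negative")
    return n_presynaptic_sites / volume_um3


@dataclass
class MicrovolumeSummary:
    """Per-microvolume statistics of a dense reconstruction."""

    volume_um3: float
    class_counts: Dict[str, int]
    n_elements: int
    axonal_cable_um: float
    dendritic_cable_um: float
    n_axonal_branch_points: int
    n_dendritic_branch_points: int
    n_presynaptic_sites: int
    n_postsynaptic_sites: int
    presynapse_density_per_um3: float
    axonal_branch_interval_um: Optional[float]
    dendritic_branch_interval_um: Optional[float]
    mean_axonal_diameter_um: Optional[float]
    mean_dendritic_diameter_um: Optional[float]
    placement_violations: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["class_counts"] = dict(self.class_counts)
        return d


def summarize_microvolume(
    segments: Sequence[NeuriteSegment],
    synapses: Sequence[SynapseAnnotation],
    volume_um3: float,
    rules: Optional[ClassRules] = None,
    min_length_um: float = 1.0,
    classify: bool = True,
) -> MicrovolumeSummary:
    """Summarise a densely reconstructed microvolume.

    Only elements with in-volume length >= ``min_length_um`` (1 µm default)
    are counted.  Segments are classified with :func:`classify_neurite`
    unless ``classify=False``, in which case stored labels are trusted.
    Axonal cable aggregates the axiform/varicose/globular classes; dendritic
    cable the dendritiform class.  A validation pass checks the synapse
    placement rule (presynaptic sites on the thick swellings of
    varicose/globular neurites) and reports the number of violations.
    """
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    if rules is None:
        rules = ClassRules()

    by_id = {s.segment_id: s for s in segments}
    bad_refs = []
    for syn in synapses:
        refs = [syn.presynaptic] + list(syn.postsynaptic)
        for seg_id, idx in refs:
            seg = by_id.get(seg_id)
            if seg is None or not (0 <= idx < seg.centerline.shape[0]):
                bad_refs.append((syn.synapse_id, seg_id, idx))
    if bad_refs:
        raise ValueError(f"inconsistent synapse references: {bad_refs}")

    counts = {k: 0 for k in CLASS_LABELS}
    ax_len = dn_len = 0.0
    ax_branch = dn_branch = 0
    ax_V = ax_L = dn_V = dn_L = 0.0
    labels: Dict[str, str] = {}
    for s in segments:
        label = classify_neurite(s, rules) if classify else s.class_label
        labels[s.segment_id] = label
        if s.length() < min_length_um:
            continue
        counts[label] += 1
        if label in AXONAL_CLASSES:
            ax_len += s.length()
            ax_branch += s.n_branch_points()
            ax_V += _frustum_volume(s.centerline, s.radii)
            ax_L += s.length()
        elif label == "dendritiform":
            dn_len += s.length()
            dn_branch += s.n_branch_points()
            dn_V += _frustum_volume(s.centerline, s.radii)
            dn_L += s.length()

    n_pre = len(synapses)
    n_post = sum(len(s.postsynaptic) for s in synapses)

    violations = 0
    for syn in synapses:
        seg = by_id[syn.presynaptic[0]]
        local_d = 2.0 * seg.radii[syn.presynaptic[1]]
        if labels.get(seg.segment_id) not in ("varicose", "globular") or (
            local_d < rules.varicose_thick[0]
        ):
            violations += 1

    def cyl(V: float, L: float) -> Optional[float]:
        return 2.0 * math.sqrt(V / (math.pi * L)) if L > 0 else None

    return MicrovolumeSummary(
        volume_um3=volume_um3,
        class_counts={k: counts[k] for k in CLASS_LABELS},
        n_elements=sum(counts.values()),
        axonal_cable_um=ax_len,
        dendritic_cable_um=dn_len,
        n_axonal_branch_points=ax_branch,
        n_dendritic_branch_points=dn_branch,
        n_presynaptic_sites=n_pre,
        n_postsynaptic_sites=n_post,
        presynapse_density_per_um3=presynapse_density(n_pre, volume_um3),
        axonal_branch_interval_um=branch_interval(ax_len, ax_branch),
        dendritic_branch_interval_um=branch_interval(dn_len, dn_branch),
        mean_axonal_diameter_um=cyl(ax_V, ax_L),
        mean_dendritic_diameter_um=cyl(dn_V, dn_L),
        placement_violations=violations,
    )


def clip_to_box(
    segment: NeuriteSegment, box_min, box_max
) -> List[NeuriteSegment]:
    """Clip a segment to an axis-aligned box, splitting at the box faces.

    Crossing edges are cut by linear interpolation of position and radius;
    each maximal in-box run becomes its own sub-segment (branch annotations
    are dropped, class label is kept).
    """
    lo = np.asarray(box_min, dtype=float)
    hi = np.asarray(box_max, dtype=float)
    pts, radii = segment.centerline, segment.radii

    def inside(p):
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def clip_edge(p0, p1):
        """Liang-Barsky parametric clip of segment p0->p1 against the box."""
        d = p1 - p0
        t0, t1 = 0.0, 1.0
        for ax in range(3):
            if d[ax] == 0:
                if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                    return None
            else:
                ta = (lo[ax] - p0[ax]) / d[ax]
                tb = (hi[ax] - p0[ax]) / d[ax]
                ta, tb = min(ta, tb), max(ta, tb)
                t0, t1 = max(t0, ta), min(t1, tb)
                if t0 > t1:
                    return None
        return t0, t1

    runs: List[Tuple[List[np.ndarray], List[float]]] = []
    cur_p: List[np.ndarray] = []
    cur_r: List[float] = []

    def flush():
        nonlocal cur_p, cur_r
        if len(cur_p) >= 2:
            runs.append((cur_p, cur_r))
        cur_p, cur_r = [], []

    for i in range(len(pts) - 1):
        p0, p1 = pts[i], pts[i + 1]
        r0, r1 = radii[i], radii[i + 1]
        res = clip_edge(p0, p1)
        if res is None:
            flush()
            continue
        t0, t1 = res
        a = p0 + t0 * (p1 - p0)
        b = p0 + t1 * (p1 - p0)
        ra = r0 + t0 * (r1 - r0)
        rb = r0 + t1 * (r1 - r0)
        if not cur_p or not np.allclose(cur_p[-1], a):
            flush()
            cur_p, cur_r = [a], [ra]
        cur_p.append(b)
        cur_r.append(rb)
        if t1 < 1.0:
            flush()
    flush()

    out = []
    for k, (ps, rs) in enumerate(runs):
        out.append(
            NeuriteSegment(
                segment_id=f"{segment.segment_id}.clip{k}",
                centerline=np.array(ps),
                radii=np.array(rs),
                class_label=segment.class_label,
            )
        )
    return out
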