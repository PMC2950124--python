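"""Imaging geometry, calibration and the segmentation data model.

The TEM volume is organised as a :class:`Stack` of serial :class:`Section`
objects, each composed of overlapping image :class:`Tile` s.  Manual
segmentation uses a small set of primitive object types — :class:`AreaList`
(per-section 2D regions), :class:`Pipe` (a tube through serial points) and
:class:`Ball` (spheres on sections) — grouped into a recursive
:class:`HierarchyNode` tree so that high-order entities (neurons, lineages,
compartments) can be manipulated as units.

Pixel coordinates are 0-based, origin at the top-left of the section-global
canvas, x rightward, y downward; the z index is the 0-based section index.
Physical coordinates are micrometres; the physical z of section *i* is
``i * section_thickness``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Calibration",
    "Tile",
    "Section",
    "Stack",
    "AreaList",
    "Pipe",
    "Ball",
    "TextLabel",
    "HierarchyNode",
    "to_physical",
    "from_physical",
    "collect_primitives",
    "export_sif",
    "import_sif",
    "pipe_to_segment",
]


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of the image stack.

    Parameters
    ----------
    lateral_resolution : float
        Lateral pixel size in nm/px (4 nm/px for the reference acquisitions).
    section_thickness : float
        Section thickness in nm (60 nm serial sections).
    """

    lateral_resolution: float = 4.0
    section_thickness: float = 60.0

    def __post_init__(self) -> None:
        if self.lateral_resolution <= 0:
            raise ValueError("lateral_resolution must be > 0")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be > 0")


@dataclass
class Tile:
    """One acquired image tile with its transform chain.

    ``transform_chain`` is an ordered list of callables mapping tile-local
    pixel coordinates to section-global pixel coordinates, applied first to
    last (lens correction, then rigid montage transform, then section warp).
    """

    tile_id: str
    section_index: int
    image_ref: Optional[str] = None
    nominal_offset: Tuple[float, float] = (0.0, 0.0)
    transform_chain: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.section_index < 0:
            raise ValueError("section_index must be non-negative")

    def map_to_section(self, points: np.ndarray) -> np.ndarray:
        """Apply the full transform chain to (n, 2) tile-local points."""
        pts = np.asarray(points, dtype=float)
        for t in self.transform_chain:
            pts = t(pts)
        return pts


@dataclass
class Section:
    index: int
    tiles: List[Tile] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.tile_id for t in self.tiles]
        if len(ids) != len(set(ids)):
            raise ValueError("tile ids must be unique within a section")


@dataclass
class Stack:
    """Ordered series of sections with shared calibration.

    Section indices must be strictly increasing; gaps are allowed only for
    indices listed in ``missing_sections`` (serial sectioning occasionally
    loses sections; the reference VNC series lost two out of 300).
    """

    sections: List[Section] = field(default_factory=list)
    calibration: Calibration = field(default_factory=Calibration)
    missing_sections: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        idx = [s.index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section indices must be strictly increasing")
        if idx:
            expected = set(range(idx[0], idx[-1] + 1))
            gaps = expected - set(idx) - set(self.missing_sections)
            if gaps:
                raise ValueError(
                    f"sections {sorted(gaps)} absent but not flagged missing"
                )


@dataclass
class AreaList:
    """Per-section 2D multi-area object.

    ``regions`` maps section index to a list of polygons, each an (n, 2)
    array of section-global pixel vertices (even-odd fill convention).
    """

    object_id: str
    regions: dict = field(default_factory=dict)

    def area_px2(self, section_index: int) -> float:
        """Total (shoelace) polygon area on one section, in px^2."""
        total = 0.0
        for poly in self.regions.get(section_index, []):
            p = np.asarray(poly, dtype=float)
            x, y = p[:, 0], p[:, 1]
            total += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        return total


@dataclass
class Pipe:
    """Serial sequence of (x px, y px, section_index, radius px) points."""

    object_id: str
    points: np.ndarray  # (n, 4)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 4)
        if pts.shape[0] < 1:
            raise ValueError("pipe needs at least one point")
        if np.any(pts[:, 3] <= 0):
            raise ValueError("pipe radii must be > 0")
        self.points = pts


@dataclass
class Ball:
    """List of (x px, y px, section_index, radius px) spheres."""

    object_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 4)
        if np.any(pts[:, 3] <= 0):
            raise ValueError("ball radii must be > 0")
        self.points = pts


@dataclass
class TextLabel:
    """Floating annotation anchored to (x px, y px, section_index)."""

    text: str
    x: float
    y: float
    section_index: int


@dataclass
class HierarchyNode:
    """Node of the recursive object-hierarchy tree.

    Group nodes hold children; primitive nodes are leaves and carry a
    ``payload`` referencing a segmentation object (AreaList, Pipe, Ball, ...).
    """

    name: str
    node_kind: str = "group"  # "group" | "primitive"
    children: List["HierarchyNode"] = field(default_factory=list)
    payload: object = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("node name must be non-empty")
        if self.node_kind not in ("group", "primitive"):
            raise ValueError(f"unknown node_kind {self.node_kind!r}")
        if self.node_kind == "primitive" and self.children:
            raise ValueError("primitive nodes must be leaves")


def to_physical(point, calibration: Calibration) -> np.ndarray:
    """Map (x px, y px, section_index) to a 3D physical point in µm.

    x and y are scaled by the lateral resolution; z is
    ``section_index * section_thickness``.  Accepts a single triple or an
    (n, 3) array.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(p[:, 2] < 0):
        raise ValueError("section index must be non-negative")
    out = np.empty_like(p)
    out[:, 0] = p[:, 0] * calibration.lateral_resolution / 1000.0
    out[:, 1] = p[:, 1] * calibration.lateral_resolution / 1000.0
    out[:, 2] = p[:, 2] * calibration.section_thickness / 1000.0
    return out[0] if single else out


def from_physical(point_um, calibration: Calibration) -> np.ndarray:
    """Inverse of :func:`to_physical` (µm back to pixel/section coordinates)."""
    p = np.asarray(point_um, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    out = np.empty_like(p)
    out[:, 0] = p[:, 0] * 1000.0 / calibration.lateral_resolution
    out[:, 1] = p[:, 1] * 1000.0 / calibration.lateral_resolution
    out[:, 2] = p[:, 2] * 1000.0 / calibration.section_thickness
    return out[0] if single else out


def collect_primitives(node: HierarchyNode) -> list:
    """Depth-first (document-order) list of primitive payloads under ``node``.

    Raises ``ValueError`` if the structure contains a cycle.
    """
    out: list = []
    on_path: set = set()

    def visit(n: HierarchyNode) -> None:
        if id(n) in on_path:
            raise ValueError(f"cycle detected at node {n.name!r}")
        on_path.add(id(n))
        if n.node_kind == "primitive":
            out.append(n.payload)
        else:
            for c in n.children:
                visit(c)
        on_path.remove(id(n))

    visit(node)
    return out


def export_sif(graph, path) -> None:
    """Write a network in SIF (simple interaction format) text.

    One line per edge ``PRE<tab>syn<tab>POST``; isolated nodes are written
    as single-column lines.  Lines are sorted for stable output.  ``graph``
    is any networkx-like directed graph with string node ids.
    """
    edges = sorted((str(u), str(v)) for u, v in graph.edges())
    connected = {u for u, v in edges} | {v for u, v in edges}
    isolated = sorted(str(n) for n in graph.nodes() if str(n) not in connected)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in edges:
            fh.write(f"{u}\tsyn\t{v}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def import_sif(path):
    """Read a SIF file back into an edge list + isolated-node list."""
    edges: List[Tuple[str, str]] = []
    isolated: List[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                isolated.append(parts[0])
            elif len(parts) == 3:
                edges.append((parts[0], parts[2]))
            elif parts != [""]:
                raise ValueError(f"malformed SIF line: {line!r}")
    return edges, isolated


def pipe_to_segment(pipe: Pipe, calibration: Calibration):
    """Convert a :class:`Pipe` to a µm-space neurite segment.

    The centerline goes through :func:`to_physical`; radii are scaled by the
    lateral resolution.  Returns a
    :class:`microtem.morphometry.NeuriteSegment`.
    """
    from .morphometry import NeuriteSegment

    pts = pipe.points
    centerline = to_physical(pts[:, :3], calibration)
    centerline = np.atleast_2d(centerline)
    radii = pts[:, 3] * calibration.lateral_resolution / 1000.0
    return NeuriteSegment(segment_id=pipe.object_id, centerline=centerline, radii=radii)


# ---------------------------------------------------------------------------
# Project persistence (single JSON document)


def save_project(path, stack: Stack, hierarchy: Optional[HierarchyNode] = None) -> None:
    """Persist stack layout, calibration and the object hierarchy as JSON."""

    def node_to_dict(n: HierarchyNode) -> dict:
        d = {"name": n.name, "kind": n.node_kind}
        if n.node_kind == "group":
            d["children"] = [node_to_dict(c) for c in n.children]
        else:
            d["payload"] = _payload_to_dict(n.payload)
        return d

    doc = {
        "format": "microtem-project",
        "version": 1,
        "calibration": {
            "lateral_resolution_nm_per_px": stack.calibration.lateral_resolution,
            "section_thickness_nm": stack.calibration.section_thickness,
        },
        "missing_sections": list(stack.missing_sections),
        "sections": [
            {
                "index": s.index,
                "tiles": [
                    {
                        "tile_id": t.tile_id,
                        "image_ref": t.image_ref,
                        "nominal_offset": list(t.nominal_offset),
                    }
                    for t in s.tiles
                ],
            }
            for s in stack.sections
        ],
    }
    if hierarchy is not None:
        doc["hierarchy"] = node_to_dict(hierarchy)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def _payload_to_dict(payload) -> dict:
    if isinstance(payload, Pipe):
        return {"type": "pipe", "id": payload.object_id, "points": payload.points.tolist()}
    if isinstance(payload, Ball):
        return {"type": "ball", "id": payload.object_id, "points": payload.points.tolist()}
    if isinstance(payload, AreaList):
        return {
            "type": "area_list",
            "id": payload.object_id,
            "regions": {
                str(k): [np.asarray(p).tolist() for p in v]
                for k, v in payload.regions.items()
            },
        }
    if isinstance(payload, TextLabel):
        return {
            "type": "text_label",
            "text": payload.text,
            "x": payload.x,
            "y": payload.y,
            "section_index": payload.section_index,
        }
    raise TypeError(f"cannot serialise payload of type {type(payload).__name__}")


def load_project(path) -> Tuple[Stack, Optional[HierarchyNode]]:
    """Inverse of :func:`save_project`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    cal = Calibration(
        lateral_resolution=doc["calibration"]["lateral_resolution_nm_per_px"],
        section_thickness=doc["calibration"]["section_thickness_nm"],
    )
    sections = [
        Section(
            index=s["index"],
            tiles=[
                Tile(
                    tile_id=t["tile_id"],
                    section_index=s["index"],
                    image_ref=t["image_ref"],
                    nominal_offset=tuple(t["nominal_offset"]),
                )
                for t in s["tiles"]
            ],
        )
        for s in doc["sections"]
    ]
    stack = Stack(
        sections=sections,
        calibration=cal,
        missing_sections=tuple(doc.get("missing_sections", ())),
    )

    def dict_to_node(d: dict) -> HierarchyNode:
        if d["kind"] == "group":
            return HierarchyNode(
                name=d["name"],
                node_kind="group",
                children=[dict_to_node(c) for c in d["children"]],
            )
        return HierarchyNode(
            name=d["name"], node_kind="primitive", payload=_dict_to_payload(d["payload"])
        )

    hierarchy = dict_to_node(doc["hierarchy"]) if "hierarchy" in doc else None
    return stack, hierarchy


def _dict_to_payload(d: dict):
    kind = d["type"]
    if kind == "pipe":
        return Pipe(object_id=d["id"], points=np.asarray(d["points"]))
    if kind == "ball":
        return Ball(object_id=d["id"], points=np.asarray(d["points"]))
    if kind == "area_list":
        return AreaList(
            object_id=d["id"],
            regions={
                int(k): [np.asarray(p) for p in v] for k, v in d["regions"].items()
            },
        )
    if kind == "text_label":
        return TextLabel(
            text=d["text"], x=d["x"], y=d["y"], section_index=d["section_index"]
        )
    raise ValueError(f"unknown payload type {kind!r}")
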