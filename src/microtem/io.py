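"""Readers and writers for the on-disk formats.

Skeletons travel as SWC (one neurite per file, radius column in µm, the
integer type field encoding the neurite class), synapse tables and montage
manifests as CSV, reports as JSON or CSV with a versioned schema.

SWC type codes: 0 unclassified, 2 axiform, 3 dendritiform, 5 varicose,
6 globular.  A point marked as a branch node carries its class code + 10, so
marked branch points survive a write→read round trip even on an unbranched
polyline; on reading, points with two or more children are additionally
inferred as branch nodes (standard SWC trees).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .morphometry import NeuriteSegment, SynapseAnnotation
from .registration import MLSWarp2D, MontageSolution, RigidTransform2D

__all__ = [
    "CLASS_TO_SWC",
    "SWC_TO_CLASS",
    "read_swc",
    "write_swc",
    "read_swc_dir",
    "read_synapse_csv",
    "write_synapse_csv",
    "read_fiducial_csv",
    "read_manifest",
    "write_manifest",
    "save_montage_solution",
    "load_montage_solution",
    "write_report",
]

CLASS_TO_SWC = {
    "unclassified": 0,
    "axiform": 2,
    "dendritiform": 3,
    "varicose": 5,
    "globular": 6,
}
SWC_TO_CLASS = {v: k for k, v in CLASS_TO_SWC.items()}
_BRANCH_OFFSET = 10


def read_swc(path) -> NeuriteSegment:
    """Read one neurite from an SWC file.

    Columns: id, type, x, y, z, radius, parent (µm).  Branch nodes are
    points with >=2 children or with a branch-marked type code.  Malformed
    lines raise with their line number.
    """
    ids: List[int] = []
    types: List[int] = []
    xyz: List[Tuple[float, float, float]] = []
    radii: List[float] = []
    parents: List[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                xyz.append((float(parts[2]), float(parts[3]), float(parts[4])))
                radii.append(float(parts[5]))
                parents.append(int(parts[6]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not ids:
        raise ValueError(f"{path}: empty SWC file")

    index = {node_id: k for k, node_id in enumerate(ids)}
    n_children = {node_id: 0 for node_id in ids}
    for p in parents:
        if p != -1:
            if p not in index:
                raise ValueError(f"{path}: parent id {p} not defined")
            n_children[p] += 1

    branch = set()
    for k, node_id in enumerate(ids):
        if n_children[node_id] >= 2 or types[k] >= _BRANCH_OFFSET:
            branch.add(k)

    base_types = [t - _BRANCH_OFFSET if t >= _BRANCH_OFFSET else t for t in types]
    label_codes = {t for t in base_types if t in SWC_TO_CLASS and t != 0}
    label = SWC_TO_CLASS[label_codes.pop()] if len(label_codes) == 1 else "unclassified"

    return NeuriteSegment(
        segment_id=Path(path).stem,
        centerline=np.asarray(xyz, dtype=float),
        radii=np.asarray(radii, dtype=float),
        branch_nodes=tuple(sorted(branch)),
        class_label=label,
    )


def write_swc(segment: NeuriteSegment, path) -> None:
    """Write a neurite as SWC (chain topology, branch nodes type-marked)."""
    code = CLASS_TO_SWC[segment.class_label]
    branch = set(segment.branch_nodes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# microtem {__version__} neurite {segment.segment_id}\n")
        fh.write("# id type x y z radius parent\n")
        for k, (p, r) in enumerate(zip(segment.centerline, segment.radii)):
            t = code + _BRANCH_OFFSET if k in branch else code
            parent = -1 if k == 0 else k
            fh.write(
                f"{k + 1} {t} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {r:.6f} {parent}\n"
            )


def read_swc_dir(directory) -> List[NeuriteSegment]:
    """All ``*.swc`` files of a directory, sorted by filename."""
    files = sorted(Path(directory).glob("*.swc"))
    return [read_swc(f) for f in files]


def write_synapse_csv(synapses: Sequence[SynapseAnnotation], path) -> None:
    """One row per postsynaptic contact."""
    rows = []
    for s in synapses:
        for post_seg, post_node in s.postsynaptic:
            rows.append(
                {
                    "synapse_id": s.synapse_id,
                    "pre_segment": s.presynaptic[0],
                    "pre_node": s.presynaptic[1],
                    "post_segment": post_seg,
                    "post_node": post_node,
                    "t_bar": int(s.has_t_bar),
                }
            )
    pd.DataFrame(
        rows,
        columns=["synapse_id", "pre_segment", "pre_node", "post_segment", "post_node", "t_bar"],
    ).to_csv(path, index=False)


def read_synapse_csv(path) -> List[SynapseAnnotation]:
    df = pd.read_csv(path)
    out: List[SynapseAnnotation] = []
    for syn_id, grp in df.groupby("synapse_id", sort=True):
        first = grp.iloc[0]
        out.append(
            SynapseAnnotation(
                synapse_id=str(syn_id),
                presynaptic=(str(first["pre_segment"]), int(first["pre_node"])),
                postsynaptic=[
                    (str(r["post_segment"]), int(r["post_node"])) for _, r in grp.iterrows()
                ],
                has_t_bar=bool(first["t_bar"]),
            )
        )
    return out


def read_fiducial_csv(path):
    """Fiducial pairs: columns label, sx, sy, sz, tx, ty, tz (µm)."""
    from .crossmodal import FiducialSet

    df = pd.read_csv(path)
    return FiducialSet(
        source=df[["sx", "sy", "sz"]].to_numpy(float),
        target=df[["tx", "ty", "tz"]].to_numpy(float),
        labels=tuple(str(x) for x in df["label"]),
    )


def write_manifest(rows: Sequence[dict], path) -> None:
    """Montage manifest: tile_id, section, path, nominal_x, nominal_y."""
    pd.DataFrame(rows, columns=["tile_id", "section", "path", "nominal_x", "nominal_y"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"tile_id", "section", "path", "nominal_x", "nominal_y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def save_montage_solution(solution: MontageSolution, path) -> None:
    doc = {
        "format": "microtem-montage",
        "version": 1,
        "residual_px2": solution.residual,
        "iterations": solution.iterations,
        "tiles": {
            tid: {"angle_rad": t.angle, "translation_px": t.translation.tolist()}
            for tid, t in sorted(solution.transforms.items())
        },
        "section_warps": {
            str(k): {
                "control": w.control.tolist(),
                "target": w.target.tolist(),
                "alpha": w.alpha,
                "model": w.model,
            }
            for k, w in sorted(solution.section_warps.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_montage_solution(path) -> MontageSolution:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    transforms = {
        tid: RigidTransform2D(d["angle_rad"], np.asarray(d["translation_px"]))
        for tid, d in doc["tiles"].items()
    }
    warps = {
        int(k): MLSWarp2D(
            np.asarray(d["control"]), np.asarray(d["target"]), d["alpha"], d["model"]
        )
        for k, d in doc.get("section_warps", {}).items()
    }
    return MontageSolution(
        transforms=transforms,
        residual=doc["residual_px2"],
        iterations=doc["iterations"],
        section_warps=warps,
    )


def _flatten(prefix: str, obj, out: Dict[str, object]) -> None:
    if isinstance(obj, dict):
        for k in sorted(obj, key=str):
            _flatten(f"{prefix}.{k}" if prefix else str(k), obj[k], out)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, out)
    else:
        out[prefix] = obj


def write_report(data, path, format: str = "json", seed: Optional[int] = None) -> None:
    """Write an analysis report with a versioned schema.

    ``data`` is a dict or an object with ``to_dict``.  JSON reports embed
    the payload under ``data``; CSV reports are flattened key,value rows.
    Both carry the tool version and the run seed for provenance.
    """
    payload = data.to_dict() if hasattr(data, "to_dict") else dict(data)
    header = {
        "schema_version": 1,
        "tool": "microtem",
        "tool_version": __version__,
        "seed": seed,
    }
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({**header, "data": payload}, fh, indent=1, sort_keys=True, default=_json_default)
    elif format == "csv":
        flat: Dict[str, object] = {}
        _flatten("", {**header, **payload}, flat)
        pd.DataFrame(
            {"key": list(flat.keys()), "value": [flat[k] for k in flat]}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj).__name__}")
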