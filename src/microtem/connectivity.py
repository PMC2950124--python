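"""Polyadic synapse graph, network motifs, and envelope-overlap analysis.

Insect synapses are polyadic: a single presynaptic site (marked by a T-bar)
contacts several postsynaptic elements at once, with a pre:post ratio mostly
between three and five.  The contact structure of a microvolume is captured
as a directed multigraph with one edge per (synapse, postsynaptic-site)
contact.  Two motifs dominate such microvolumes: the *dense overlapping
regulon* (an axon diverging onto many dendrites, each dendrite converging
input from several axons) and the rarer *feed-forward* triad (B→A, B→C,
A→C).  Spatial proximity is analysed through axis-aligned neurite envelopes
and the frequency of synaptic contact as a function of envelope overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .morphometry import NeuriteSegment, SynapseAnnotation

__all__ = [
    "MotifInstance",
    "EnvelopeOverlapTable",
    "build_graph",
    "polyadic_stats",
    "detect_feed_forward",
    "detect_dor",
    "envelope",
    "overlap_fraction",
    "contact_frequency_by_overlap",
]


@dataclass
class MotifInstance:
    """One detected network motif.

    For ``feed_forward`` the members are the ordered triple (B, A, C) with
    edges B→A, B→C, A→C.  For ``dense_overlapping_regulon`` the instance
    records the primary axon, its dendrite targets, and the secondary axons
    innervating those dendrites.
    """

    motif_kind: str
    members: Tuple[str, ...] = ()
    primary_axon: Optional[str] = None
    dendrites: Tuple[str, ...] = ()
    secondary_axons: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {"motif_kind": self.motif_kind}
        if self.motif_kind == "feed_forward":
            d["members"] = list(self.members)
        else:
            d["primary_axon"] = self.primary_axon
            d["dendrites"] = list(self.dendrites)
            d["secondary_axons"] = list(self.secondary_axons)
        return d


def build_graph(synapses: Sequence[SynapseAnnotation],
                segment_ids: Optional[Sequence[str]] = None) -> nx.MultiDiGraph:
    """Directed multigraph of pre→post contacts.

    One edge per postsynaptic contact, annotated with its synapse id.  Node
    attributes ``has_pre`` / ``has_post`` record the synaptic roles.  When
    ``segment_ids`` is given, references outside it raise; all listed
    segments appear as nodes (possibly isolated).
    """
    g = nx.MultiDiGraph()
    known = set(segment_ids) if segment_ids is not None else None
    if segment_ids is not None:
        for s in segment_ids:
            g.add_node(s, has_pre=False, has_post=False)
    for syn in synapses:
        pre = syn.presynaptic[0]
        refs = [pre] + [p[0] for p in syn.postsynaptic]
        if known is not None:
            dangling = [r for r in refs if r not in known]
            if dangling:
                raise ValueError(
                    f"synapse {syn.synapse_id!r} references unknown segments {dangling}"
                )
        for r in refs:
            if r not in g:
                g.add_node(r, has_pre=False, has_post=False)
        g.nodes[pre]["has_pre"] = True
        for post_id, _ in syn.postsynaptic:
            g.nodes[post_id]["has_post"] = True
            g.add_edge(pre, post_id, synapse_id=syn.synapse_id)
    return g


def polyadic_stats(synapses: Sequence[SynapseAnnotation]) -> dict:
    """Fan-out statistics of polyadic synapses.

    Returns the mean number of postsynaptic contacts per presynaptic site,
    the aggregate post:pre ratio (total contacts / total sites), and the
    fan-out distribution.  Empty input yields NaN means and an empty
    distribution.
    """
    if not synapses:
        return {
            "mean_posts_per_presite": float("nan"),
            "post_to_pre_ratio": float("nan"),
            "n_presynaptic_sites": 0,
            "n_postsynaptic_contacts": 0,
            "fanout_distribution": {},
        }
    fanouts = [len(s.postsynaptic) for s in synapses]
    dist: Dict[int, int] = {}
    for f in fanouts:
        dist[f] = dist.get(f, 0) + 1
    total_post = sum(fanouts)
    return {
        "mean_posts_per_presite": float(np.mean(fanouts)),
        "post_to_pre_ratio": total_post / len(synapses),
        "n_presynaptic_sites": len(synapses),
        "n_postsynaptic_contacts": total_post,
        "fanout_distribution": dict(sorted(dist.items())),
    }


def detect_feed_forward(graph: nx.MultiDiGraph) -> List[MotifInstance]:
    """All feed-forward triads (B, A, C): edges B→A, B→C and A→C.

    Members are distinct; parallel edges count once.  Output is sorted by
    (B, A, C) for deterministic ordering.
    """
    simple = nx.DiGraph(graph)
    out: List[MotifInstance] = []
    for b in simple.nodes:
        succ_b = set(simple.successors(b)) - {b}
        for a in succ_b:
            for c in set(simple.successors(a)) - {a}:
                if c in succ_b and c != b:
                    out.append(MotifInstance("feed_forward", members=(str(b), str(a), str(c))))
    out.sort(key=lambda m: m.members)
    return out


def detect_dor(
    graph: nx.MultiDiGraph,
    min_targets: int = 2,
    min_shared_inputs: int = 2,
) -> List[MotifInstance]:
    """Dense-overlapping-regulon instances.

    For each axon ``a`` with out-neighborhood D(a) of size >= ``min_targets``
    an instance is emitted when at least half the targets receive input from
    >= ``min_shared_inputs`` distinct axons.  The instance records the
    primary axon, its targets, and all secondary axons innervating them.
    """
    simple = nx.DiGraph(graph)
    out: List[MotifInstance] = []
    for a in sorted(simple.nodes, key=str):
        targets = sorted((set(simple.successors(a)) - {a}), key=str)
        if len(targets) < min_targets:
            continue
        shared = sum(
            1 for d in targets if len(set(simple.predecessors(d)) - {d}) >= min_shared_inputs
        )
        if 2 * shared >= len(targets):
            secondary = sorted(
                {p for d in targets for p in simple.predecessors(d) if p not in (a, d)},
                key=str,
            )
            out.append(
                MotifInstance(
                    "dense_overlapping_regulon",
                    primary_axon=str(a),
                    dendrites=tuple(str(d) for d in targets),
                    secondary_axons=tuple(str(s) for s in secondary),
                )
            )
    return out


def envelope(segment: NeuriteSegment) -> np.ndarray:
    """Axis-aligned bounding box inflated by per-point radii.

    Returns a (2, 3) array ``[[xmin, ymin, zmin], [xmax, ymax, zmax]]``.
    """
    pts = segment.centerline
    r = segment.radii[:, None]
    lo = np.min(pts - r, axis=0)
    hi = np.max(pts + r, axis=0)
    return np.stack([lo, hi])


def overlap_fraction(env_axon: np.ndarray, env_dendrite: np.ndarray) -> float:
    """Fraction of the axon envelope volume shared with the dendrite envelope.

    NaN (missing) for a zero-volume axon envelope.
    """
    a = np.asarray(env_axon, dtype=float)
    b = np.asarray(env_dendrite, dtype=float)
    va = float(np.prod(np.maximum(a[1] - a[0], 0.0)))
    if va == 0.0:
        return float("nan")
    inter = np.maximum(np.minimum(a[1], b[1]) - np.maximum(a[0], b[0]), 0.0)
    return float(np.prod(inter)) / va


@dataclass
class EnvelopeOverlapTable:
    """Contact frequency stratified by envelope-overlap fraction."""

    bin_edges: Tuple[float, ...]  # interior edges, e.g. (0.10, 0.50)
    n_pairs: List[int] = field(default_factory=list)
    n_contacted: List[int] = field(default_factory=list)

    @property
    def frequencies(self) -> List[float]:
        return [
            c / n if n else float("nan") for c, n in zip(self.n_contacted, self.n_pairs)
        ]

    @property
    def bin_labels(self) -> List[str]:
        edges = [0.0, *self.bin_edges, 1.0]
        return [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]

    def to_dict(self) -> dict:
        return {
            "bin_edges": list(self.bin_edges),
            "bin_labels": self.bin_labels,
            "n_pairs": list(self.n_pairs),
            "n_contacted": list(self.n_contacted),
            "frequencies": self.frequencies,
        }


def contact_frequency_by_overlap(
    graph: nx.MultiDiGraph,
    segments: Sequence[NeuriteSegment],
    bin_edges: Sequence[float] = (0.10, 0.50),
) -> EnvelopeOverlapTable:
    """Frequency of synaptic contact as a function of envelope overlap.

    The pair universe is (presynaptic-capable segment) × (dendritiform
    segment); presynaptic-capable means class varicose/globular/axiform.
    Each pair falls in the overlap bin given by
    :func:`overlap_fraction` (interior edges ``bin_edges``, half-open bins,
    the last bin closed at 1); per-bin frequency is contacted pairs over
    total pairs.
    """
    edges = tuple(sorted(bin_edges))
    n_bins = len(edges) + 1
    table = EnvelopeOverlapTable(edges, [0] * n_bins, [0] * n_bins)
    axons = [s for s in segments if s.class_label in ("varicose", "globular", "axiform")]
    dendrites = [s for s in segments if s.class_label == "dendritiform"]
    contacted = {(u, v) for u, v in graph.edges()} if graph.number_of_edges() else set()
    for a in axons:
        env_a = envelope(a)
        for d in dendrites:
            frac = overlap_fraction(env_a, envelope(d))
            if np.isnan(frac):
                continue
            k = int(np.searchsorted(edges, frac, side="right"))
            table.n_pairs[k] += 1
            if (a.segment_id, d.segment_id) in contacted:
                table.n_contacted[k] += 1
    return table
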