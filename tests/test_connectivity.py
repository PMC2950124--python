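import itertools

import networkx as nx
import numpy as np
import pytest

from microtem import connectivity as cn
from microtem.morphometry import NeuriteSegment, SynapseAnnotation


def _syn(sid, pre, posts):
    return SynapseAnnotation(sid, (pre, 0), [(p, 0) for p in posts])


def _random_graph(rng, n_nodes, p):
    g = nx.MultiDiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


class TestBuildGraph:
    def test_triadic_synapse_gives_three_edges(self):
        g = cn.build_graph([_syn("s", "pre", ["d1", "d2", "d3"])])
        assert g.number_of_edges() == 3
        assert g.nodes["pre"]["has_pre"] and g.nodes["d1"]["has_post"]

    def test_empty_input_empty_graph(self):
        g = cn.build_graph([])
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_edge_count_equals_total_postsynaptic_contacts(self, rng):
        syns = [
            _syn(f"s{k}", f"pre{rng.integers(0, 5)}",
                 [f"d{rng.integers(0, 10)}" for _ in range(int(rng.integers(1, 6)))])
            for k in range(30)
        ]
        g = cn.build_graph(syns)
        assert g.number_of_edges() == sum(len(s.postsynaptic) for s in syns)

    def test_dangling_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cn.build_graph([_syn("s", "pre", ["d"])], segment_ids=["pre"])


class TestPolyadicStats:
    def test_monadic_synapse_mean_one(self):
        assert cn.polyadic_stats([_syn("s", "a", ["b"])])["mean_posts_per_presite"] == 1.0

    def test_vnc_totals_aggregate_ratio(self, vnc):
        stats = cn.polyadic_stats(vnc.synapses)
        assert stats["n_presynaptic_sites"] == 68
        assert stats["n_postsynaptic_contacts"] == 256
        assert stats["post_to_pre_ratio"] == pytest.approx(256 / 68)
        assert round(stats["post_to_pre_ratio"]) == 4

    def test_matches_brute_force_averaging(self, rng):
        syns = [
            _syn(f"s{k}", "p", [f"d{i}" for i in range(int(rng.integers(1, 8)))])
            for k in range(25)
        ]
        stats = cn.polyadic_stats(syns)
        fanouts = [len(s.postsynaptic) for s in syns]
        assert stats["mean_posts_per_presite"] == pytest.approx(sum(fanouts) / len(fanouts))
        assert stats["post_to_pre_ratio"] == pytest.approx(sum(fanouts) / len(syns))

    def test_empty_input_missing_values(self):
        stats = cn.polyadic_stats([])
        assert np.isnan(stats["mean_posts_per_presite"])


def _ff_oracle(g):
    simple = nx.DiGraph(g)
    out = []
    for b, a, c in itertools.permutations(simple.nodes, 3):
        if simple.has_edge(b, a) and simple.has_edge(b, c) and simple.has_edge(a, c):
            out.append((str(b), str(a), str(c)))
    return sorted(out)


def _dor_oracle(g, min_targets=2, min_shared=2):
    simple = nx.DiGraph(g)
    out = []
    for a in simple.nodes:
        targets = set(simple.successors(a)) - {a}
        if len(targets) < min_targets:
            continue
        n_ok = sum(
            1 for d in targets if len(set(simple.predecessors(d)) - {d}) >= min_shared
        )
        if 2 * n_ok >= len(targets):
            out.append(str(a))
    return sorted(out)


class TestMotifs:
    def test_single_feed_forward_triad(self):
        g = nx.MultiDiGraph([("B", "A"), ("B", "C"), ("A", "C")])
        inst = cn.detect_feed_forward(g)
        assert len(inst) == 1 and inst[0].members == ("B", "A", "C")

    def test_no_shared_targets_no_feed_forward(self):
        g = nx.MultiDiGraph([("a", "b"), ("c", "d"), ("e", "f")])
        assert cn.detect_feed_forward(g) == []

    def test_feed_forward_matches_exhaustive_enumeration(self, rng):
        for trial in range(100):
            g = _random_graph(rng, int(rng.integers(3, 31)), 0.15)
            assert sorted(m.members for m in cn.detect_feed_forward(g)) == _ff_oracle(g)

    def test_reference_dor_instance(self):
        # one primary axon onto 12 dendrites; 7 secondary axons also
        # innervate them so every dendrite has >= 2 inputs
        g = nx.MultiDiGraph()
        dendrites = [f"d{i}" for i in range(12)]
        for d in dendrites:
            g.add_edge("primary", d)
        for k in range(7):
            for i in range(k, 12, 7):
                g.add_edge(f"sec{k}", dendrites[i])
        # ensure every dendrite has at least two presynaptic partners
        for i, d in enumerate(dendrites):
            g.add_edge(f"sec{i % 7}", d)
        inst = [m for m in cn.detect_dor(g) if m.primary_axon == "primary"]
        assert len(inst) == 1
        assert len(inst[0].dendrites) == 12
        assert len(inst[0].secondary_axons) == 7

    def test_star_without_convergence_is_not_dor(self):
        g = nx.MultiDiGraph([("a", f"d{i}") for i in range(5)])
        assert cn.detect_dor(g) == []

    def test_dor_matches_brute_force_rule(self, rng):
        for trial in range(100):
            g = _random_graph(rng, int(rng.integers(3, 31)), 0.2)
            got = sorted(m.primary_axon for m in cn.detect_dor(g))
            assert got == _dor_oracle(g)


class TestEnvelopes:
    def test_single_point_envelope(self):
        seg = NeuriteSegment("s", [[0.0, 0.0, 0.0]], [0.5])
        assert np.allclose(cn.envelope(seg), [[-0.5, -0.5, -0.5], [0.5, 0.5, 0.5]])

    def test_straight_segment_extent(self):
        seg = NeuriteSegment("s", [[0, 0, 0], [2.0, 0, 0]], [0.1, 0.1])
        assert np.allclose(cn.envelope(seg), [[-0.1, -0.1, -0.1], [2.1, 0.1, 0.1]])

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            pts = rng.uniform(-5, 5, (n, 3))
            r = rng.uniform(0.05, 1.0, n)
            env = cn.envelope(NeuriteSegment("s", pts, r))
            lo = np.min([p - ri for p, ri in zip(pts, r)], axis=0)
            hi = np.max([p + ri for p, ri in zip(pts, r)], axis=0)
            assert np.allclose(env, [lo, hi])

    def test_overlap_fraction_analytic_cases(self):
        unit = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        assert cn.overlap_fraction(unit, unit) == 1.0
        far = unit + 5.0
        assert cn.overlap_fraction(unit, far) == 0.0
        half = unit + np.array([0.5, 0.0, 0.0])
        assert cn.overlap_fraction(unit, half) == pytest.approx(0.5)

    def test_overlap_monotone_in_dendrite_growth(self):
        a = np.array([[0.0, 0, 0], [2.0, 2, 2]])
        prev = 0.0
        for grow in (0.5, 1.0, 2.0, 4.0):
            b = np.array([[1.0, 1, 1], [1.0 + grow, 1 + grow, 1 + grow]])
            frac = cn.overlap_fraction(a, b)
            assert frac >= prev
            prev = frac

    def test_zero_volume_axon_is_missing(self):
        degenerate = np.array([[0.0, 0, 0], [0.0, 1, 1]])
        assert np.isnan(cn.overlap_fraction(degenerate, degenerate))


def _table_oracle(graph, segments, edges):
    axons = [s for s in segments if s.class_label in ("varicose", "globular", "axiform")]
    dens = [s for s in segments if s.class_label == "dendritiform"]
    contacted = {(u, v) for u, v in graph.edges()}
    n = [0] * (len(edges) + 1)
    c = [0] * (len(edges) + 1)
    for a in axons:
        for d in dens:
            f = cn.overlap_fraction(cn.envelope(a), cn.envelope(d))
            if np.isnan(f):
                continue
            k = sum(f >= e for e in edges)
            n[k] += 1
            c[k] += (a.segment_id, d.segment_id) in contacted
    return n, c


class TestContactFrequencyByOverlap:
    def _segments(self, rng, n_axons, n_dens):
        segs = []
        for i in range(n_axons):
            p0 = rng.uniform(0, 8, 3)
            segs.append(NeuriteSegment(f"a{i}", [p0, p0 + [2, 0, 0]], [0.3, 0.3],
                                       class_label="varicose"))
        for i in range(n_dens):
            p0 = rng.uniform(0, 8, 3)
            segs.append(NeuriteSegment(f"d{i}", [p0, p0 + rng.uniform(0.5, 2, 3)],
                                       [0.08, 0.08], class_label="dendritiform"))
        return segs

    def test_all_pairs_connected_gives_frequency_one(self, rng):
        segs = self._segments(rng, 2, 3)
        syns = [
            _syn(f"s{i}{j}", f"a{i}", [f"d{j}"]) for i in range(2) for j in range(3)
        ]
        table = cn.contact_frequency_by_overlap(cn.build_graph(syns), segs)
        for f, n in zip(table.frequencies, table.n_pairs):
            if n:
                assert f == 1.0

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(10):
            segs = self._segments(rng, 4, 8)
            syns = []
            k = 0
            for i in range(4):
                for j in range(8):
                    if rng.random() < 0.3:
                        syns.append(_syn(f"s{k}", f"a{i}", [f"d{j}"]))
                        k += 1
            g = cn.build_graph(syns)
            table = cn.contact_frequency_by_overlap(g, segs)
            n, c = _table_oracle(g, segs, table.bin_edges)
            assert table.n_pairs == n and table.n_contacted == c

    def test_frequency_nondecreasing_when_contact_prob_grows_with_overlap(self, rng):
        # generator in which the chance of contact rises with envelope overlap
        segs = self._segments(rng, 10, 50)
        axons = [s for s in segs if s.segment_id.startswith("a")]
        dens = [s for s in segs if s.segment_id.startswith("d")]
        syns = []
        k = 0
        for a in axons:
            for d in dens:
                f = cn.overlap_fraction(cn.envelope(a), cn.envelope(d))
                if rng.random() < 0.1 + 0.85 * f:
                    syns.append(_syn(f"s{k}", a.segment_id, [d.segment_id]))
                    k += 1
        table = cn.contact_frequency_by_overlap(cn.build_graph(syns), segs)
        freqs = [f for f, n in zip(table.frequencies, table.n_pairs) if n >= 5]
        assert all(b >= a - 1e-12 for a, b in zip(freqs, freqs[1:]))

    def test_empty_universe_empty_table(self):
        table = cn.contact_frequency_by_overlap(nx.MultiDiGraph(), [])
        assert sum(table.n_pairs) == 0


class TestEdgeConservationOnFixture:
    def test_edges_equal_postsynaptic_contacts(self, vnc):
        g = cn.build_graph(vnc.synapses)
        assert g.number_of_edges() == sum(len(s.postsynaptic) for s in vnc.synapses)
        assert g.number_of_edges() == 256

    def test_feed_forward_requires_dual_role_segments(self, vnc):
        # presynaptic hosts are varicose/globular, postsynaptic targets are
        # dendritiform; with disjoint roles no feed-forward triads can exist
        g = cn.build_graph(vnc.synapses)
        assert cn.detect_feed_forward(g) == []
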