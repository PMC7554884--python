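from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waternet._util import random_rotation
from waternet.structures_io import Frame, TIP3PParams
from waternet.water_networks import (
    FrameAnalysisError,
    HBondGraph,
    SingularGeometryError,
    WaterRing,
    analyze_frames,
    build_hbond_graph,
    enumerate_rings,
    pair_energy,
    ring_center_of_mass,
)

from _oracles import (
    canonical_cycle,
    center_of_mass_oracle,
    chordless_cycles_oracle,
    pair_energy_oracle,
)
from conftest import ideal_hbond_dimer, make_water, random_water


def graph_from_edges(edges) -> HBondGraph:
    nodes = sorted({n for e in edges for n in e})
    return HBondGraph(
        nodes=nodes,
        edges={tuple(sorted(e)): -3.0 for e in edges},
    )


class TestPairEnergy:
    def test_long_range_decay(self):
        a = make_water(0, [0, 0, 0], [1, 0, 0], [0, 1, 0])
        b = make_water(1, [50, 0, 0], [1, 0, 0], [0, 1, 0])
        assert abs(pair_energy(a, b)) < 0.05

    def test_ideal_dimer_matches_oracle_and_criterion(self):
        donor, acceptor = ideal_hbond_dimer()
        e = pair_energy(donor, acceptor)
        oracle = pair_energy_oracle(donor.positions, acceptor.positions)
        assert e == pytest.approx(oracle, abs=1e-9)
        assert e <= -2.25

    def test_oracle_agreement_on_random_geometries(self, rng):
        for trial in range(100):
            a = random_water(0, rng, span=8.0)
            b = random_water(1, rng, span=8.0)
            if np.linalg.norm(a.oxygen.position - b.oxygen.position) < 1.0:
                continue  # avoid near-singular geometries, tested separately
            assert pair_energy(a, b) == pytest.approx(
                pair_energy_oracle(a.positions, b.positions), abs=1e-9
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = random_water(0, rng)
        b = random_water(1, rng)
        if np.linalg.norm(a.oxygen.position - b.oxygen.position) < 1.0:
            return
        assert pair_energy(a, b) == pytest.approx(
            pair_energy(b, a), abs=1e-12, rel=1e-12
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = random_water(0, rng)
        b = random_water(1, rng)
        if np.linalg.norm(a.oxygen.position - b.oxygen.position) < 2.0:
            return  # sub-contact separations amplify r^-12 rounding error
        e0 = pair_energy(a, b)
        rot = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)

        def moved(w):
            p = w.positions @ rot.T + t
            return make_water(w.index, p[0], p[1] - p[0], p[2] - p[0])

        assert pair_energy(moved(a), moved(b)) == pytest.approx(
            e0, abs=1e-9, rel=1e-9
        )

    def test_coincident_sites_raise(self):
        a = make_water(0, [0, 0, 0], [1, 0, 0], [0, 1, 0])
        b = make_water(1, [0, 0, 0], [1, 0, 0], [0, 1, 0])
        with pytest.raises(SingularGeometryError):
            pair_energy(a, b)

    def test_nonstandard_params_change_energy(self):
        donor, acceptor = ideal_hbond_dimer()
        default = pair_energy(donor, acceptor)
        doubled = pair_energy(donor, acceptor, TIP3PParams(A=2 * 582000.0))
        assert doubled > default


class TestBuildGraph:
    def test_single_water(self):
        frame = Frame(waters=[make_water(0, [1, 1, 1], [1, 0, 0], [0, 1, 0])])
        g = build_hbond_graph(frame)
        assert g.nodes == [0]
        assert g.n_edges == 0

    def test_ideal_dimer_one_edge(self):
        donor, acceptor = ideal_hbond_dimer()
        g = build_hbond_graph(Frame(waters=[donor, acceptor]))
        assert set(g.edges) == {(0, 1)}
        assert g.edges[(0, 1)] <= -2.25

    def test_distant_pair_no_edge(self):
        a = make_water(0, [0, 0, 0], [1, 0, 0], [0, 1, 0])
        b = make_water(1, [6, 0, 0], [1, 0, 0], [0, 1, 0])
        g = build_hbond_graph(Frame(waters=[a, b]))
        assert g.n_edges == 0

    def test_minimum_image_without_box_raises(self):
        frame = Frame(waters=[make_water(0, [0, 0, 0], [1, 0, 0], [0, 1, 0])])
        with pytest.raises(ValueError, match="box"):
            build_hbond_graph(frame, minimum_image=True)

    def test_minimum_image_finds_cross_boundary_bond(self):
        # donor near the +x face bonded to the acceptor's periodic image
        donor, acceptor = ideal_hbond_dimer()
        shift = np.array([28.0, 5.0, 5.0])
        d = donor.positions + shift
        a = acceptor.positions + shift - np.array([30.0, 0.0, 0.0])
        w0 = make_water(0, d[0], d[1] - d[0], d[2] - d[0])
        w1 = make_water(1, a[0], a[1] - a[0], a[2] - a[0])
        frame = Frame(waters=[w0, w1], box=[30.0, 30.0, 30.0])
        assert build_hbond_graph(frame, minimum_image=False).n_edges == 0
        g = build_hbond_graph(frame, minimum_image=True)
        assert set(g.edges) == {(0, 1)}
        assert g.edges[(0, 1)] == pytest.approx(
            pair_energy(donor, acceptor), abs=1e-9
        )

    def test_criterion_monotonicity(self, planted_frames):
        frame = planted_frames[0]
        loose = TIP3PParams(hbond_energy_criterion=-0.5)
        strict = TIP3PParams(hbond_energy_criterion=-4.0)
        edges_strict = set(build_hbond_graph(frame, strict).edges)
        edges_default = set(build_hbond_graph(frame).edges)
        edges_loose = set(build_hbond_graph(frame, loose).edges)
        assert edges_strict <= edges_default <= edges_loose
        n_strict = len(enumerate_rings(build_hbond_graph(frame, strict)))
        n_loose = len(enumerate_rings(build_hbond_graph(frame, loose)))
        assert n_strict <= n_loose

    def test_invalid_cutoff(self, planted_frames):
        with pytest.raises(ValueError, match="cutoff"):
            build_hbond_graph(planted_frames[0], cutoff=0.0)


class TestEnumerateRings:
    def test_triangle(self):
        g = graph_from_edges([(0, 1), (1, 2), (0, 2)])
        rings = enumerate_rings(g)
        assert [r.members for r in rings] == [(0, 1, 2)]
        assert rings[0].ring_class == "R3"

    def test_path_graph_has_no_rings(self):
        g = graph_from_edges([(0, 1), (1, 2), (2, 3)])
        assert enumerate_rings(g) == []

    @pytest.mark.parametrize("chord,expected_classes", [
        ((0, 2), ["R3", "R5"]),
        ((0, 3), ["R4", "R4"]),
    ])
    def test_chorded_hexagon_splits(self, chord, expected_classes):
        hexagon = [(i, (i + 1) % 6) for i in range(6)]
        g = graph_from_edges(hexagon + [chord])
        rings = enumerate_rings(g)
        assert sorted(r.ring_class for r in rings) == sorted(expected_classes)
        assert all(len(r.members) < 6 for r in rings)
        oracle = chordless_cycles_oracle(hexagon + [chord])
        assert {r.members for r in rings} == oracle

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.15, 0.5))
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < p
            ]
            g = graph_from_edges(edges) if edges else HBondGraph(nodes=list(range(n)), edges={})
            assert {r.members for r in enumerate_rings(g)} == chordless_cycles_oracle(edges)

    def test_canonical_form(self):
        g = graph_from_edges([(5, 9), (9, 2), (2, 5)])
        (ring,) = enumerate_rings(g)
        assert ring.members == canonical_cycle([5, 9, 2])
        assert ring.members[0] == min(ring.members)
        assert ring.members[1] < ring.members[-1]

    def test_empty_graph(self):
        assert enumerate_rings(HBondGraph(nodes=[], edges={})) == []

    def test_size_bounds_validated(self):
        g = graph_from_edges([(0, 1)])
        with pytest.raises(ValueError):
            enumerate_rings(g, min_size=2)
        with pytest.raises(ValueError):
            enumerate_rings(g, max_size=7)


class TestRingCOM:
    def test_square_of_identical_waters_symmetric(self):
        waters = [
            make_water(i, pos, [1, 0, 0], [0, 1, 0])
            for i, pos in enumerate([[0, 0, 0], [4, 0, 0], [4, 4, 0], [0, 4, 0]])
        ]
        frame = Frame(waters=waters)
        ring = WaterRing(members=(0, 1, 2, 3))
        com = ring_center_of_mass(ring, frame)
        # identical orientations: COM = O centroid + the one-water mass offset
        w = waters[0]
        masses = np.array([a.mass for a in w.atoms])
        offset = (
            (w.positions - w.oxygen.position) * masses[:, None]
        ).sum(axis=0) / masses.sum()
        assert np.allclose(com, np.array([2.0, 2.0, 0.0]) + offset, atol=1e-12)
        assert np.linalg.norm(offset) < 0.5  # H mass is small

    def test_translation_equivariance(self, rng):
        waters = [random_water(i, rng) for i in range(5)]
        ring = WaterRing(members=(0, 1, 2, 3, 4))
        com0 = ring_center_of_mass(ring, Frame(waters=waters))
        t = np.array([3.0, -2.0, 7.5])
        moved = []
        for w in waters:
            p = w.positions + t
            moved.append(make_water(w.index, p[0], p[1] - p[0], p[2] - p[0]))
        com1 = ring_center_of_mass(ring, Frame(waters=moved))
        assert np.allclose(com1, com0 + t, atol=1e-9)

    def test_r5_matches_direct_sum_oracle(self, rng):
        waters = [random_water(i, rng) for i in range(5)]
        frame = Frame(waters=waters)
        ring = WaterRing(members=(0, 1, 2, 3, 4))
        positions = [a.position for w in waters for a in w.atoms]
        masses = [a.mass for w in waters for a in w.atoms]
        assert np.allclose(
            ring_center_of_mass(ring, frame),
            center_of_mass_oracle(positions, masses),
            atol=1e-12,
        )

    def test_missing_member_raises(self, rng):
        waters = [random_water(i, rng) for i in range(3)]
        ring = WaterRing(members=(0, 1, 7))
        with pytest.raises(KeyError, match="7"):
            ring_center_of_mass(ring, Frame(waters=waters))

    def test_oxygen_mode(self, rng):
        waters = [random_water(i, rng) for i in range(3)]
        frame = Frame(waters=waters)
        ring = WaterRing(members=(0, 1, 2))
        com_o = ring_center_of_mass(ring, frame, com_mode="oxygen")
        centroid = np.mean([w.oxygen.position for w in waters], axis=0)
        assert np.allclose(com_o, centroid)
        with pytest.raises(ValueError, match="com_mode"):
            ring_center_of_mass(ring, frame, com_mode="bogus")


class TestAnalyzeFrames:
    def test_planted_truth_recovery(self, planted_frames):
        rings = analyze_frames(planted_frames)
        assert len(rings) == 30
        assert Counter(r.ring_class for r in rings) == {"R3": 20, "R6": 10}
        assert all(r.center_of_mass is not None for r in rings)

    def test_per_frame_tagging(self, planted_frames):
        rings = analyze_frames(planted_frames)
        per_frame = Counter(r.frame_id for r in rings)
        assert per_frame == {fid: 3 for fid in range(1, 11)}

    def test_empty_frames_empty_result(self):
        frames = [Frame(waters=[], frame_id=i) for i in (1, 2)]
        assert analyze_frames(frames) == []

    def test_no_frames_rejected(self):
        with pytest.raises(ValueError):
            analyze_frames([])

    def test_error_carries_frame_id(self):
        good = Frame(waters=[], frame_id=1, box=[30.0, 30.0, 30.0])
        bad = Frame(waters=[], frame_id=2, box=None)
        with pytest.raises(FrameAnalysisError, match="frame 2"):
            analyze_frames([good, bad], minimum_image=True)

    def test_determinism_under_water_reordering(self, planted_frames):
        frame = planted_frames[0]
        shuffled = Frame(
            waters=list(reversed(frame.waters)),
            box=frame.box,
            frame_id=frame.frame_id,
        )
        r1 = {r.members for r in analyze_frames([frame])}
        r2 = {r.members for r in analyze_frames([shuffled])}
        assert r1 == r2


class TestGraphType:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            HBondGraph(nodes=[0], edges={(0, 0): -3.0})

    def test_unsorted_edge_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            HBondGraph(nodes=[0, 1], edges={(1, 0): -3.0})

    def test_ring_size_validated(self):
        with pytest.raises(ValueError):
            WaterRing(members=(0, 1))
        with pytest.raises(ValueError):
            WaterRing(members=(0, 1, 2, 3, 4, 5, 6))
        with pytest.raises(ValueError, match="distinct"):
            WaterRing(members=(0, 1, 1))
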