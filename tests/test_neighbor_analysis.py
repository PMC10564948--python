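import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from nucleofiber.neighbor_analysis import (
    ANGLE_BIN_PRESETS,
    DISTANCE_BIN_PRESETS,
    NeighborPair,
    StackGate,
    deduplicate,
    detect_motifs,
    nearest_neighbors,
    run_pipeline,
    select_subpopulation,
    summarize,
)
from nucleofiber.particle_io import ParticleSet

from conftest import make_set, random_set


def brute_force_nn(pset):
    """O(n^2) all-pairs oracle for directed nearest neighbours."""
    out = {}
    for tomo, idx in pset.by_tomogram().items():
        if len(idx) < 2:
            continue
        D = cdist(pset.centers[idx], pset.centers[idx])
        np.fill_diagonal(D, np.inf)
        for k, row in enumerate(D):
            j = int(np.argmin(row))
            out[int(pset.particle_ids[idx[k]])] = (int(pset.particle_ids[idx[j]]), float(row[j]))
    return out


def brute_force_dedup(centers, threshold):
    """Enumerate the documented greedy removal (ascending id) explicitly."""
    kept = []
    removed = []
    for i, c in enumerate(centers):
        if any(np.linalg.norm(np.asarray(c) - np.asarray(centers[k])) < threshold for k in kept):
            removed.append(i)
        else:
            kept.append(i)
    return kept, removed


class TestDeduplicate:
    def test_pair_below_threshold_drops_higher_id(self):
        pset = make_set([(0, 0, 0), (59, 0, 0)])
        retained, removed = deduplicate(pset, 60.0)
        assert list(retained.particle_ids) == [0]
        assert removed == [1]

    def test_pair_at_threshold_both_survive(self):
        pset = make_set([(0, 0, 0), (60, 0, 0)])
        retained, removed = deduplicate(pset, 60.0)
        assert len(retained) == 2 and removed == []

    def test_chain_keeps_ends(self):
        """0-55-110 Å: greedy ascending-id removal drops only the middle."""
        centers = [(0, 0, 0), (55, 0, 0), (110, 0, 0)]
        retained, removed = deduplicate(make_set(centers), 60.0)
        kept_oracle, removed_oracle = brute_force_dedup(centers, 60.0)
        assert list(retained.particle_ids) == kept_oracle == [0, 2]
        assert removed == removed_oracle == [1]

    def test_matches_greedy_oracle_on_random_scenes(self, rng):
        for _ in range(5):
            centers = rng.random((60, 3)) * 300
            retained, removed = deduplicate(make_set(centers), 60.0)
            kept_oracle, removed_oracle = brute_force_dedup(centers, 60.0)
            assert list(retained.particle_ids) == kept_oracle
            assert removed == removed_oracle

    def test_idempotent(self, rng):
        pset = make_set(rng.random((100, 3)) * 400)
        once, removed1 = deduplicate(pset, 60.0)
        twice, removed2 = deduplicate(once, 60.0)
        assert removed2 == []
        assert list(twice.particle_ids) == list(once.particle_ids)

    def test_cross_tomogram_pairs_ignored(self):
        a = make_set([(0, 0, 0)], tomo="a", ids=[0])
        b = make_set([(1, 0, 0)], tomo="b", ids=[1])
        merged = ParticleSet(a.particles() + b.particles())
        retained, removed = deduplicate(merged, 60.0)
        assert len(retained) == 2 and removed == []

    def test_empty_input(self):
        empty = make_set(np.zeros((1, 3))).subset(np.zeros(1, dtype=bool))
        retained, removed = deduplicate(empty)
        assert len(retained) == 0 and removed == []


class TestNearestNeighbors:
    def test_two_particles_symmetric(self):
        pairs = nearest_neighbors(make_set([(0, 0, 0), (100, 0, 0)]))
        assert len(pairs) == 2
        assert {p.distance for p in pairs} == {100.0}

    def test_three_collinear(self):
        pairs = nearest_neighbors(make_set([(0, 0, 0), (100, 0, 0), (250, 0, 0)]))
        neighbor_of = {p.source_id: p.neighbor_id for p in pairs}
        assert neighbor_of == {0: 1, 1: 0, 2: 1}

    def test_matches_brute_force_oracle(self, rng):
        a = random_set(rng, 400, tomo="a")
        rots = Rotation.random(300, rng=rng).as_matrix()
        b = make_set(rng.random((300, 3)) * 2000, list(rots), tomo="b",
                     ids=range(1000, 1300))
        merged = ParticleSet(a.particles() + b.particles())
        pairs = nearest_neighbors(merged)
        oracle = brute_force_nn(merged)
        assert len(pairs) == len(oracle)
        for p in pairs:
            nb, d = oracle[p.source_id]
            assert p.neighbor_id == nb
            assert p.distance == pytest.approx(d, abs=1e-9)

    def test_invariant_under_rigid_motion(self, rng):
        pset = random_set(rng, 150)
        G = Rotation.random(rng=rng).as_matrix()
        t = np.array([500.0, -200.0, 80.0])
        moved = make_set(
            (pset.centers @ G.T) + t, [G @ R for R in pset.rotations]
        )
        p1 = nearest_neighbors(pset)
        p2 = nearest_neighbors(moved)
        for a, b in zip(p1, p2):
            assert a.neighbor_id == b.neighbor_id
            assert a.distance == pytest.approx(b.distance, abs=1e-6)
            assert a.angle == pytest.approx(b.angle, abs=1e-6)

    def test_single_particle_tomogram_contributes_nothing(self):
        pairs = nearest_neighbors(make_set([(0, 0, 0)]))
        assert pairs == []

    def test_mutual_option_restricts(self):
        pairs = nearest_neighbors(make_set([(0, 0, 0), (100, 0, 0), (250, 0, 0)]), mutual=True)
        assert {(p.source_id, p.neighbor_id) for p in pairs} == {(0, 1), (1, 0)}


class TestSummarize:
    def _pairs(self, distances, angles=None):
        angles = angles or [0.0] * len(distances)
        return [NeighborPair(i, i + 1, d, a) for i, (d, a) in enumerate(zip(distances, angles))]

    def test_odd_count_median(self):
        s = summarize(self._pairs([100.0, 120.0, 140.0]))
        assert s.median_distance == pytest.approx(120.0)

    def test_degenerate_angles_in_first_bin(self):
        s = summarize(self._pairs([100.0, 100.0], [0.0, 0.0]))
        edges, counts = s.angle_histogram
        assert counts[0] == 2 and counts[1:].sum() == 0

    def test_histogram_counts_sum_to_pairs(self, rng):
        d = list(rng.random(200) * 300)
        a = list(rng.random(200) * 90)
        s = summarize(self._pairs(d, a))
        assert s.distance_histogram[1].sum() == 200
        assert s.angle_histogram[1].sum() == 200

    def test_count_bookkeeping(self):
        s = summarize(self._pairs([100.0, 110.0]), n_input=10, n_removed_duplicates=3)
        assert s.n_input == s.n_removed_duplicates + s.n_retained == 10

    def test_empty_pairs_raise(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])


class TestSubpopulations:
    def test_half_open_bins(self):
        pairs = [NeighborPair(0, 1, 80.0, 10.0)]
        assert select_subpopulation(pairs, "distance", 60, 80) == set()
        assert select_subpopulation(pairs, "distance", 80, 100) == {0}

    def test_distance_presets_tile_without_overlap(self):
        edges = sorted(DISTANCE_BIN_PRESETS)
        assert edges[0][0] == 60.0 and edges[-1][1] == 120.0
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            assert hi1 == lo2

    def test_angle_presets_union(self, rng):
        pairs = [NeighborPair(i, 0, 100.0, float(a)) for i, a in enumerate(rng.random(100) * 90)]
        union = set()
        for lo, hi in ANGLE_BIN_PRESETS:
            union |= select_subpopulation(pairs, "angle", lo, hi)
        assert union == {p.source_id for p in pairs if p.angle < 60.0}

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            select_subpopulation([], "distance", 80, 80)


class TestMotifs:
    def test_coaxial_pair_is_type_one(self):
        calls = detect_motifs(make_set([(0, 0, 0), (0, 0, 60)]))
        assert [c.motif_class for c in calls] == ["stacked_type_I"]

    def test_lateral_pair_is_type_two(self):
        calls = detect_motifs(make_set([(0, 0, 0), (90, 0, 0)]))
        assert [c.motif_class for c in calls] == ["stacked_type_II"]

    def test_tilted_pair_fails_angle_gate(self):
        R = Rotation.from_euler("x", 40, degrees=True).as_matrix()
        calls = detect_motifs(make_set([(0, 0, 0), (0, 0, 60)], rotations=[np.eye(3), R]))
        assert calls == []

    def test_four_stack_merges_to_tetra(self):
        stack = make_set([(0, 0, z) for z in (0, 60, 120, 180)])
        calls = detect_motifs(stack, extend=True)
        assert [c.motif_class for c in calls] == ["tetra"]
        assert calls[0].member_ids == (0, 1, 2, 3)

    def test_four_stack_without_extension_gives_di_calls(self):
        stack = make_set([(0, 0, z) for z in (0, 60, 120, 180)])
        calls = detect_motifs(stack, extend=False)
        assert [c.motif_class for c in calls] == ["stacked_type_I"] * 3

    def test_five_stack_is_poly(self):
        stack = make_set([(0, 0, z) for z in (0, 60, 120, 180, 240)])
        calls = detect_motifs(stack, extend=True)
        assert [c.motif_class for c in calls] == ["poly"]

    def test_gate_is_configurable(self):
        pair = make_set([(0, 0, 0), (0, 0, 60)])
        assert detect_motifs(pair, StackGate(distance_lo_A=70.0)) == []


class TestEdgeFlagging:
    def test_flags_only_boundary_particles(self):
        from nucleofiber.neighbor_analysis import flag_edge_particles

        pset = make_set([(500, 500, 500), (50, 500, 500), (500, 990, 500)])
        mask = flag_edge_particles(pset, (0, 0, 0), (1000, 1000, 1000), radius=200.0)
        assert list(mask) == [False, True, True]
        census_safe = pset.subset(~mask)
        assert list(census_safe.particle_ids) == [0]


class TestPipeline:
    def test_counts_are_conserved(self, default_scene):
        pset, _ = default_scene
        result = run_pipeline(pset)
        s = result.summary
        assert s.n_input == len(pset)
        assert s.n_input == s.n_removed_duplicates + s.n_retained
        assert s.n_pairs == len(result.pairs)

    def test_retained_set_has_no_close_pairs(self, default_scene):
        pset, _ = default_scene
        result = run_pipeline(pset)
        nn = nearest_neighbors(result.retained)
        assert min(p.distance for p in nn) >= 60.0
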