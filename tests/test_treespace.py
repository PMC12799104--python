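import itertools

import numpy as np
import pytest
from scipy.spatial import procrustes

import treerug as tr
from treerug.treespace import (
    classical_mds,
    distance_matrix,
    landscape_overlay,
    nni_path_tip_relocation,
    path_profile,
    relocate_tip,
    rf_rooted,
    rspr_distance_small,
    topology_classes,
)

from conftest import all_rooted_topologies, make_trace

LETTERS = [chr(65 + i) for i in range(12)]


class TestRfRooted:
    def test_identical_zero(self, quartet):
        assert rf_rooted(quartet, quartet.copy()) == 0

    def test_triplet_distance_two(self):
        t1 = tr.parse_newick("((A:1,B:1):1,C:2);")
        t2 = tr.parse_newick("(A:2,(B:1,C:1):1);", t1.taxon_set)
        assert rf_rooted(t1, t2) == 2

    def test_taxon_mismatch_rejected(self, quartet):
        other = tr.parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError):
            rf_rooted(quartet, other)

    def test_metric_axioms_exhaustive_n5(self):
        csets = [
            tr.parse_newick(nwk).clades()
            for nwk in all_rooted_topologies(list("ABCDE"))
        ]
        m = len(csets)
        d = np.zeros((m, m), dtype=int)
        for i in range(m):
            for j in range(i + 1, m):
                d[i, j] = d[j, i] = len(csets[i] ^ csets[j])
        assert np.all(np.diag(d) == 0)
        assert np.all(d.T == d)
        off = d + np.where(np.eye(m, dtype=bool), 10**6, 0)
        assert off.min() > 0  # identity of indiscernibles
        # triangle inequality over all ordered triples, via broadcasting
        assert np.all(d[:, None, :] <= d[:, :, None] + d[None, :, :])


class TestRelocateTip:
    def test_rf_equals_2k_on_caterpillar(self):
        t = tr.build_caterpillar(LETTERS)
        for k in range(1, 7):
            dest = LETTERS[1 : 2 + k]
            assert rf_rooted(t, relocate_tip(t, "A", dest)) == 2 * k

    def test_relocate_back_restores_topology(self):
        t = tr.build_caterpillar(LETTERS)
        moved = relocate_tip(t, "A", LETTERS[1:4])
        back = relocate_tip(moved, "A", ["B"])
        assert back.clades() == t.clades()

    def test_one_spr_move_by_construction(self):
        t = tr.build_caterpillar(list("ABCDEFG"))
        moved = relocate_tip(t, "A", ["B", "C", "D"])
        assert rspr_distance_small(t, moved) == 1

    def test_noop_and_infeasible_rejected(self):
        t = tr.build_caterpillar(LETTERS)
        with pytest.raises(ValueError, match="no-op"):
            relocate_tip(t, "A", ["B"])
        # A was sampled long before the (C,D) cherry existed: regrafting A
        # onto C's pendant branch is infeasible on the time axis
        t2 = tr.parse_newick("((A:1,B:5):1,(C:1,D:1):5);")
        assert t2.tip("A").height > 1
        with pytest.raises(ValueError, match="infeasible"):
            relocate_tip(t2, "A", ["C"])

    def test_heights_of_untouched_nodes_preserved(self):
        t = tr.build_caterpillar(LETTERS)
        moved = relocate_tip(t, "A", LETTERS[1:3])
        a_bit = 1 << t.taxon_set.index["A"]
        hb = {v: k.height for k, v in t.node_bitsets().items()}
        ha = {v: k.height for k, v in moved.node_bitsets().items()}
        # clades not involving the moved tip keep their heights exactly
        shared = {b for b in set(hb) & set(ha) if not b & a_bit}
        assert shared
        assert all(abs(hb[b] - ha[b]) < 1e-12 for b in shared)


class TestNniPath:
    def test_adjacent_destination_single_move(self):
        t = tr.build_caterpillar(LETTERS)
        path = nni_path_tip_relocation(t, "A", ["B", "C"])
        assert len(path) == 2  # start tree + one move

    def test_six_node_valley(self):
        t = tr.build_caterpillar(LETTERS)
        dest = LETTERS[1:8]
        path = nni_path_tip_relocation(t, "A", dest)
        target = relocate_tip(t, "A", dest)
        assert len(path) - 1 == 6
        assert path[-1].clades() == target.clades()
        for a, b in zip(path, path[1:]):
            assert rf_rooted(a, b) == 2

    def test_lower_bound_proves_minimality(self):
        """Each NNI changes at most 2 clades, so rf/2 = k NNIs is minimal."""
        t = tr.build_caterpillar(LETTERS)
        for k in (2, 4, 6):
            dest = LETTERS[1 : 2 + k]
            path = nni_path_tip_relocation(t, "A", dest)
            rf = rf_rooted(t, path[-1])
            assert len(path) - 1 == rf // 2 == k


class TestRsprSmall:
    def test_identical(self, quartet):
        assert rspr_distance_small(quartet, quartet.copy()) == 0

    def test_constructed_one_move_pairs(self):
        rng = np.random.default_rng(3)
        t = tr.simulate_time_tree(8, Ne=2.0, seed=5)
        bits = t.node_bitsets()
        clades = [
            b for nd, b in bits.items()
            if nd.parent is not None and nd.label != "t0"
        ]
        done = 0
        for b in clades:
            try:
                moved = relocate_tip(t, t.tips()[0].label, b)
            except (ValueError, KeyError):
                continue
            assert rspr_distance_small(t, moved) == 1
            done += 1
            if done >= 4:
                break
        assert done >= 2

    def test_lower_bound_vs_rf(self):
        """One SPR changes at most 2(n-2) clades; rspr >= rf / (2(n-2))."""
        rng = np.random.default_rng(1)
        for i in range(20):
            a = tr.simulate_time_tree(7, Ne=2.0, seed=1000 + i)
            b = tr.simulate_time_tree(
                7, Ne=2.0, seed=2000 + i, labels=a.taxon_set.labels
            )
            rf = rf_rooted(a, b)
            d = rspr_distance_small(a, b)
            assert d >= rf / (2 * (7 - 2))
            assert (d == 0) == (rf == 0)

    def test_large_trees_rejected(self):
        a = tr.simulate_time_tree(12, Ne=2.0, seed=1)
        b = tr.simulate_time_tree(12, Ne=2.0, seed=2, labels=a.taxon_set.labels)
        with pytest.raises(ValueError, match="10 tips"):
            rspr_distance_small(a, b)


class TestTopologyClasses:
    def test_single_topology(self, quartet):
        classes = topology_classes([make_trace([quartet.copy()] * 5)])
        assert len(classes) == 1

    def test_counts_partition_samples(self, stuck_study):
        classes = topology_classes(stuck_study.traces)
        total = sum(c["total"] for c in classes.values())
        assert total == sum(len(t) for t in stuck_study.traces)

    def test_pruning_wobblers_collapses_classes(self, stuck_study):
        assert len(topology_classes(stuck_study.traces)) == 2
        pruned = tr.prune_tips(stuck_study.traces, stuck_study.wobblers)
        assert len(topology_classes(pruned)) == 1


class TestClassicalMds:
    def test_exact_on_euclidean_input(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = tr.DistanceMatrix([("c", i) for i in range(4)], d, "rf")
        emb = classical_mds(dm, dims=2)
        d2 = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1
        )
        assert np.max(np.abs(d2 - d)) < 1e-9
        assert emb.stress < 1e-9

    def test_third_eigenvalue_vanishes_for_planar_input(self):
        pts = np.array([[0, 0], [2, 0], [2, 1], [0, 1], [1, 0.5]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = tr.DistanceMatrix([("c", i) for i in range(5)], d, "rf")
        emb = classical_mds(dm, dims=3)
        assert abs(emb.eigenvalues[2]) < 1e-9

    def test_spectrum_sorted_and_truncated(self, stuck_study):
        dm = distance_matrix(stuck_study.traces, max_samples=60)
        emb = classical_mds(dm, dims=2)
        ev = emb.eigenvalues
        assert np.all(np.diff(ev) <= 1e-9)
        assert np.all(np.isfinite(emb.coordinates))

    def test_two_peak_cluster_separation(self, stuck_study):
        dm = distance_matrix(stuck_study.traces, max_samples=80)
        emb = classical_mds(dm, dims=2)
        states = np.array([
            stuck_study.truth["peak_states"][chain][i]
            for chain, i in dm.labels
        ])
        a = emb.coordinates[states == 0]
        b = emb.coordinates[states == 1]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        rms = lambda c: np.sqrt(
            np.mean(np.sum((c - c.mean(0)) ** 2, axis=1))
        )
        within = max(rms(a), rms(b), 1e-12)
        assert between / within > 5

    def test_embedding_invariant_under_relabeling(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        perm = rng.permutation(12)
        dm1 = tr.DistanceMatrix([("c", i) for i in range(12)], d, "rf")
        dm2 = tr.DistanceMatrix(
            [("c", i) for i in range(12)], d[np.ix_(perm, perm)], "rf"
        )
        e1 = classical_mds(dm1).coordinates
        e2 = classical_mds(dm2).coordinates
        _, _, disparity = procrustes(e1[perm], e2)
        assert disparity < 1e-12


def dm_stride(study, max_samples):
    import math

    total = sum(len(t) for t in study.traces)
    return math.ceil(total / max_samples)


class TestDistanceMatrix:
    def test_identical_trees_zero(self, quartet):
        dm = distance_matrix([make_trace([quartet.copy()] * 3)])
        assert np.all(dm.matrix == 0)

    def test_two_peak_bimodal_distances(self, stuck_study):
        dm = distance_matrix(stuck_study.traces, max_samples=40)
        off = dm.matrix[np.triu_indices(len(dm), 1)]
        assert set(np.unique(off)) == {0.0, 12.0}

    def test_stride_subsampling(self, stuck_study):
        dm = distance_matrix(stuck_study.traces, max_samples=100)
        total = sum(len(t) for t in stuck_study.traces)
        stride = dm_stride(stuck_study, 100)
        expected = sum(
            len(range(0, len(t), stride)) for t in stuck_study.traces
        )
        assert len(dm) == expected <= 120


class TestLandscapeOverlay:
    def _embedding(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = tr.DistanceMatrix([("c", i) for i in range(n)], d, "rf")
        return classical_mds(dm)

    def test_uniform_density_flat_heatmap(self):
        emb = self._embedding()
        res = landscape_overlay(emb, np.full(100, 2.5), mode="heatmap")
        vals = res["mean_density"][res["counts"] > 0]
        assert np.allclose(vals, 2.5)

    def test_top_fraction_count(self):
        emb = self._embedding(1000, seed=1)
        res = landscape_overlay(
            emb, np.arange(1000.0), mode="top_fraction", top_fraction=0.01
        )
        assert len(res["indices"]) == 10
        assert np.all(res["density"] >= 990)

    def test_two_peak_density_separates(self, stuck_study):
        dm = distance_matrix(stuck_study.traces, max_samples=80)
        emb = classical_mds(dm)
        dens = dm.density
        res = landscape_overlay(emb, dens, mode="scatter3d")
        assert len(res["z"]) == len(emb.coordinates)

    def test_length_mismatch_rejected(self):
        emb = self._embedding()
        with pytest.raises(ValueError):
            landscape_overlay(emb, np.ones(5), mode="heatmap")


class TestPathProfile:
    def test_parsimony_valley_minimum_at_generating_peak(self):
        """An alignment simulated on the peak topology is most parsimonious
        there; scores rise along the NNI path away from it."""
        t = tr.build_caterpillar(LETTERS, step=1.0)
        aln, _ = tr.simulate_alignment(
            t, clock_rate=0.08, n_sites=500, seed=4
        )
        path = nni_path_tip_relocation(t, "A", LETTERS[1:8])
        scores = [tr.fitch_score(p, aln).total_score for p in path]
        prof = path_profile(path, scores)
        assert len(prof) == 7
        assert np.argmin(scores) == 0

    def test_constant_scores_flat(self, quartet):
        prof = path_profile([quartet] * 3, [1.0, 1.0, 1.0])
        assert [s for _, s in prof] == [1.0, 1.0, 1.0]
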