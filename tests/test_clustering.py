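"""Average-linkage SGB clustering, classification, overlap, and MDS."""

import itertools

import numpy as np
import pytest

from labgut import Genome
from labgut.clustering import (average_linkage_cluster, classical_mds,
                               classify_sgbs, overlap_summary)
from labgut.sketching import DistanceMatrix

from conftest import random_distance_matrix


def naive_average_linkage(ids, values, threshold):
    """Independent oracle: recompute average inter-cluster distances from the
    original matrix at every step, merging the global minimum pair."""
    clusters = [frozenset([i]) for i in range(len(ids))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = np.mean([values[i, j] for i in a for j in b])
            if best is None or avg < best[0]:
                best = (avg, a, b)
        avg, a, b = best
        if avg > threshold:
            break
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return {frozenset(ids[i] for i in c) for c in clusters}


def as_partition(sgbs):
    return {frozenset(s.members) for s in sgbs}


def make_dm(values, ids=None):
    n = values.shape[0]
    ids = ids or [f"g{i}" for i in range(n)]
    return DistanceMatrix(ids=ids, values=values)


class TestAverageLinkage:
    def test_all_zero_distances_give_single_cluster(self):
        d = make_dm(np.zeros((4, 4)))
        sgbs, _ = average_linkage_cluster(d, 0.05)
        assert len(sgbs) == 1

    def test_all_unit_distances_give_singletons(self):
        v = np.ones((4, 4)) - np.eye(4)
        sgbs, _ = average_linkage_cluster(make_dm(v), 0.05)
        assert len(sgbs) == 4

    def test_two_planted_pairs(self):
        # d(A,B)=0.02, d(C,D)=0.03, cross >= 0.2 -> {A,B}, {C,D}
        v = np.array([[0.00, 0.02, 0.25, 0.30],
                      [0.02, 0.00, 0.22, 0.28],
                      [0.25, 0.22, 0.00, 0.03],
                      [0.30, 0.28, 0.03, 0.00]])
        d = make_dm(v, ids=list("ABCD"))
        sgbs, _ = average_linkage_cluster(d, 0.05)
        assert as_partition(sgbs) == {frozenset("AB"), frozenset("CD")}
        assert as_partition(sgbs) == naive_average_linkage(d.ids, v, 0.05)

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(20)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            v = random_distance_matrix(n, rng)
            threshold = float(rng.uniform(0.05, 0.9))
            d = make_dm(v)
            sgbs, _ = average_linkage_cluster(d, threshold)
            assert as_partition(sgbs) == naive_average_linkage(d.ids, v, threshold)

    def test_matches_scipy_flat_clusters(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(21)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            v = random_distance_matrix(n, rng)
            threshold = float(rng.uniform(0.05, 0.9))
            d = make_dm(v)
            sgbs, _ = average_linkage_cluster(d, threshold)
            labels = fcluster(linkage(squareform(v), method="average"),
                              t=threshold, criterion="distance")
            scipy_part = {frozenset(np.array(d.ids)[labels == lab])
                          for lab in set(labels)}
            assert as_partition(sgbs) == scipy_part

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(22)
        v = random_distance_matrix(8, rng)
        counts = [len(average_linkage_cluster(make_dm(v), t)[0])
                  for t in (0.0, 0.1, 0.3, 0.5, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_cut_is_inclusive_at_threshold(self):
        v = np.array([[0.0, 0.05], [0.05, 0.0]])
        sgbs, _ = average_linkage_cluster(make_dm(v), 0.05)
        assert len(sgbs) == 1

    def test_input_order_invariance_with_ties(self):
        # equilateral ties: tie-break by smallest member id must fix the result
        v = np.full((3, 3), 0.04)
        np.fill_diagonal(v, 0.0)
        for order in itertools.permutations(["a", "b", "c"]):
            idx = {g: i for i, g in enumerate(["a", "b", "c"])}
            perm = [idx[g] for g in order]
            d = make_dm(v[np.ix_(perm, perm)], ids=list(order))
            sgbs, tree = average_linkage_cluster(d, 0.045)
            assert as_partition(sgbs) == {frozenset("abc")}
            first = tree.merges[0]
            assert sorted(first.left | first.right) == ["a", "b"]

    def test_merge_heights_are_nondecreasing(self):
        rng = np.random.default_rng(23)
        v = random_distance_matrix(8, rng)
        _, tree = average_linkage_cluster(make_dm(v), 1.0)
        heights = [m.height for m in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_newick_export_round_trips_leaves(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(24)
        v = random_distance_matrix(6, rng)
        d = make_dm(v)
        _, tree = average_linkage_cluster(d, 1.0)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(d.ids)

    def test_sgb_ids_ordered_by_size_then_member(self):
        v = np.array([[0.00, 0.01, 0.01, 0.9],
                      [0.01, 0.00, 0.01, 0.9],
                      [0.01, 0.01, 0.00, 0.9],
                      [0.90, 0.90, 0.90, 0.0]])
        sgbs, _ = average_linkage_cluster(make_dm(v, ids=["w", "x", "y", "z"]), 0.05)
        assert [len(s.members) for s in sgbs] == [3, 1]
        assert sgbs[0].sgb_id < sgbs[1].sgb_id


def _genome(gid, source, origin, completeness=95.0):
    return Genome(id=gid, source_category=source, origin=origin,
                  completeness=completeness, contamination=1.0)


class TestClassifySgbs:
    def _catalogue(self):
        return {
            "foodA": _genome("foodA", "food", "MAG"),
            "foodB": _genome("foodB", "food", "MAG"),
            "ref1": _genome("ref1", "other", "reference"),
            "hum1": _genome("hum1", "human", "MAG"),
            "oth1": _genome("oth1", "other", "MAG"),
        }

    def test_reference_genome_makes_ksgb(self):
        from labgut.clustering import SGB

        sgbs = classify_sgbs([SGB("SGB1", ["foodA", "ref1"])], self._catalogue())
        assert sgbs[0].sgb_class == "kSGB"
        assert sgbs[0].contains_reference

    def test_human_mag_makes_ksgb(self):
        from labgut.clustering import SGB

        sgbs = classify_sgbs([SGB("SGB1", ["foodA", "hum1"])], self._catalogue())
        assert sgbs[0].sgb_class == "kSGB"

    def test_food_only_makes_fsgb(self):
        from labgut.clustering import SGB

        sgbs = classify_sgbs([SGB("SGB1", ["foodA", "foodB"])], self._catalogue())
        assert sgbs[0].sgb_class == "fSGB"

    def test_mixed_non_reference_makes_other(self):
        from labgut.clustering import SGB

        sgbs = classify_sgbs([SGB("SGB1", ["foodA", "oth1"])], self._catalogue())
        assert sgbs[0].sgb_class == "other"

    def test_strict_reference_only_mode(self):
        from labgut.clustering import SGB

        sgbs = classify_sgbs([SGB("SGB1", ["foodA", "hum1"])], self._catalogue(),
                             ksgb_requires_reference=True)
        assert sgbs[0].sgb_class == "other"

    def test_every_sgb_gets_exactly_one_class(self):
        from labgut.clustering import SGB

        cat = self._catalogue()
        sgbs = classify_sgbs([SGB("SGB1", ["foodA"]), SGB("SGB2", ["ref1"]),
                              SGB("SGB3", ["hum1", "oth1"])], cat)
        assert all(s.sgb_class in {"kSGB", "fSGB", "other"} for s in sgbs)

    def test_unresolvable_member_named_in_error(self):
        from labgut.clustering import SGB

        with pytest.raises(KeyError, match="ghost"):
            classify_sgbs([SGB("SGB1", ["ghost"])], self._catalogue())


class TestOverlapSummary:
    def test_no_food_mags_gives_zero_counts(self):
        from labgut.clustering import SGB

        cat = {"hum1": _genome("hum1", "human", "MAG"),
               "ref1": _genome("ref1", "other", "reference")}
        sgbs = classify_sgbs([SGB("SGB1", ["hum1", "ref1"])], cat)
        out = overlap_summary(sgbs, cat)
        assert out["n_food_mags"].sum() == 0

    def test_half_of_food_mags_overlap_human(self):
        from labgut.clustering import SGB

        cat = {"f1": _genome("f1", "food", "MAG"),
               "f2": _genome("f2", "food", "MAG"),
               "f3": _genome("f3", "food", "MAG"),
               "f4": _genome("f4", "food", "MAG"),
               "h1": _genome("h1", "human", "MAG")}
        sgbs = classify_sgbs([SGB("SGB1", ["f1", "f2", "h1"]),
                              SGB("SGB2", ["f3", "f4"])], cat)
        out = overlap_summary(sgbs, cat)
        assert out.loc["human_overlap", "n_food_mags"] == 2
        assert out.loc["human_overlap", "pct_food_mags"] == 50.0
        assert out.loc["food_only", "n_food_mags"] == 2

    def test_summary_equals_independent_tally(self):
        from labgut.clustering import SGB

        rng = np.random.default_rng(31)
        cat, members = {}, []
        for i in range(40):
            source = rng.choice(["food", "human", "other"])
            origin = rng.choice(["MAG", "reference"])
            gid = f"g{i:02d}"
            cat[gid] = _genome(gid, str(source), str(origin))
            members.append(gid)
        rng.shuffle(members)
        groups = np.array_split(np.array(members), 8)
        sgbs = classify_sgbs(
            [SGB(f"SGB{i}", sorted(g)) for i, g in enumerate(groups) if len(g)], cat)
        out = overlap_summary(sgbs, cat)
        # independent recount
        total = sum(1 for g in cat.values() if g.is_food_mag)
        tallied = int(out["n_food_mags"].sum())
        assert tallied == total


class TestClassicalMds:
    def test_collinear_points_recovered_in_one_dimension(self):
        # points at 0, 3, 4 on a line
        v = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.1], [0.4, 0.1, 0.0]])
        d = make_dm(v)
        coords = classical_mds(d, dims=1)
        for i, j in itertools.combinations(range(3), 2):
            got = abs(coords.iloc[i, 0] - coords.iloc[j, 0])
            assert got == pytest.approx(v[i, j], abs=1e-9)

    def test_identical_genomes_share_coordinates(self):
        v = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        coords = classical_mds(make_dm(v), dims=2)
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_euclidean_realizable_matrix_reconstructs(self):
        rng = np.random.default_rng(41)
        pts = rng.uniform(0, 0.3, size=(7, 3))
        v = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = classical_mds(make_dm(v), dims=3).to_numpy()
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recon, v, atol=1e-6)

    def test_excess_dims_reduced_with_warning(self):
        v = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.1], [0.4, 0.1, 0.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords = classical_mds(make_dm(v), dims=3)
        assert coords.shape[1] < 3

    def test_invalid_dims_rejected(self):
        v = np.zeros((2, 2))
        with pytest.raises(ValueError):
            classical_mds(make_dm(v), dims=0)
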