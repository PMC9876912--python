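"""Nearest-center benchmark metrics, occupancy maps, energy inversion, lineage."""

import numpy as np
import pytest

from elbench.evaluation import (
    LINEAGE_PALETTE,
    OccupancyMap,
    RecallTable,
    accuracy,
    assign_nearest_center,
    energy_from_occupancy,
    evaluate_embedding,
    lineage_map,
    occupancy_map,
    recall_per_well,
    well_centers,
)

from conftest import make_clusters


class TestWellCenters:
    def test_singleton_class_center_is_the_point(self):
        coords = np.array([[1.0, 2.0]] + [[i, i] for i in range(11)])
        labels = np.arange(1, 13)
        assert np.array_equal(well_centers(coords, labels)[0], [1.0, 2.0])

    def test_symmetric_pair_centers_at_origin(self):
        coords = np.vstack([[[1.0, 3.0], [-1.0, -3.0]], np.tile(np.arange(2, 13)[:, None], (1, 2))])
        labels = np.array([1, 1] + list(range(2, 13)))
        assert np.allclose(well_centers(coords, labels)[0], [0.0, 0.0])

    def test_matches_per_class_mean_oracle(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(500, 2))
        labels = rng.integers(1, 13, size=500)
        centers = well_centers(coords, labels)
        for k in range(1, 13):
            expected = coords[labels == k].sum(axis=0) / (labels == k).sum()
            assert np.allclose(centers[k - 1], expected, rtol=1e-12)

    def test_empty_class_error_names_missing_well(self):
        coords = np.zeros((11, 2))
        labels = np.arange(1, 12)  # well 12 missing
        with pytest.raises(ValueError, match="12"):
            well_centers(coords, labels)


class TestAssignNearestCenter:
    def test_point_at_center_gets_that_label(self):
        centers = np.array([(i % 4, i // 4) for i in range(12)], dtype=float)
        assert assign_nearest_center(centers[6][None, :], centers)[0] == 7

    def test_tie_breaks_to_lowest_id(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert assign_nearest_center(np.array([[1.0, 5.0]]), centers)[0] == 1

    def test_matches_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(1000, 2))
        centers = rng.normal(size=(12, 2))
        got = assign_nearest_center(coords, centers)
        d2 = np.array([[np.sum((x - c) ** 2) for c in centers] for x in coords])
        assert np.array_equal(got, d2.argmin(axis=1) + 1)


class TestRecall:
    def test_perfect_assignment_gives_recall_one(self, tight_clusters):
        coords, labels = tight_clusters
        table = recall_per_well(labels, labels)
        assert np.all(table.recall == 1.0)

    def test_total_miss_gives_recall_zero(self):
        true = np.repeat(np.arange(1, 13), 5)
        pred = np.where(true == 1, 2, true)
        assert recall_per_well(true, pred).recall[0] == 0.0

    def test_hand_counted_five_element_confusion(self):
        table = recall_per_well([1, 1, 1, 2, 2], [1, 1, 2, 2, 2], n_wells=2)
        assert table.recall[0] == pytest.approx(2 / 3)
        assert table.recall[1] == 1.0

    def test_positive_counts_partition_particles(self):
        rng = np.random.default_rng(1)
        true = rng.integers(1, 13, 300)
        true[:12] = np.arange(1, 13)  # ensure every well occurs
        table = recall_per_well(true, rng.integers(1, 13, 300))
        assert table.positives.sum() == 300

    def test_missing_well_rejected(self):
        with pytest.raises(ValueError, match="P\\(n\\) = 0"):
            recall_per_well([1, 2], [1, 2])


class TestAccuracy:
    def test_constant_recalls(self):
        table = RecallTable(
            well_ids=np.arange(1, 13),
            positives=np.full(12, 1000),
            true_positives=np.full(12, 776),
        )
        acc, std = accuracy(table)
        assert acc == pytest.approx(77.6)
        assert std == pytest.approx(0.0)

    def test_single_perfect_well(self):
        table = RecallTable(
            well_ids=np.arange(1, 13),
            positives=np.full(12, 10),
            true_positives=np.array([10] + [0] * 11),
        )
        acc, _ = accuracy(table)
        assert acc == pytest.approx(100 / 12)

    def test_matches_brute_force_statistics(self):
        rng = np.random.default_rng(2)
        p = np.full(12, 1000)
        tp = rng.integers(0, 1001, 12)
        table = RecallTable(well_ids=np.arange(1, 13), positives=p, true_positives=tp)
        acc, std = accuracy(table)
        r = tp / p
        assert acc == pytest.approx(100 * sum(r) / 12, rel=1e-12)
        assert std == pytest.approx(100 * np.sqrt(sum((x - r.mean()) ** 2 for x in r) / 12), rel=1e-12)

    def test_sample_convention_switch(self):
        rng = np.random.default_rng(3)
        tp = rng.integers(0, 1001, 12)
        table = RecallTable(well_ids=np.arange(1, 13), positives=np.full(12, 1000), true_positives=tp)
        _, pop = accuracy(table, ddof=0)
        _, samp = accuracy(table, ddof=1)
        assert samp > pop


class TestEvaluateEmbedding:
    def test_perfectly_separated_input_scores_100(self, tight_clusters):
        coords, labels = tight_clusters
        report = evaluate_embedding(coords, labels)
        assert report.accuracy == 100.0
        assert report.recall_std == 0.0

    def test_uninformative_embedding_scores_chance(self):
        rng = np.random.default_rng(4)
        n = 12_000
        labels = np.repeat(np.arange(1, 13), n // 12)
        coords = rng.uniform(size=(n, 2))  # independent of labels
        report = evaluate_embedding(coords, labels)
        se = 100 * np.sqrt((1 / 12) * (11 / 12) / n) * np.sqrt(12)  # mean-recall SE
        assert abs(report.accuracy - 100 / 12) < 4 * se

    def test_invariant_under_similarity_transform(self):
        rng = np.random.default_rng(5)
        coords, labels = make_clusters(rng, n_per=84, spread=2.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        mapped = 3.5 * coords @ rot.T + np.array([100.0, -40.0])
        a = evaluate_embedding(coords, labels)
        b = evaluate_embedding(mapped, labels)
        assert np.array_equal(a.recall_table.true_positives, b.recall_table.true_positives)
        assert a.accuracy == b.accuracy

    def test_accuracy_bounded(self):
        rng = np.random.default_rng(6)
        coords, labels = make_clusters(rng, n_per=10, spread=20.0)
        report = evaluate_embedding(coords, labels)
        assert 0.0 <= report.accuracy <= 100.0

    def test_noise_degrades_accuracy_monotonically(self):
        rng = np.random.default_rng(7)
        sigmas = [0.0, 2.0, 5.0, 12.0]
        reps = 20
        acc = np.empty((len(sigmas), reps))
        for rep in range(reps):
            coords, labels = make_clusters(np.random.default_rng(100 + rep), n_per=40, spread=0.5)
            for i, s in enumerate(sigmas):
                noisy = coords + rng.normal(0.0, s, coords.shape)
                acc[i, rep] = evaluate_embedding(noisy, labels).accuracy
        means = acc.mean(axis=1)
        ses = acc.std(axis=1, ddof=1) / np.sqrt(reps)
        for i in range(len(sigmas) - 1):
            assert means[i + 1] <= means[i] + (ses[i] + ses[i + 1])


class TestOccupancyMap:
    def test_single_bin_holds_all_mass(self):
        coords = np.full((50, 2), 0.5)
        occ = occupancy_map(coords, n_bins=4)
        assert occ.probabilities.max() == 1.0

    def test_probabilities_sum_to_one(self):
        coords = np.random.default_rng(2).normal(size=(1234, 2))
        assert occupancy_map(coords, 10).probabilities.sum() == pytest.approx(1.0)

    def test_counts_sum_to_n(self):
        coords = np.random.default_rng(3).normal(size=(777, 2))
        assert occupancy_map(coords, 13).counts.sum() == 777

    def test_uniform_cloud_bin_deviation_within_5se(self):
        n, bins = 1_000_000, 10
        coords = np.random.default_rng(4).uniform(size=(n, 2))
        occ = occupancy_map(coords, bins)
        p0 = 1 / bins**2
        se = np.sqrt(p0 * (1 - p0) / n)
        assert np.abs(occ.probabilities - p0).max() < 5 * se

    def test_requires_2d(self):
        with pytest.raises(ValueError, match="2-D"):
            occupancy_map(np.zeros((10, 3)), 8)


class TestEnergyFromOccupancy:
    def test_uniform_occupancy_flat_zero(self):
        occ = OccupancyMap(counts=np.full((4, 4), 5.0), edges1=np.arange(5.0), edges2=np.arange(5.0))
        assert np.allclose(energy_from_occupancy(occ), 0.0)

    def test_two_level_delta_is_ln2(self):
        counts = np.zeros((4, 4))
        counts[0, 0], counts[0, 1] = 20, 10  # probabilities 2/3, 1/3
        occ = OccupancyMap(counts=counts, edges1=np.arange(5.0), edges2=np.arange(5.0))
        e = energy_from_occupancy(occ, kT=1.0)
        assert e[0, 1] - e[0, 0] == pytest.approx(np.log(2))
        assert np.isnan(e[2, 2])

    def test_all_below_floor_rejected(self):
        occ = OccupancyMap(counts=np.zeros((4, 4)), edges1=np.arange(5.0), edges2=np.arange(5.0))
        with pytest.raises(ValueError, match="floor"):
            energy_from_occupancy(occ)

    def test_min_energy_shifted_to_zero(self):
        counts = np.random.default_rng(5).integers(1, 50, (6, 6)).astype(float)
        e = energy_from_occupancy(OccupancyMap(counts=counts, edges1=np.arange(7.0), edges2=np.arange(7.0)))
        assert np.nanmin(e) == 0.0


class TestLineage:
    def test_twelve_distinct_colors(self, tight_clusters):
        coords, labels = tight_clusters
        df = lineage_map(coords, labels)
        assert df["color"].nunique() == 12
        assert set(df["color_id"]) == set(range(1, 13))

    def test_order_invariance(self, tight_clusters):
        coords, labels = tight_clusters
        perm = np.random.default_rng(6).permutation(len(labels))
        a = lineage_map(coords, labels)
        b = lineage_map(coords[perm], labels[perm])
        key = ["dim1", "dim2", "color_id"]
        assert sorted(map(tuple, a[key].to_numpy())) == sorted(map(tuple, b[key].to_numpy()))

    def test_color_purity_in_voronoi_cells(self, tight_clusters):
        coords, labels = tight_clusters
        centers = well_centers(coords, labels)
        assigned = assign_nearest_center(coords, centers)
        df = lineage_map(coords, labels)
        # well-separated clusters: each Voronoi cell holds exactly one color
        for k in range(1, 13):
            assert df.loc[assigned == k, "color_id"].nunique() == 1

    def test_palette_size(self):
        assert len(LINEAGE_PALETTE) == len(set(LINEAGE_PALETTE)) == 12
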