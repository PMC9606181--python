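"""Distance matrices, complete linkage, fractional tree cuts and profiles."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from fosnet import community
from fosnet.hierarchy import (
    DistanceMatrix,
    complete_linkage,
    cut_profile,
    euclidean_distance_matrix,
    tree_cut,
)
from fosnet.simulate import generate_cohort, planted_modules_structure
from fosnet.correlation import correlation_matrix

from conftest import make_corr, one_group_design

import pandas as pd


def dist_from(matrix, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    labels = labels or [chr(65 + i) for i in range(matrix.shape[0])]
    return DistanceMatrix(
        group_label="g", d=pd.DataFrame(matrix, index=labels, columns=labels)
    )


THREE_POINT = dist_from([[0, 1, 5], [1, 0, 5], [5, 5, 0]])  # AB=1, AC=BC=5


class TestDistance:
    def test_identical_rows_have_zero_distance(self):
        corr = make_corr(np.ones((3, 3)))
        d = euclidean_distance_matrix(corr)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-15)

    def test_matches_naive_loop_oracle(self, rng):
        m = rng.uniform(-1, 1, (7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        corr = make_corr(m)
        d = euclidean_distance_matrix(corr).values
        for i in range(7):
            for j in range(7):
                expect = np.sqrt(((m[i] - m[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_diagonal_exclusion_flag(self):
        m = np.eye(3)
        corr = make_corr(m)
        # rows (1,0,0) vs (0,1,0): with diagonal sqrt(2); without it 0
        with_diag = euclidean_distance_matrix(corr, include_diagonal=True)
        without = euclidean_distance_matrix(corr, include_diagonal=False)
        assert with_diag.values[0, 1] == pytest.approx(np.sqrt(2))
        assert without.values[0, 1] == pytest.approx(0.0)

    def test_missing_region_excluded_before_distances(self):
        m = np.eye(4)
        m[3, :] = np.nan
        m[:, 3] = np.nan
        corr = make_corr(m)
        d = euclidean_distance_matrix(corr)
        assert d.excluded_regions == ("R4",)
        assert d.region_names == ("R1", "R2", "R3")

    def test_too_few_usable_regions_rejected(self):
        m = np.full((3, 3), np.nan)
        np.fill_diagonal(m, 1.0)
        m[0, 1] = m[1, 0] = 0.5
        corr = make_corr(np.where(np.isnan(m), np.nan, m))
        corr.r.iloc[2, :] = np.nan
        corr.r.iloc[:, 2] = np.nan
        with pytest.raises(ValueError):
            euclidean_distance_matrix(corr)


class TestCompleteLinkage:
    def test_three_point_hand_trace(self):
        dend = complete_linkage(THREE_POINT)
        (a0, b0, h0, s0), (a1, b1, h1, s1) = dend.merges
        assert (a0, b0, h0, s0) == (0, 1, 1.0, 2)
        assert h1 == 5.0 and s1 == 3
        assert dend.max_height == 5.0

    def test_equal_distances_tie_break_is_lexicographic(self):
        d = dist_from(np.ones((4, 4)) - np.eye(4))
        dend = complete_linkage(d)
        assert [m[:2] for m in dend.merges] == [(0, 1), (2, 3), (4, 5)]
        assert all(m[2] == 1.0 for m in dend.merges)

    def test_heights_match_scipy_reference(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(10, 4))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dend = complete_linkage(dist_from(d, labels=[f"P{i}" for i in range(10)]))
            ref = linkage(squareform(d, checks=False), method="complete")
            np.testing.assert_allclose(
                [m[2] for m in dend.merges], ref[:, 2], atol=1e-10
            )

    def test_monotone_heights(self, rng):
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dend = complete_linkage(dist_from(d, labels=[f"P{i}" for i in range(12)]))
        heights = [m[2] for m in dend.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_non_finite_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            complete_linkage(dist_from(d))


def test_leaf_order_covers_all_leaves_contiguously():
    dend = complete_linkage(THREE_POINT)
    order = dend.leaf_order()
    assert sorted(order) == ["A", "B", "C"]
    # A and B merge first, so they are adjacent in display order
    assert abs(order.index("A") - order.index("B")) == 1


class TestTreeCut:
    def test_fraction_one_gives_single_module(self):
        labels = tree_cut(complete_linkage(THREE_POINT), 1.0)
        assert len(set(labels.values())) == 1

    def test_tiny_fraction_gives_singletons(self):
        labels = tree_cut(complete_linkage(THREE_POINT), 0.1)
        assert len(set(labels.values())) == 3

    def test_three_point_cut_at_half(self):
        labels = tree_cut(complete_linkage(THREE_POINT), 0.5)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            tree_cut(complete_linkage(THREE_POINT), 0.0)


class TestCutProfile:
    def test_two_leaf_dendrogram_counts(self):
        d = dist_from([[0, 2.0], [2.0, 0]])
        profile = cut_profile(complete_linkage(d), (0.5, 1.0))
        assert set(profile.module_counts) <= {1, 2}

    def test_counts_non_increasing_on_random_inputs(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(9, 3))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dend = complete_linkage(dist_from(d, labels=[f"P{i}" for i in range(9)]))
            counts = cut_profile(dend).module_counts
            assert all(c2 <= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_unsorted_fractions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            cut_profile(complete_linkage(THREE_POINT), (0.9, 0.5))


class TestPlantedStructureConsistency:
    def test_spectral_and_tree_cut_agree_on_well_separated_modules(self):
        # large-n cohort: both methods recover the same clean 3-module split
        from sklearn.metrics import adjusted_rand_score

        regions = tuple(f"R{i}" for i in range(30))
        planted = planted_modules_structure(regions)
        truth = planted.module_labels(regions)
        design, label = one_group_design(regions, n=300, seed=21)
        table = generate_cohort(design, planted)[label]
        corr = correlation_matrix(table)
        spectral = community.spectral_communities(
            community.WeightedNetwork.from_correlation(corr)
        )
        labels = tree_cut(complete_linkage(euclidean_distance_matrix(corr)), 0.70)
        lab_s = spectral.label_array(regions)
        lab_t = [labels[r] for r in regions]
        assert adjusted_rand_score(lab_s, lab_t) >= 0.9
        assert adjusted_rand_score(truth, lab_s) >= 0.9

    def test_more_planted_modules_yield_more_detected_modules(self):
        regions = tuple(f"R{i}" for i in range(24))
        design, label = one_group_design(regions, n=120, seed=8)
        counts = {}
        for k in (2, 6):
            planted = planted_modules_structure(regions, n_modules=k)
            table = generate_cohort(design, planted)[label]
            corr = correlation_matrix(table)
            spectral = community.spectral_communities(
                community.WeightedNetwork.from_correlation(corr)
            )
            cut = tree_cut(complete_linkage(euclidean_distance_matrix(corr)), 0.70)
            counts[k] = (spectral.n_modules, len(set(cut.values())))
        assert counts[6][0] > counts[2][0]
        assert counts[6][1] > counts[2][1]
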