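"""Synthetic cohort generator: planted targets, reproducibility, scale."""

import numpy as np
import pandas as pd
import pytest

from fosnet.design import PlantedStructure, StudyDesign
from fosnet.simulate import (
    build_target_correlation,
    default_design,
    generate_cohort,
    hub_recovery_structure,
    planted_modules_structure,
    summarize_table,
)

from conftest import make_table, one_group_design


def uniform_structure(regions, within=0.0, between=0.0, **kw):
    return PlantedStructure(
        module_assignment={r: 0 for r in regions},
        within_module_r=within,
        between_module_r=between,
        base_mean={r: 100.0 for r in regions},
        **kw,
    )


class TestTargetCorrelation:
    def test_independent_regions_give_identity(self):
        regions = ["A", "B", "C"]
        target = build_target_correlation(uniform_structure(regions), regions)
        np.testing.assert_array_equal(target, np.eye(3))

    def test_two_blocks_are_block_diagonal_and_psd(self):
        regions = list("ABCDEF")
        planted = PlantedStructure(
            module_assignment=dict(zip(regions, [0, 0, 0, 1, 1, 1])),
            within_module_r=0.8,
            between_module_r=0.0,
        )
        target = build_target_correlation(planted, regions)
        expected = np.kron(np.eye(2), np.full((3, 3), 0.8) + 0.2 * np.eye(3))
        np.testing.assert_allclose(target, expected, atol=1e-12)
        # PSD verified by direct eigendecomposition
        assert np.linalg.eigvalsh(target).min() >= -1e-12

    def test_hub_boost_is_capped_below_one(self):
        regions = list("ABCD")
        planted = PlantedStructure(
            module_assignment={r: 0 for r in regions},
            within_module_r=0.9,
            between_module_r=0.0,
            hub_regions=frozenset("AB"),
            hub_extra_r=0.3,
        )
        target = build_target_correlation(planted, regions)
        off = target[~np.eye(4, dtype=bool)]
        assert off.max() <= planted.r_max + 1e-9

    def test_non_repairable_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlantedStructure(module_assignment={"A": 0}, within_module_r=1.0)
        with pytest.raises(ValueError):
            PlantedStructure(
                module_assignment={"A": 0}, within_module_r=0.3, between_module_r=0.5
            )

    def test_repair_restores_unit_diagonal(self, rng):
        regions = [f"R{i}" for i in range(8)]
        planted = PlantedStructure(
            module_assignment={r: i % 2 for i, r in enumerate(regions)},
            within_module_r=0.95,
            between_module_r=-0.5,
            hub_regions=frozenset(regions[:3]),
            hub_extra_r=0.4,
        )
        target = build_target_correlation(planted, regions)
        np.testing.assert_allclose(np.diag(target), 1.0, atol=1e-12)
        np.testing.assert_allclose(target, target.T, atol=1e-12)
        assert np.linalg.eigvalsh(target).min() >= -1e-10


class TestGenerateCohort:
    def test_zero_noise_limit_returns_group_means(self):
        regions = ["A", "B", "C"]
        design, label = one_group_design(regions, n=4)
        planted = uniform_structure(regions, noise_cv=0.0)
        table = generate_cohort(design, planted)[label]
        np.testing.assert_allclose(table.values.to_numpy(), 100.0, rtol=1e-12)

    def test_region_mismatch_rejected(self):
        design, _ = one_group_design(["A", "B", "C"])
        planted = uniform_structure(["A", "B", "D"])
        with pytest.raises(ValueError, match="region"):
            generate_cohort(design, planted)

    def test_same_seed_bit_identical_and_positive(self):
        design = default_design(seed=7, n_regions=12)
        planted = planted_modules_structure(design.region_names)
        t1 = generate_cohort(design, planted)
        t2 = generate_cohort(design, planted)
        for label in t1:
            pd.testing.assert_frame_equal(t1[label].values, t2[label].values)
            assert (t1[label].values.to_numpy() > 0).all()

    def test_child_seeds_stable_under_added_group(self):
        regions = tuple(f"R{i}" for i in range(6))
        base, label = one_group_design(regions, n=5, seed=3)
        wider = StudyDesign(
            genotypes=("WT", "KO"),
            treatments=("vehicle",),
            stress_conditions=("naive",),
            n_per_cell={label: 5, "KO:vehicle:naive": 5},
            region_names=regions,
            seed=3,
        )
        planted = uniform_structure(regions, noise_cv=0.4)
        narrow = generate_cohort(base, planted)[label]
        wide = generate_cohort(wider, planted)[label]
        pd.testing.assert_frame_equal(narrow.values, wide.values)

    def test_table1_scale_sample_means_within_3_sem(self):
        # scale check at n = 200: per-region sample means near targets
        regions = tuple(f"R{i}" for i in range(20))
        design, label = one_group_design(regions, n=200, seed=11)
        planted = planted_modules_structure(regions)
        table = generate_cohort(design, planted)[label]
        means = table.values.mean(axis=0)
        sems = table.values.std(axis=0, ddof=1) / np.sqrt(200)
        targets = np.asarray([planted.base_mean[r] for r in regions])
        assert (np.abs(means.to_numpy() - targets) <= 3 * sems.to_numpy()).all()
        assert (targets >= 30).all() and (targets <= 900).all()

    def test_large_n_correlations_converge_to_target(self):
        regions = tuple(f"R{i}" for i in range(30))
        design, label = one_group_design(regions, n=5000, seed=5)
        planted = planted_modules_structure(regions, within_module_r=0.8)
        table = generate_cohort(design, planted)[label]
        sample = np.corrcoef(table.values.to_numpy(), rowvar=False)
        target = build_target_correlation(planted, regions)
        assert np.abs(sample - target).max() <= 0.05


class TestSummarize:
    def test_constant_column_gives_zero_sem(self):
        table = make_table(np.full((4, 3), 100.0))
        out = summarize_table([table])
        assert (out["mean"] == 100.0).all()
        assert (out["sem"] == 0.0).all()

    def test_hand_computed_sem(self):
        table = make_table(np.array([[1.0], [2.0], [3.0], [4.0]]), regions=["A"])
        out = summarize_table([table])
        assert out.loc[0, "mean"] == pytest.approx(2.5)
        assert out.loc[0, "sem"] == pytest.approx(0.6455, abs=1e-4)

    def test_single_animal_group_rejected(self):
        table = make_table(np.ones((1, 3)))
        with pytest.raises(ValueError, match="n >= 2"):
            summarize_table([table])


class TestScenarios:
    def test_hub_recovery_background_below_detection_band(self):
        planted = hub_recovery_structure()
        assert planted.within_module_r < 0.79
        assert planted.within_module_r + planted.hub_extra_r >= 0.87
        assert len(planted.hub_regions) == 12

    def test_design_validation(self):
        with pytest.raises(ValueError, match="unique"):
            StudyDesign(
                genotypes=("WT",),
                treatments=("v",),
                stress_conditions=("n",),
                n_per_cell={"WT:v:n": 4},
                region_names=("A", "A", "B"),
            )
        with pytest.raises(ValueError, match="n >= 2"):
            one_group_design(["A", "B", "C"], n=1)
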