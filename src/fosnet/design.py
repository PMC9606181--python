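"""Study designs and planted covariance structure for synthetic cohorts.

A factorial immediate-early-gene mapping study assigns animals to the cells
of a genotype x treatment x stress design and quantifies Fos-positive cell
density (cells/mm^2) in a fixed panel of brain regions.  The synthetic
generator needs two ingredients: the *design* (factors, cell sizes, region
panel, master seed) and the *planted structure* (block-modular inter-regional
correlation, designated hub regions, per-group mean shifts) that gives every
downstream network statistic a ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

__all__ = ["StudyDesign", "PlantedStructure", "group_label"]


def group_label(genotype: str, treatment: str, stress: str) -> str:
    """Canonical label for one factorial cell, e.g. ``'KO:deferiprone:PST'``."""
    return f"{genotype}:{treatment}:{stress}"


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of a regional-activity cohort.

    Parameters
    ----------
    genotypes, treatments, stress_conditions
        Factor levels; their Cartesian product defines the groups.
    n_per_cell
        Mapping from group label to the number of animals in that cell.
        Every cell of the factorial must be present with n >= 2 (Pearson
        correlation needs at least two observations; thresholded networks
        are only meaningful for n >= 4).
    region_names
        Ordered, unique identifiers of the quantified brain regions (R >= 3).
    seed
        Master seed; per-group child seeds are derived from it by stable
        hashing of the group label.
    """

    genotypes: tuple[str, ...]
    treatments: tuple[str, ...]
    stress_conditions: tuple[str, ...]
    n_per_cell: Mapping[str, int]
    region_names: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        regions = tuple(self.region_names)
        if len(regions) < 3:
            raise ValueError("need at least 3 regions")
        if len(set(regions)) != len(regions):
            raise ValueError("region names must be unique")
        object.__setattr__(self, "region_names", regions)
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "stress_conditions", tuple(self.stress_conditions))
        for label in self.group_labels():
            n = self.n_per_cell.get(label)
            if n is None:
                raise ValueError(f"n_per_cell missing group {label!r}")
            if n < 2:
                raise ValueError(f"group {label!r} has n={n}; need n >= 2")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def group_labels(self) -> list[str]:
        """All factorial cells in deterministic (row-major) order."""
        return [
            group_label(g, t, s)
            for g, t, s in product(self.genotypes, self.treatments, self.stress_conditions)
        ]

    def group_factors(self, label: str) -> dict[str, str]:
        genotype, treatment, stress = label.split(":")
        return {"genotype": genotype, "treatment": treatment, "stress": stress}

    def child_seed(self, label: str) -> int:
        """Stable per-group seed: adding a group never perturbs the others."""
        h = zlib.crc32(f"{self.seed}:{label}".encode())
        return int(h) % (2**31 - 1)


@dataclass(frozen=True)
class PlantedStructure:
    """Ground-truth covariance and mean structure for a synthetic cohort.

    ``module_assignment`` maps each region to a module id; pairs inside a
    module get latent correlation ``within_module_r``, pairs across modules
    ``between_module_r``.  Regions in ``hub_regions`` get ``hub_extra_r``
    added to every one of their off-diagonal correlations (capped at
    ``r_max``), which elevates both their degree and their betweenness in
    the thresholded networks.  ``group_effects`` multiplies per-region mean
    densities for selected groups, so factorial ANOVA has planted effects.
    """

    module_assignment: Mapping[str, int]
    within_module_r: float = 0.8
    between_module_r: float = 0.1
    hub_regions: frozenset[str] = frozenset()
    hub_extra_r: float = 0.0
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    base_mean: Mapping[str, float] = field(default_factory=dict)
    noise_cv: float = 0.5
    r_max: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_module_r < 1.0:
            raise ValueError("within_module_r must lie in [0, 1)")
        if abs(self.between_module_r) >= max(self.within_module_r, 1e-12) and (
            self.between_module_r != 0.0 or self.within_module_r != 0.0
        ):
            if abs(self.between_module_r) >= self.within_module_r:
                raise ValueError("|between_module_r| must be < within_module_r")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        object.__setattr__(self, "hub_regions", frozenset(self.hub_regions))

    def validate_regions(self, region_names: Sequence[str]) -> None:
        regions = set(region_names)
        missing = set(self.module_assignment) ^ regions
        if set(self.module_assignment) - regions:
            raise ValueError(
                f"module_assignment names unknown regions: {sorted(set(self.module_assignment) - regions)}"
            )
        if regions - set(self.module_assignment):
            raise ValueError(
                f"regions missing from module_assignment: {sorted(regions - set(self.module_assignment))}"
            )
        del missing
        if not self.hub_regions <= regions:
            raise ValueError(
                f"hub_regions not a subset of the region panel: {sorted(self.hub_regions - regions)}"
            )

    def mean_for(self, region: str, group: str, default: float = 100.0) -> float:
        mean = float(self.base_mean.get(region, default))
        return mean * float(self.group_effects.get((group, region), 1.0))

    def module_labels(self, region_names: Sequence[str]) -> np.ndarray:
        return np.asarray([self.module_assignment[r] for r in region_names])
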