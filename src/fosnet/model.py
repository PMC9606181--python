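"""Model/Results interface for one group's coactivation network analysis.

`CoactivationNetwork` is built from an animals x regions density table and
`fit()` runs the full inference chain for that experimental group:

1. inter-regional Pearson correlation matrix (pairwise-complete);
2. six thresholded confidence networks (low/primary/high x positive/negative);
3. degree per level and betweenness on the primary network;
4. composite 80th-percentile hub classification;
5. spectral modularity communities on the weighted correlation network;
6. complete-linkage dendrogram of Euclidean correlation-profile distances
   with the fractional tree cut and module-count profile.

The returned `CoactivationResults` carries all artefacts, tabular views and
a text `summary()`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import centrality, community, hierarchy, networks
from .correlation import CorrelationMatrix, correlation_matrix
from .simulate import RegionActivityTable

__all__ = ["CoactivationNetwork", "CoactivationResults"]


class CoactivationNetwork:
    """Coactivation-network model for one experimental group.

    Parameters
    ----------
    data
        Animals x regions density table (`RegionActivityTable` or a
        DataFrame with animals as rows and regions as columns).
    group_label
        Name of the experimental group (defaults to the table's label).
    """

    def __init__(self, data, group_label: str | None = None):
        if isinstance(data, RegionActivityTable):
            self.table = data if group_label is None else RegionActivityTable(
                group_label=group_label, values=data.values
            )
        elif isinstance(data, pd.DataFrame):
            self.table = RegionActivityTable(
                group_label=group_label or "group", values=data.astype(float)
            )
        else:
            raise TypeError("data must be a RegionActivityTable or DataFrame")
        if self.table.n_animals < 2:
            raise ValueError("coactivation analysis needs at least 2 animals")

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, group_label: str | None = None
    ) -> "CoactivationNetwork":
        return cls(frame, group_label=group_label)

    @property
    def group_label(self) -> str:
        return self.table.group_label

    def fit(
        self,
        thresholds: Mapping[str, float] | None = None,
        hub_percentile: float = 80.0,
        sign_policy: str = "positive_only",
        cut_fraction: float = hierarchy.DEFAULT_CUT_FRACTION,
        cut_fractions: Sequence[float] = hierarchy.DEFAULT_CUT_GRID,
        require_all_levels: bool = True,
        include_diagonal: bool = True,
    ) -> "CoactivationResults":
        """Run the full chain and return a results object."""
        corr = correlation_matrix(self.table)
        nets = networks.all_confidence_networks(corr, dict(thresholds) if thresholds else None)
        positive = {lvl: nets[(lvl, "positive")] for lvl in networks.LEVELS}
        hubs = centrality.identify_hubs(
            positive, percentile=hub_percentile, require_all_levels=require_all_levels
        )
        weighted = community.WeightedNetwork.from_correlation(corr, sign_policy)
        modules = community.spectral_communities(weighted)
        dist = hierarchy.euclidean_distance_matrix(corr, include_diagonal=include_diagonal)
        dend = hierarchy.complete_linkage(dist)
        labels = hierarchy.tree_cut(dend, cut_fraction)
        profile = hierarchy.cut_profile(dend, tuple(cut_fractions))
        return CoactivationResults(
            model=self,
            corr=corr,
            networks=nets,
            hub_report=hubs,
            weighted=weighted,
            communities=modules,
            distance=dist,
            dendrogram=dend,
            cut_fraction=float(cut_fraction),
            tree_cut_labels=labels,
            cut_profile=profile,
        )


class CoactivationResults:
    """Fitted coactivation-network artefacts for one group."""

    def __init__(
        self,
        model: CoactivationNetwork,
        corr: CorrelationMatrix,
        networks,
        hub_report,
        weighted,
        communities,
        distance,
        dendrogram,
        cut_fraction,
        tree_cut_labels,
        cut_profile,
    ):
        self.model = model
        self.corr = corr
        self.networks = networks
        self.hub_report = hub_report
        self.weighted = weighted
        self.communities = communities
        self.distance = distance
        self.dendrogram = dendrogram
        self.cut_fraction = cut_fraction
        self.tree_cut_labels = tree_cut_labels
        self.cut_profile = cut_profile

    @property
    def group_label(self) -> str:
        return self.model.group_label

    @property
    def hubs(self) -> tuple[str, ...]:
        return self.hub_report.hubs

    @property
    def Q(self) -> float:
        return self.communities.Q

    def node_metrics(self) -> pd.DataFrame:
        """Per-region degree (per level), betweenness, hub flag, module ids."""
        report = self.hub_report
        rows = []
        for region in self.corr.region_names:
            rows.append(
                {
                    "region": region,
                    "degree_low": report.degrees["low"][region],
                    "degree_primary": report.degrees["primary"][region],
                    "degree_high": report.degrees["high"][region],
                    "betweenness": report.betweenness[region],
                    "is_hub": region in report.hubs,
                    "module_spectral": self.communities.labels[region],
                    "module_tree_cut": self.tree_cut_labels.get(region, -1),
                }
            )
        return pd.DataFrame(rows)

    def edge_counts(self) -> dict[tuple[str, str], int]:
        return {key: net.n_edges for key, net in self.networks.items()}

    def summary(self) -> str:
        counts = self.edge_counts()
        mean_r = float(np.nanmean(self.corr.values[np.triu_indices(len(self.corr.region_names), 1)]))
        lines = [
            f"Coactivation network: group {self.group_label!r}",
            f"  animals: {self.model.table.n_animals}, regions: {len(self.corr.region_names)}",
            f"  mean inter-regional r: {mean_r:.3f}",
            "  edges (positive): "
            + ", ".join(
                f"{lvl} (r>={self.networks[(lvl, 'positive')].r_cut:.2f}): {counts[(lvl, 'positive')]}"
                for lvl in networks.LEVELS
            ),
            f"  edges (negative, r<=-{self.networks[('primary', 'negative')].r_cut:.2f}): "
            f"{counts[('primary', 'negative')]}",
            f"  hubs ({self.hub_report.percentile:.0f}th percentile): "
            + (", ".join(self.hubs) if self.hubs else "none"),
            f"  spectral modules: {self.communities.n_modules} (Q = {self.Q:.3f})",
            f"  tree-cut modules at {self.cut_fraction:.2f} x max height: "
            f"{len(set(self.tree_cut_labels.values()))}",
        ]
        return "\n".join(lines)
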