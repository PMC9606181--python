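"""Thresholded confidence networks.

A correlation matrix is binarised at fixed Pearson cutoffs into signed
confidence networks: positive edges where r >= r_cut, negative edges where
r <= -r_cut.  Three nested confidence levels are used — low (r >= 0.79),
primary (r >= 0.83) and high (r >= 0.87) — so that for a fixed sign the
high-confidence edge set is contained in the primary one, which is contained
in the low one.  Nodes are brain regions; isolated nodes are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix

__all__ = [
    "ThresholdedNetwork",
    "threshold_network",
    "all_confidence_networks",
    "DEFAULT_THRESHOLDS",
    "ALT_LOW_THRESHOLD",
    "ALT_NEGATIVE_THRESHOLD",
    "LEVELS",
]

#: Default Pearson cutoffs per confidence level; ``negative`` is the
#: magnitude of the cutoff for the negative-correlation network.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "low": 0.79,
    "primary": 0.83,
    "high": 0.87,
    "negative": 0.83,
}

#: Alternative presets used in some published figure conventions.
ALT_LOW_THRESHOLD = 0.78
ALT_NEGATIVE_THRESHOLD = 0.87

LEVELS = ("low", "primary", "high")


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Binary undirected network at one confidence level and sign."""

    group_label: str
    level: str
    sign: str  # 'positive' or 'negative'
    r_cut: float
    graph: nx.Graph  # nodes = all regions, edge attr 'r' = correlation

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def threshold_network(
    corr: CorrelationMatrix,
    level: str = "primary",
    sign: str = "positive",
    thresholds: dict[str, float] | None = None,
) -> ThresholdedNetwork:
    """Binarise a correlation matrix at a named confidence level.

    ``sign='positive'`` keeps pairs with r >= r_cut; ``sign='negative'``
    keeps pairs with r <= -r_cut where r_cut is ``thresholds['negative']``
    regardless of level (published negative networks use a single cutoff).
    Missing (NaN) correlations never create edges.  All regions appear as
    nodes even when isolated.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if sign not in ("positive", "negative"):
        raise ValueError(f"unknown sign {sign!r}")
    if level not in thresholds or level == "negative":
        raise ValueError(f"unknown confidence level {level!r}")
    r_cut = float(thresholds[level] if sign == "positive" else thresholds["negative"])

    regions = corr.region_names
    arr = corr.values
    graph = nx.Graph()
    graph.add_nodes_from(regions)
    iu, ju = np.triu_indices(len(regions), k=1)
    vals = arr[iu, ju]
    if sign == "positive":
        keep = vals >= r_cut
    else:
        keep = vals <= -r_cut
    keep &= ~np.isnan(vals)
    for i, j, r in zip(iu[keep], ju[keep], vals[keep]):
        graph.add_edge(regions[i], regions[j], r=float(r))
    return ThresholdedNetwork(
        group_label=corr.group_label,
        level=level,
        sign=sign,
        r_cut=r_cut,
        graph=graph,
    )


def all_confidence_networks(
    corr: CorrelationMatrix, thresholds: dict[str, float] | None = None
) -> dict[tuple[str, str], ThresholdedNetwork]:
    """All six networks (3 levels x 2 signs) for one group.

    The three negative networks share the single negative cutoff and hence
    identical edge sets; they are emitted per level for bookkeeping symmetry.
    """
    out: dict[tuple[str, str], ThresholdedNetwork] = {}
    for level in LEVELS:
        out[(level, "positive")] = threshold_network(corr, level, "positive", thresholds)
        out[(level, "negative")] = threshold_network(corr, level, "negative", thresholds)
    return out


def display_edge_list(corr: CorrelationMatrix, r_min: float = 0.6) -> pd.DataFrame:
    """Edge list at a visualisation-only cutoff (default r > 0.6).

    This export feeds external plotting tools; it plays no role in metric
    computation or community detection.
    """
    regions = corr.region_names
    arr = corr.values
    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            r = arr[i, j]
            if not np.isnan(r) and r > r_min:
                rows.append({"region_a": regions[i], "region_b": regions[j], "r": float(r)})
    return pd.DataFrame(rows, columns=["region_a", "region_b", "r"])


def edge_list_frame(net: ThresholdedNetwork) -> pd.DataFrame:
    """Edge list (region_a, region_b, r, level, sign) for TSV export."""
    rows = [
        {
            "region_a": a,
            "region_b": b,
            "r": d["r"],
            "level": net.level,
            "sign": net.sign,
        }
        for a, b, d in sorted(net.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["region_a", "region_b", "r", "level", "sign"])
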