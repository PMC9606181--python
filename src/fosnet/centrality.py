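"""Node centralities and composite hub classification.

Degree counts a region's supra-threshold correlations; betweenness
centrality is the fraction of all shortest paths in the network that pass
through the region, computed on the binarised primary-confidence network.
A region is a hub when it sits in the 80th percentile for degree in the
low, primary and high positive confidence networks *and* in the 80th
percentile for betweenness centrality — i.e. a region that is both broadly
coactive and a shortest-path bottleneck at every confidence level.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .networks import LEVELS, ThresholdedNetwork

__all__ = [
    "degree",
    "betweenness",
    "nearest_rank_percentile",
    "identify_hubs",
    "HubReport",
]


def degree(net: ThresholdedNetwork) -> dict[str, int]:
    """Number of incident edges per region; isolated regions score 0."""
    return {node: int(d) for node, d in net.graph.degree()}


def betweenness(net: ThresholdedNetwork, weighted: bool = False) -> dict[str, float]:
    """Normalised betweenness centrality via Brandes' accumulation.

    For node v, sums sigma_st(v)/sigma_st over ordered pairs (s, t) with
    s != t != v, normalised by (R-1)(R-2); pairs in different components
    contribute nothing.  Deterministic; exact for unweighted graphs.

    With ``weighted=True`` (off by default), shortest paths minimise the
    sum of edge lengths 1/|r|, so stronger correlations are shorter — the
    usual mapping for correlation-weighted connectomes.
    """
    graph = net.graph
    nodes = list(graph.nodes)
    R = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    if R < 3:
        return bc

    adj = {v: list(graph.neighbors(v)) for v in nodes}
    for s in nodes:
        # single-source shortest paths with path counting
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        if not weighted:
            dist = dict.fromkeys(nodes, -1)
            dist[s] = 0
            queue = deque([s])
            while queue:
                v = queue.popleft()
                stack.append(v)
                for w in adj[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        pred[w].append(v)
        else:
            # Dijkstra with path counting; edge length 1/|r|, exact-equality
            # tie handling so equal-length geodesics split the counts
            import heapq

            done: dict = {}
            seen = {s: 0.0}
            heap: list = [(0.0, 0, s, s)]
            tiebreak = 1
            while heap:
                d, _, prev, v = heapq.heappop(heap)
                if v in done:
                    continue
                sigma[v] += sigma[prev]
                stack.append(v)
                done[v] = d
                for w in adj[v]:
                    r = abs(graph[v][w].get("r", 1.0))
                    if r <= 0:
                        continue
                    vw = d + 1.0 / r
                    if w not in done and (w not in seen or vw < seen[w]):
                        seen[w] = vw
                        heapq.heappush(heap, (vw, tiebreak, v, w))
                        tiebreak += 1
                        sigma[w] = 0.0
                        pred[w] = [v]
                    elif vw == seen[w]:
                        sigma[w] += sigma[v]
                        pred[w].append(v)
        # back-propagation of dependencies
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    norm = (R - 1) * (R - 2)  # ordered-pair count excluding v
    return {v: bc[v] / norm for v in nodes}


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p/100 * N) (1-based,
    ascending).  No interpolation, so a tie at the cutoff qualifies."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    ordered = sorted(values)
    if not ordered:
        raise ValueError("empty value list")
    rank = int(np.ceil(percentile / 100.0 * len(ordered)))
    return ordered[max(rank, 1) - 1]


@dataclass(frozen=True)
class HubReport:
    """Composite hub classification with per-region criterion traces."""

    group_label: str
    hubs: tuple[str, ...]
    percentile: float
    degree_cutoffs: Mapping[str, float]  # per confidence level
    betweenness_cutoff: float
    trace: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)
    degrees: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    betweenness: Mapping[str, float] = field(default_factory=dict)


def identify_hubs(
    nets: Mapping[str, ThresholdedNetwork],
    percentile: float = 80.0,
    require_all_levels: bool = True,
) -> HubReport:
    """Classify hub regions from the three positive confidence networks.

    Parameters
    ----------
    nets
        Mapping with keys 'low', 'primary', 'high' over an identical region
        panel (positive-sign networks).
    percentile
        Percentile cutoff (default 80), nearest-rank over all R regions.
    require_all_levels
        If True (default), the degree criterion must hold in all three
        networks; if False, only in the primary network.  Betweenness is
        always evaluated on the primary network.
    """
    missing = [lvl for lvl in LEVELS if lvl not in nets]
    if missing:
        raise ValueError(f"missing confidence network(s): {missing}")
    node_sets = {tuple(nets[lvl].region_names) for lvl in LEVELS}
    if len(node_sets) != 1:
        raise ValueError("confidence networks must share one region panel")
    regions = next(iter(node_sets))

    degrees = {lvl: degree(nets[lvl]) for lvl in LEVELS}
    btw = betweenness(nets["primary"])

    if all(d == 0 for d in degrees["low"].values()):
        warnings.warn(
            f"group {nets['primary'].group_label!r}: all degrees zero, no hubs",
            UserWarning,
            stacklevel=2,
        )

    deg_cut = {
        lvl: nearest_rank_percentile(list(degrees[lvl].values()), percentile)
        for lvl in LEVELS
    }
    btw_cut = nearest_rank_percentile(list(btw.values()), percentile)

    levels_required = LEVELS if require_all_levels else ("primary",)
    trace: dict[str, dict[str, bool]] = {}
    hubs: list[str] = []
    for region in regions:
        checks = {
            f"degree_{lvl}": degrees[lvl][region] >= deg_cut[lvl]
            for lvl in LEVELS
        }
        checks["betweenness"] = btw[region] >= btw_cut
        trace[region] = checks
        qualifies = all(checks[f"degree_{lvl}"] for lvl in levels_required)
        qualifies = qualifies and checks["betweenness"]
        # a region with no connections at all is never a hub
        if qualifies and degrees["low"][region] > 0:
            hubs.append(region)
    return HubReport(
        group_label=nets["primary"].group_label,
        hubs=tuple(hubs),
        percentile=percentile,
        degree_cutoffs=deg_cut,
        betweenness_cutoff=btw_cut,
        trace=trace,
        degrees=degrees,
        betweenness=btw,
    )
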