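"""Validation benchmarks: oracle comparisons and recovery simulations.

These routines re-derive every quantitative claim the package makes from
scratch — exhaustive shortest-path and partition oracles on small graphs,
planted-structure recovery on synthetic cohorts, null-calibration of the
ANOVA stage, and end-to-end determinism — and return plain dictionaries of
measured numbers.  The oracles here are deliberately written against
independent machinery (explicit path enumeration via networkx, literal
double sums, hand-built design matrices) rather than the implementation
code they check.
"""

from __future__ import annotations

import hashlib
import itertools
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import centrality, community, hierarchy
from .config import RunConfig
from .correlation import CorrelationMatrix, correlation_matrix
from .design import StudyDesign
from .networks import LEVELS, ThresholdedNetwork, all_confidence_networks, threshold_network
from .pipeline import run_pipeline
from .simulate import (
    generate_cohort,
    hub_recovery_structure,
    planted_modules_structure,
)

__all__ = [
    "betweenness_oracle_benchmark",
    "modularity_oracle_benchmark",
    "module_recovery_benchmark",
    "hub_recovery_benchmark",
    "invariant_benchmark",
    "anova_benchmark",
    "pipeline_defaults_and_determinism",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_net(graph: nx.Graph) -> ThresholdedNetwork:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    return ThresholdedNetwork(group_label="bench", level="primary", sign="positive", r_cut=0.83, graph=g)


def _brute_force_betweenness(graph: nx.Graph) -> dict:
    """Oracle: enumerate every shortest path explicitly per (s, t) pair."""
    nodes = list(graph.nodes)
    R = len(nodes)
    acc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.permutations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            acc[v] += sum(1 for p in paths if v in p[1:-1]) / len(paths)
    norm = (R - 1) * (R - 2)
    return {v: acc[v] / norm for v in nodes}


def _one_group_cohort(planted, regions, n, seed):
    label = "WT:vehicle:naive"
    design = StudyDesign(
        genotypes=("WT",),
        treatments=("vehicle",),
        stress_conditions=("naive",),
        n_per_cell={label: n},
        region_names=tuple(regions),
        seed=seed,
    )
    return generate_cohort(design, planted)[label]


def _adjusted_rand(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(a), list(b)))


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

def betweenness_oracle_benchmark(seed: int = 0, n_random: int = 200, max_random_nodes: int = 12) -> dict:
    """Max |betweenness - exhaustive oracle| over all connected graphs with
    <= 6 nodes plus random connected graphs with <= ``max_random_nodes``."""
    rng = np.random.default_rng(seed)
    graphs = [
        g
        for g in nx.graph_atlas_g()
        if 3 <= g.number_of_nodes() <= 6 and nx.is_connected(g)
    ]
    n_atlas = len(graphs)
    while len(graphs) < n_atlas + n_random:
        n = int(rng.integers(4, max_random_nodes + 1))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.6)), seed=int(rng.integers(2**31)))
        graphs.append(g)
    max_err = 0.0
    for g in graphs:
        mine = centrality.betweenness(_as_net(g))
        oracle = _brute_force_betweenness(g)
        for v in g.nodes:
            max_err = max(max_err, abs(mine[v] - oracle[v]))
    return {"n_graphs": len(graphs), "n_atlas": n_atlas, "max_abs_error": max_err}


def modularity_oracle_benchmark(seed: int = 0, n_random: int = 20) -> dict:
    """Spectral Q vs the best partition found by exhaustive enumeration on
    small graphs, plus the Q formula against a literal double sum."""
    rng = np.random.default_rng(seed)
    fixtures = []
    atlas = [
        g
        for g in nx.graph_atlas_g()
        if 3 <= g.number_of_nodes() <= 6 and nx.is_connected(g) and g.number_of_edges() > 0
    ]
    for g in atlas[:: max(1, len(atlas) // 40)]:
        w = nx.to_numpy_array(g)
        fixtures.append(w)
    for _ in range(n_random):
        n = int(rng.integers(5, 9))
        mask = rng.uniform(size=(n, n)) < 0.5
        w = rng.uniform(0.1, 1.0, size=(n, n)) * mask
        w = np.triu(w, 1)
        w = w + w.T
        if w.sum() == 0:
            w[0, 1] = w[1, 0] = 1.0
        fixtures.append(w)

    worst_ratio = np.inf
    formula_err = 0.0
    for w in fixtures:
        names = tuple(f"R{i}" for i in range(w.shape[0]))
        net = community.WeightedNetwork(region_names=names, weights=w)
        spectral = community.spectral_communities(net)
        best = community.exhaustive_best_partition(net)
        if best.Q > 1e-12:
            worst_ratio = min(worst_ratio, spectral.Q / best.Q)
        else:
            worst_ratio = min(worst_ratio, 1.0 if spectral.Q >= -1e-12 else 0.0)
        # literal double-sum check on the spectral labels
        labels = spectral.labels
        two_m = w.sum()
        k = w.sum(axis=1)
        naive = 0.0
        for i, ri in enumerate(names):
            for j, rj in enumerate(names):
                if labels[ri] == labels[rj]:
                    naive += w[i, j] - k[i] * k[j] / two_m
        naive /= two_m
        formula_err = max(formula_err, abs(naive - community.modularity_score(net, labels)))
    return {
        "n_graphs": len(fixtures),
        "min_q_ratio": float(worst_ratio),
        "q_formula_max_error": float(formula_err),
    }


def module_recovery_benchmark(seed: int = 0, n_seeds: int = 50, n_animals: int = 40) -> dict:
    """Planted 3-module recovery (within-r 0.8 / between-r 0.1, 60 regions)
    by spectral communities and the 0.70 tree cut, over ``n_seeds`` cohorts."""
    regions = tuple(f"region_{i + 1:02d}" for i in range(60))
    planted = planted_modules_structure(regions)
    truth = planted.module_labels(regions)
    ari_spectral, ari_tree, count3 = [], [], 0
    for k in range(n_seeds):
        table = _one_group_cohort(planted, regions, n_animals, seed=seed * 100003 + k)
        corr = correlation_matrix(table)
        spectral = community.spectral_communities(
            community.WeightedNetwork.from_correlation(corr)
        )
        ari_spectral.append(_adjusted_rand(truth, spectral.label_array(regions)))
        dend = hierarchy.complete_linkage(hierarchy.euclidean_distance_matrix(corr))
        labels = hierarchy.tree_cut(dend, 0.70)
        lab = [labels[r] for r in regions]
        ari_tree.append(_adjusted_rand(truth, lab))
        count3 += int(len(set(lab)) == 3)
    return {
        "n_seeds": n_seeds,
        "ari_spectral_mean": float(np.mean(ari_spectral)),
        "ari_tree_cut_mean": float(np.mean(ari_tree)),
        "tree_cut_count3_fraction": count3 / n_seeds,
    }


def hub_recovery_benchmark(seed: int = 0, n_seeds: int = 50, n_animals: int = 40) -> dict:
    """Planted-hub recovery (hub_extra_r 0.15, 12 hubs over 60 regions)."""
    regions = tuple(f"region_{i + 1:02d}" for i in range(60))
    planted = hub_recovery_structure(regions)
    truth = set(planted.hub_regions)
    scores = []
    for k in range(n_seeds):
        table = _one_group_cohort(planted, regions, n_animals, seed=seed * 99991 + k)
        corr = correlation_matrix(table)
        nets = {lvl: threshold_network(corr, lvl, "positive") for lvl in LEVELS}
        detected = set(centrality.identify_hubs(nets).hubs)
        union = detected | truth
        scores.append(len(detected & truth) / len(union) if union else 1.0)
    return {"n_seeds": n_seeds, "jaccard_mean": float(np.mean(scores))}


def invariant_benchmark(seed: int = 0, n_inputs: int = 500) -> dict:
    """Threshold nestedness and cut-profile monotonicity on random inputs."""
    rng = np.random.default_rng(seed)
    nest_violations = 0
    for _ in range(n_inputs):
        n = int(rng.integers(5, 15))
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        names = [f"R{i}" for i in range(n)]
        cm = CorrelationMatrix(group_label="b", r=pd.DataFrame(m, index=names, columns=names), n_animals=8)
        nets = all_confidence_networks(cm)
        for sign in ("positive", "negative"):
            low, primary, high = (nets[(lvl, sign)].edges for lvl in LEVELS)
            if not (high <= primary <= low):
                nest_violations += 1
    mono_violations = 0
    for _ in range(n_inputs):
        n = int(rng.integers(4, 12))
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dist = hierarchy.DistanceMatrix(
            group_label="b", d=pd.DataFrame(d, index=[f"P{i}" for i in range(n)], columns=[f"P{i}" for i in range(n)])
        )
        counts = hierarchy.cut_profile(hierarchy.complete_linkage(dist)).module_counts
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            mono_violations += 1
    return {
        "n_inputs": n_inputs,
        "nestedness_violations": nest_violations,
        "monotonicity_violations": mono_violations,
    }


def _type3_f_oracle(data: pd.DataFrame, response: str, factors) -> dict:
    """Independent Type-III F computation from hand-built design matrices."""
    def sum_code(series):
        levels = sorted(series.unique())
        return np.column_stack(
            [
                (series == lv).astype(float).to_numpy()
                - (series == levels[-1]).astype(float).to_numpy()
                for lv in levels[:-1]
            ]
        )

    mains = {f: sum_code(data[f]) for f in factors}
    blocks = {}
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            block = mains[combo[0]]
            for f in combo[1:]:
                block = np.column_stack(
                    [
                        block[:, i] * mains[f][:, j]
                        for i in range(block.shape[1])
                        for j in range(mains[f].shape[1])
                    ]
                )
            blocks[":".join(combo)] = block
    y = data[response].to_numpy(dtype=float)
    ones = np.ones((len(y), 1))

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    x_full = np.column_stack([ones] + list(blocks.values()))
    rss_full = rss(x_full)
    df_den = len(y) - x_full.shape[1]
    out = {}
    for effect, block in blocks.items():
        x_red = np.column_stack([ones] + [b for nm, b in blocks.items() if nm != effect])
        out[effect] = ((rss(x_red) - rss_full) / block.shape[1]) / (rss_full / df_den)
    return out


def anova_benchmark(seed: int = 0, n_reps: int = 200, n_per_cell: int = 8) -> dict:
    """F agreement with the matrix oracle on fixed unbalanced fixtures, and
    the empirical type-I error rate of the three-way interaction under the
    null (with its exact binomial 95% acceptance interval at alpha 0.05)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    factors = ("genotype", "treatment", "stress")

    def cohort(sizes, mu=100.0):
        rows = []
        it = iter(sizes)
        for g in ("WT", "KO"):
            for t in ("veh", "dfp"):
                for s in ("naive", "PST"):
                    for v in rng.normal(mu, 15.0, next(it)):
                        rows.append(
                            {"genotype": g, "treatment": t, "stress": s, "density": v}
                        )
        return pd.DataFrame(rows)

    max_f_err = 0.0
    for sizes in ([5, 6, 7, 8, 9, 8, 7, 6], [5, 5, 9, 9, 6, 8, 7, 5]):
        data = cohort(sizes)
        mine = {r.effect_name: r.F for r in anova_mod.factorial_anova(data, factors=factors)}
        oracle = _type3_f_oracle(data, "density", factors)
        for effect, f in oracle.items():
            max_f_err = max(max_f_err, abs(mine[effect] - f))

    hits = 0
    for _ in range(n_reps):
        data = cohort([n_per_cell] * 8)
        results = {r.effect_name: r for r in anova_mod.factorial_anova(data, factors=factors)}
        if results["genotype:treatment:stress"].p < 0.05:
            hits += 1
    lo = int(stats.binom.ppf(0.025, n_reps, 0.05))
    hi = int(stats.binom.ppf(0.975, n_reps, 0.05))
    return {
        "max_f_error": max_f_err,
        "n_reps": n_reps,
        "type1_hits": hits,
        "type1_rate": hits / n_reps,
        "binomial_95_interval": (lo / n_reps, hi / n_reps),
    }


def pipeline_defaults_and_determinism(out_root: str | Path, seed: int = 0, n_regions: int = 60) -> dict:
    """Two fresh full runs: manifest default constants + byte-identity."""
    out_root = Path(out_root)
    config = RunConfig(seed=seed, n_regions=n_regions)
    hashes = []
    manifests = []
    for tag in ("a", "b"):
        out = out_root / f"run_{tag}"
        manifests.append(run_pipeline(config, out))
        digest = hashlib.sha256()
        for name in sorted(p.name for p in out.iterdir()):
            digest.update(name.encode())
            digest.update((out / name).read_bytes())
        hashes.append(digest.hexdigest())
    cfg = manifests[0]["config"]
    return {
        "thresholds": cfg["thresholds"],
        "hub_percentile": cfg["hub_percentile"],
        "cut_fraction": cfg["cut_fraction"],
        "alpha": cfg["alpha"],
        "n_groups": len(manifests[0]["groups"]),
        "byte_identical": hashes[0] == hashes[1],
    }
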