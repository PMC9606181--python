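"""End-to-end orchestration of the coactivation-network pipeline.

`run_pipeline` takes a `RunConfig`, obtains per-group activity tables
(either read from files or generated synthetically with planted ground
truth), fits the `CoactivationNetwork` model per group, optionally runs the
factorial ANOVA stage, and writes every artefact plus a manifest.  Outputs
are deterministic: identical config + seed produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .anova import RegionalAnova
from .config import RunConfig
from .io import (
    read_region_tables,
    tables_to_long,
    write_design_sidecar,
    write_graphml,
    write_long_tsv,
    write_wide_csv,
)
from .model import CoactivationNetwork
from .networks import LEVELS, display_edge_list, edge_list_frame
from .simulate import RegionActivityTable, default_design, generate_cohort, planted_hubs_structure, summarize_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_tables"]

_FLOAT_FMT = "%.10g"


def load_tables(config: RunConfig) -> dict[str, RegionActivityTable]:
    """Input tables per group: from files, or the default synthetic cohort."""
    if config.input_paths:
        tables: dict[str, RegionActivityTable] = {}
        for path in config.input_paths:
            for label, table in read_region_tables(path).items():
                if label in tables:
                    raise ValueError(f"duplicate group {label!r} across input files")
                tables[label] = table
        return tables
    design = default_design(seed=config.seed, n_regions=config.n_regions)
    planted = planted_hubs_structure(design.region_names)
    return generate_cohort(design, planted)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage for every group and write artefacts + manifest.

    Groups with fewer than 2 animals are skipped with a logged reason.
    Returns the manifest dictionary.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables = load_tables(config)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "groups": {},
        "skipped_groups": {},
        "files": [],
    }

    def save_frame(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        sep = "\t" if name.endswith(".tsv") else ","
        frame.to_csv(path, sep=sep, float_format=_FLOAT_FMT, **kwargs)
        manifest["files"].append(name)

    if config.synthetic and not config.input_paths:
        design = default_design(seed=config.seed, n_regions=config.n_regions)
        planted = planted_hubs_structure(design.region_names)
        write_design_sidecar(design, planted, out / "design.json")
        manifest["files"].append("design.json")
        for label in sorted(tables):
            write_wide_csv(tables[label], out / f"densities_{_slug(label)}.csv")
            manifest["files"].append(f"densities_{_slug(label)}.csv")
        write_long_tsv(tables, out / "densities_long.tsv")
        manifest["files"].append("densities_long.tsv")

    for label in sorted(tables):
        if tables[label].n_animals < 2:
            logger.warning("skipping group %s: n=%d < 2", label, tables[label].n_animals)
            manifest["skipped_groups"][label] = f"n={tables[label].n_animals} < 2"
    usable = {k: v for k, v in tables.items() if k not in manifest["skipped_groups"]}

    summary = summarize_table(usable)
    save_frame(summary, "group_means_sem.csv", index=False)

    for label in sorted(usable):
        table = usable[label]
        slug = _slug(label)
        res = CoactivationNetwork(table).fit(
            thresholds=config.thresholds,
            hub_percentile=config.hub_percentile,
            sign_policy=config.sign_policy,
            cut_fraction=config.cut_fraction,
            cut_fractions=config.cut_fractions,
            require_all_levels=config.require_all_levels,
            include_diagonal=config.include_diagonal,
        )
        save_frame(res.corr.r, f"correlation_{slug}.csv", index=True)
        edge_frames = []
        for (level, sign), net in sorted(res.networks.items()):
            edge_frames.append(edge_list_frame(net))
            write_graphml(net, out / f"network_{slug}_{level}_{sign}.graphml")
            manifest["files"].append(f"network_{slug}_{level}_{sign}.graphml")
        nonempty = [f for f in edge_frames if not f.empty]
        all_edges = (
            pd.concat(nonempty, ignore_index=True) if nonempty else edge_frames[0]
        )
        save_frame(all_edges, f"edges_{slug}.tsv", index=False)
        save_frame(res.node_metrics(), f"node_metrics_{slug}.tsv", index=False)

        hub_payload = {
            "group": label,
            "hubs": list(res.hubs),
            "percentile": res.hub_report.percentile,
            "degree_cutoffs": {k: float(v) for k, v in res.hub_report.degree_cutoffs.items()},
            "betweenness_cutoff": float(res.hub_report.betweenness_cutoff),
        }
        (out / f"hubs_{slug}.json").write_text(
            json.dumps(hub_payload, indent=2, sort_keys=True) + "\n"
        )
        manifest["files"].append(f"hubs_{slug}.json")

        modules = pd.DataFrame(
            {
                "region": list(res.communities.labels),
                "module_id": list(res.communities.labels.values()),
            }
        )
        save_frame(modules, f"modules_spectral_{slug}.tsv", index=False)
        (out / f"communities_{slug}.json").write_text(
            json.dumps(
                {
                    "group": label,
                    "Q": res.Q,
                    "n_modules": res.communities.n_modules,
                    "sign_policy": config.sign_policy,
                    "split_trace": [list(t) for t in res.communities.split_trace],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        manifest["files"].append(f"communities_{slug}.json")
        save_frame(
            display_edge_list(res.corr), f"edges_display_{slug}.tsv", index=False
        )
        tree_labels = pd.DataFrame(
            {
                "region": list(res.tree_cut_labels),
                "module_id": list(res.tree_cut_labels.values()),
            }
        )
        save_frame(tree_labels, f"modules_tree_cut_{slug}.tsv", index=False)
        merge_table = pd.DataFrame(
            res.dendrogram.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )
        merge_table.insert(0, "step", range(1, len(merge_table) + 1))
        save_frame(merge_table, f"dendrogram_{slug}.tsv", index=False)
        save_frame(res.cut_profile.frame(), f"cut_profile_{slug}.csv", index=False)
        order = list(res.dendrogram.leaf_order())
        save_frame(
            res.distance.d.loc[order, order], f"distance_ordered_{slug}.csv", index=True
        )

        counts = res.edge_counts()
        manifest["groups"][label] = {
            "n_animals": table.n_animals,
            "n_regions": len(res.corr.region_names),
            "edges": {f"{lvl}_{sign}": counts[(lvl, sign)] for lvl in LEVELS for sign in ("positive", "negative")},
            "hubs": list(res.hubs),
            "n_modules_spectral": res.communities.n_modules,
            "Q": res.Q,
            "n_modules_tree_cut": len(set(res.tree_cut_labels.values())),
            "excluded_regions": list(res.distance.excluded_regions),
        }
        logger.info(
            "group %s: %d regions, %d primary edges, %d hubs, %d modules (Q=%.3f)",
            label,
            len(res.corr.region_names),
            counts[("primary", "positive")],
            len(res.hubs),
            res.communities.n_modules,
            res.Q,
        )

    if config.run_anova:
        long = tables_to_long(
            {k: v for k, v in tables.items() if v.n_animals >= 2}
        )
        if {"genotype", "treatment", "stress"} <= set(long.columns):
            results = RegionalAnova.from_long(long).fit(alpha=config.alpha)
            save_frame(results.effects_frame(), "anova_effects.csv", index=False)
            save_frame(results.contrasts_frame(), "anova_contrasts.csv", index=False)
            manifest["anova"] = {
                "alpha": config.alpha,
                "regions": int(results.effects_frame()["region"].nunique()),
                "note": "per-region tests are not corrected across regions",
            }

    manifest["files"] = sorted(manifest["files"])
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _slug(label: str) -> str:
    return label.replace(":", "_").replace("/", "_")
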