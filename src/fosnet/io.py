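"""Reading and writing regional activity tables and network artefacts.

Two tabular dialects are accepted and auto-detected from the header:

* **wide** — one file per group: rows = animals, columns = regions, a
  leading ``animal`` index column; densities in cells/mm^2.
* **long** — one file for the whole cohort with columns
  (animal, group, region, density).

Empty cells and the token ``NA`` are treated as missing.  Negative
densities and duplicated (animal, region) pairs are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .simulate import RegionActivityTable

__all__ = [
    "read_region_tables",
    "write_wide_csv",
    "write_long_tsv",
    "tables_to_long",
    "write_graphml",
]

_LONG_COLUMNS = {"animal", "group", "region", "density"}
_NA_TOKENS = ["NA", "na", ""]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_region_tables(
    path: str | Path, group_label: str | None = None
) -> dict[str, RegionActivityTable]:
    """Read one CSV/TSV file into per-group activity tables.

    The dialect is detected from the header: a file whose columns include
    (animal, group, region, density) is long format; anything else is a
    wide animals x regions table, which requires ``group_label`` (or takes
    the file stem as the group name).
    """
    path = Path(path)
    sep = _sep_for(path)
    header = path.read_text().splitlines()[0].split(sep)
    names = [c.strip() for c in header[1:]]  # first column is the index/animal
    dupes = sorted({c for c in names if names.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated region column(s) {dupes}")
    columns = {c.strip().lower() for c in header}
    if _LONG_COLUMNS <= columns:
        return _read_long(path)
    label = group_label if group_label is not None else path.stem
    return {label: _read_wide(path, label)}


def _validate(frame: pd.DataFrame, where: str) -> None:
    if frame.columns.duplicated().any():
        dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ValueError(f"{where}: duplicated region column(s) {dupes}")
    numeric = frame.to_numpy(dtype=float)
    if (numeric < 0).any():
        raise ValueError(f"{where}: negative density values")


def _read_wide(path: Path, label: str) -> RegionActivityTable:
    frame = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=_NA_TOKENS, keep_default_na=True
    )
    frame.index = frame.index.astype(str)
    frame.columns = [str(c) for c in frame.columns]
    _validate(frame, str(path))
    return RegionActivityTable(group_label=label, values=frame.astype(float))


def _read_long(path: Path) -> dict[str, RegionActivityTable]:
    frame = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_TOKENS)
    frame.columns = [c.strip().lower() for c in frame.columns]
    dup = frame.duplicated(subset=["group", "animal", "region"])
    if dup.any():
        first = frame.loc[dup, ["animal", "region"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate (animal, region) entry "
            f"({first['animal']!r}, {first['region']!r})"
        )
    if (frame["density"].dropna() < 0).any():
        raise ValueError(f"{path}: negative density values")
    tables: dict[str, RegionActivityTable] = {}
    region_order = list(dict.fromkeys(frame["region"]))
    for label, sub in frame.groupby("group", sort=False):
        wide = sub.pivot(index="animal", columns="region", values="density")
        wide = wide.reindex(columns=[r for r in region_order if r in wide.columns])
        wide.index = wide.index.astype(str)
        wide = wide.astype(float)
        tables[str(label)] = RegionActivityTable(group_label=str(label), values=wide)
    return tables


def tables_to_long(tables: Mapping[str, RegionActivityTable]) -> pd.DataFrame:
    """Stack per-group tables into (animal, group, region, density) long form,
    with genotype/treatment/stress columns split from ':'-joined labels."""
    frames = [tables[g].to_long() for g in tables]
    long = pd.concat(frames, ignore_index=True)
    parts = long["group"].str.split(":", expand=True)
    if parts.shape[1] == 3:
        long[["genotype", "treatment", "stress"]] = parts
    return long


def write_wide_csv(table: RegionActivityTable, path: str | Path) -> None:
    frame = table.values.copy()
    frame.index.name = "animal"
    frame.to_csv(path, float_format="%.6g")


def write_long_tsv(tables: Mapping[str, RegionActivityTable], path: str | Path) -> None:
    long = tables_to_long(tables)
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_design_sidecar(design, planted, path: str | Path) -> None:
    """JSON sidecar capturing the design, planted structure and seed."""
    payload = {
        "design": {
            "genotypes": list(design.genotypes),
            "treatments": list(design.treatments),
            "stress_conditions": list(design.stress_conditions),
            "n_per_cell": dict(design.n_per_cell),
            "region_names": list(design.region_names),
            "seed": design.seed,
        },
        "planted": {
            "module_assignment": {k: int(v) for k, v in planted.module_assignment.items()},
            "within_module_r": planted.within_module_r,
            "between_module_r": planted.between_module_r,
            "hub_regions": sorted(planted.hub_regions),
            "hub_extra_r": planted.hub_extra_r,
            "group_effects": {f"{g}|{r}": v for (g, r), v in planted.group_effects.items()},
            "base_mean": {k: float(v) for k, v in planted.base_mean.items()},
            "noise_cv": planted.noise_cv,
            "r_max": planted.r_max,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_graphml(net, path: str | Path) -> None:
    """GraphML export of a thresholded network with r edge attributes."""
    nx.write_graphml(net.graph, str(path))
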