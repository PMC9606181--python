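"""Inter-regional Pearson correlation matrices.

One matrix per experimental group: each entry is the across-animal Pearson
correlation of Fos densities between two regions.  Computation is
pairwise-complete (each pair uses the animals with both regions observed),
because in real cohorts individual regions are occasionally unquantifiable
for an animal.  A region with zero variance across animals has no defined
correlation; its row and column are stored as missing (NaN), never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CorrelationMatrix", "correlation_matrix", "ZeroVarianceWarning", "LowSupportWarning"]


class ZeroVarianceWarning(UserWarning):
    """A region was constant across animals; its correlations are undefined."""


class LowSupportWarning(UserWarning):
    """Some region pairs had fewer than 3 complete observations."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric R x R Pearson matrix with unit diagonal for one group."""

    group_label: str
    r: pd.DataFrame
    n_animals: int
    low_support_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.r.columns)

    @property
    def values(self) -> np.ndarray:
        return self.r.to_numpy()

    def missing_regions(self) -> list[str]:
        """Regions whose whole off-diagonal row is undefined."""
        off = self.r.to_numpy().copy()
        np.fill_diagonal(off, np.nan)
        return [c for c, allnan in zip(self.r.columns, np.isnan(off).all(axis=1)) if allnan]


def correlation_matrix(table) -> CorrelationMatrix:
    """Pearson correlation of regional densities across animals in one group.

    Parameters
    ----------
    table : RegionActivityTable
        Animals x regions densities; NaN cells mark unquantified regions.

    Returns
    -------
    CorrelationMatrix with exact unit diagonal (where defined), symmetric,
    entries in [-1, 1].  Pairs supported by fewer than 3 complete animals
    are recorded in ``low_support_pairs`` and a warning is emitted; constant
    regions yield missing rows/columns with a :class:`ZeroVarianceWarning`.
    """
    values: pd.DataFrame = table.values
    if values.shape[0] < 2:
        raise ValueError("correlation needs at least 2 animals")

    with warnings.catch_warnings():
        # pandas delegates to numpy which warns on 0/0 for constant columns;
        # we replace that with a named, region-specific warning below.
        warnings.simplefilter("ignore", RuntimeWarning)
        r = values.corr(method="pearson", min_periods=2)

    counts = values.notna().astype(int)
    support = counts.T @ counts  # complete observations per pair
    low = set()
    cols = list(values.columns)
    sup = support.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if sup[i, j] < 3:
                low.add((cols[i], cols[j]))
    if low:
        warnings.warn(
            f"{len(low)} region pair(s) have fewer than 3 complete observations",
            LowSupportWarning,
            stacklevel=2,
        )

    constant = [c for c in cols if values[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(
            f"zero-variance region(s) {constant}: correlations undefined",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        r.loc[constant, :] = np.nan
        r.loc[:, constant] = np.nan

    arr = r.to_numpy()
    np.clip(arr, -1.0, 1.0, out=arr)
    np.fill_diagonal(arr, [np.nan if c in constant else 1.0 for c in cols])
    r = pd.DataFrame(arr, index=cols, columns=cols)

    return CorrelationMatrix(
        group_label=table.group_label,
        r=r,
        n_animals=int(values.shape[0]),
        low_support_pairs=frozenset(low),
    )
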