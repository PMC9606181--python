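"""Factorial ANOVA with Bonferroni-corrected pairwise contrasts on
regional Fos densities.

Each region is analysed separately with a two- or three-factor
between-subjects ANOVA (genotype x treatment x stress in the full design).
Because cell sizes vary (n = 5-9), sums of squares are Type III with
sum-to-zero factor coding, the convention of behavioural-neuroscience
reporting.  Pairwise group contrasts use t statistics on the pooled
residual variance with Bonferroni adjustment (p_adj = min(1, m * p)).
Per-region analyses are not corrected across regions; the report notes
this so users can layer an FDR step on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "PosthocContrast",
    "factorial_anova",
    "bonferroni_posthoc",
    "RegionalAnova",
    "RegionalAnovaResults",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    """One main effect or interaction from a factorial ANOVA."""

    effect_name: str
    F: float
    df_num: int
    df_den: int
    p: float

    def __str__(self) -> str:  # printed like F(1,50) = 9.14, p = 0.004
        return f"{self.effect_name}: F({self.df_num},{self.df_den}) = {self.F:.3g}, p = {self.p:.3g}"


@dataclass(frozen=True)
class PosthocContrast:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p: float
    p_adjusted: float
    significant: bool


def _check_cells(data: pd.DataFrame, factors: Sequence[str]) -> None:
    counts = data.groupby(list(factors), observed=True).size()
    levels = [data[f].unique() for f in factors]
    n_cells = int(np.prod([len(lv) for lv in levels]))
    if len(counts) < n_cells:
        have = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        from itertools import product

        missing = [c for c in product(*levels) if c not in have]
        raise ValueError(f"empty design cell(s): {missing}")
    if (counts >= 2).sum() < 2 or len(data) - n_cells <= 0:
        raise ValueError("no residual degrees of freedom (need >= 2 cells with n >= 2)")


def factorial_anova(
    data: pd.DataFrame,
    response: str = "density",
    factors: Sequence[str] = ("genotype", "treatment", "stress"),
) -> list[AnovaResult]:
    """Between-subjects factorial ANOVA for one region.

    Parameters
    ----------
    data
        Long-format per-animal table with one row per animal, containing
        ``response`` and the factor columns.
    factors
        Two or three between-subject factor names.

    Returns main effects and all interactions, Type III / sum-to-zero.
    A fully constant response returns F = 0, p = 1 for every effect.
    """
    if len(factors) not in (2, 3):
        raise ValueError("factorial_anova supports 2 or 3 factors")
    data = data.dropna(subset=[response, *factors]).copy()
    _check_cells(data, factors)

    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        # zero variance everywhere: every F is 0/0; define as no effect
        effects = _effect_names(factors)
        df_den = len(y) - int(
            np.prod([data[f].nunique() for f in factors])
        )
        return [
            AnovaResult(effect_name=e, F=0.0, df_num=_df_num(data, factors, e), df_den=df_den, p=1.0)
            for e in effects
        ]

    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"{response} ~ {terms}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=3)

    out: list[AnovaResult] = []
    df_den = int(table.loc["Residual", "df"])
    for effect in _effect_names(factors):
        key = ":".join(f"C({f}, Sum)" for f in effect.split(":"))
        row = table.loc[key]
        out.append(
            AnovaResult(
                effect_name=effect,
                F=float(row["F"]),
                df_num=int(row["df"]),
                df_den=df_den,
                p=float(row["PR(>F)"]),
            )
        )
    return out


def _effect_names(factors: Sequence[str]) -> list[str]:
    names = []
    for k in range(1, len(factors) + 1):
        for combo in combinations(factors, k):
            names.append(":".join(combo))
    return names


def _df_num(data: pd.DataFrame, factors: Sequence[str], effect: str) -> int:
    df = 1
    for f in effect.split(":"):
        df *= data[f].nunique() - 1
    return df


def bonferroni_posthoc(
    data: pd.DataFrame,
    response: str = "density",
    group_col: str = "group",
    comparisons: Sequence[tuple[str, str]] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[PosthocContrast]:
    """Bonferroni-adjusted pairwise contrasts on the pooled residual variance.

    The pooled error is the one-way cell-means residual mean square (the
    same error term as the factorial ANOVA's residual).  With ``m``
    requested comparisons, p_adjusted = min(1, m * p).
    """
    groups = {g: sub[response].to_numpy(dtype=float) for g, sub in data.groupby(group_col, observed=True)}
    if comparisons is None:
        comparisons = list(combinations(sorted(groups), 2))
    m = len(comparisons)
    if m == 0:
        return []

    n_total = sum(len(v) for v in groups.values())
    df_err = n_total - len(groups)
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom for the pooled error")
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / df_err

    out: list[PosthocContrast] = []
    for a, b in comparisons:
        if a not in groups or b not in groups:
            raise ValueError(f"unknown group in comparison ({a!r}, {b!r})")
        va, vb = groups[a], groups[b]
        diff = float(va.mean() - vb.mean())
        if mse == 0.0:
            t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = float(np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb))))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df_err))
        p_adj = min(1.0, m * p)
        out.append(
            PosthocContrast(
                group_a=a,
                group_b=b,
                mean_diff=diff,
                t=float(t),
                p=p,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model/Results facade over all regions
# ---------------------------------------------------------------------------

class RegionalAnova:
    """Factorial ANOVA model for a long-format multi-region dataset.

    Parameters
    ----------
    data
        Long format: one row per (animal, region) with columns ``region``,
        ``density`` and the factor columns.
    factors
        Between-subject factors (default the full genotype x treatment x
        stress design).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "density",
        factors: Sequence[str] = ("genotype", "treatment", "stress"),
        region_col: str = "region",
    ):
        self.data = data
        self.response = response
        self.factors = tuple(factors)
        self.region_col = region_col

    @classmethod
    def from_long(cls, data: pd.DataFrame, **kwargs) -> "RegionalAnova":
        return cls(data, **kwargs)

    def fit(self, alpha: float = DEFAULT_ALPHA, posthoc: bool = True) -> "RegionalAnovaResults":
        effects: dict[str, list[AnovaResult]] = {}
        contrasts: dict[str, list[PosthocContrast]] = {}
        df = self.data.copy()
        if "group" not in df.columns:
            df["group"] = df[list(self.factors)].astype(str).agg(":".join, axis=1)
        for region, sub in df.groupby(self.region_col, observed=True):
            effects[region] = factorial_anova(sub, self.response, self.factors)
            if posthoc:
                contrasts[region] = bonferroni_posthoc(
                    sub, self.response, "group", alpha=alpha
                )
        return RegionalAnovaResults(self, effects, contrasts, alpha)


class RegionalAnovaResults:
    """Per-region ANOVA tables and Bonferroni contrasts."""

    def __init__(self, model, effects, contrasts, alpha):
        self.model = model
        self.effects = effects
        self.contrasts = contrasts
        self.alpha = alpha

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for region, results in self.effects.items():
            for res in results:
                rows.append(
                    {
                        "region": region,
                        "effect": res.effect_name,
                        "F": res.F,
                        "df_num": res.df_num,
                        "df_den": res.df_den,
                        "p": res.p,
                        "significant": res.p < self.alpha,
                    }
                )
        return pd.DataFrame(rows)

    def contrasts_frame(self) -> pd.DataFrame:
        rows = []
        for region, contrasts in self.contrasts.items():
            for c in contrasts:
                rows.append(
                    {
                        "region": region,
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "mean_diff": c.mean_diff,
                        "t": c.t,
                        "p": c.p,
                        "p_adjusted": c.p_adjusted,
                        "significant": c.significant,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.effects_frame()
        sig = frame[frame["significant"]]
        lines = [
            f"Factorial ANOVA ({' x '.join(self.model.factors)}), "
            f"Type III sums of squares, alpha = {self.alpha}",
            f"Regions analysed: {frame['region'].nunique()}",
            f"Effects tested per region: {frame['effect'].nunique()}",
            f"Significant effects (uncorrected across regions): {len(sig)}",
            "Note: per-region tests are not corrected across regions.",
        ]
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['region']} | {row['effect']}: "
                f"F({row['df_num']},{row['df_den']}) = {row['F']:.2f}, p = {row['p']:.4g}"
            )
        return "\n".join(lines)
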