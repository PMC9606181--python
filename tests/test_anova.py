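"""Factorial ANOVA stage: hand-computed F values, an independent
matrix-algebra oracle, Bonferroni arithmetic, and planted-effect power."""

import numpy as np
import pandas as pd
import pytest

from fosnet.anova import bonferroni_posthoc, factorial_anova, RegionalAnova


def long_frame(cells, response="density"):
    """cells: {(a_level, b_level[, c_level]): [values]} -> long DataFrame."""
    rows = []
    names = ("genotype", "treatment", "stress")
    for combo, values in cells.items():
        for v in values:
            row = dict(zip(names, combo))
            row[response] = v
            rows.append(row)
    return pd.DataFrame(rows)


def type3_f_oracle(data, response, factors):
    """Independent least-squares computation of Type-III F statistics.

    Builds the sum-coded design matrix by hand and, for each effect,
    compares the residual sum of squares of the full model against the
    model with that effect's columns removed.
    """
    from itertools import combinations

    def sum_code(series):
        levels = sorted(series.unique())
        cols = []
        for level in levels[:-1]:
            col = (series == level).astype(float) - (series == levels[-1]).astype(float)
            cols.append(col.to_numpy())
        return np.column_stack(cols)

    mains = {f: sum_code(data[f]) for f in factors}
    blocks: dict[str, np.ndarray] = {}
    for k in range(1, len(factors) + 1):
        for combo in combinations(factors, k):
            block = mains[combo[0]]
            for f in combo[1:]:
                cols = [
                    block[:, i] * mains[f][:, j]
                    for i in range(block.shape[1])
                    for j in range(mains[f].shape[1])
                ]
                block = np.column_stack(cols)
            blocks[":".join(combo)] = block

    y = data[response].to_numpy(dtype=float)
    intercept = np.ones((len(y), 1))

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(resid @ resid)

    x_full = np.column_stack([intercept] + list(blocks.values()))
    rss_full = rss(x_full)
    df_den = len(y) - x_full.shape[1]
    out = {}
    for effect, block in blocks.items():
        x_red = np.column_stack(
            [intercept] + [b for name, b in blocks.items() if name != effect]
        )
        df_num = block.shape[1]
        f = ((rss(x_red) - rss_full) / df_num) / (rss_full / df_den)
        out[effect] = (f, df_num, df_den)
    return out


class TestFactorialAnova:
    def test_constant_response_gives_zero_f_unit_p(self):
        data = long_frame(
            {
                ("WT", "veh"): [5.0, 5.0, 5.0],
                ("WT", "dfp"): [5.0, 5.0, 5.0],
                ("KO", "veh"): [5.0, 5.0, 5.0],
                ("KO", "dfp"): [5.0, 5.0, 5.0],
            }
        )
        results = factorial_anova(data, factors=("genotype", "treatment"))
        assert {r.effect_name for r in results} == {
            "genotype",
            "treatment",
            "genotype:treatment",
        }
        for r in results:
            assert r.F == 0.0 and r.p == 1.0

    def test_pure_main_effect_matches_hand_computed_f(self):
        # balanced 2x2, n=3: +2 shift for KO, within-cell pattern (-1, 0, +1)
        base = [-1.0, 0.0, 1.0]
        data = long_frame(
            {
                ("WT", "veh"): [10 + b for b in base],
                ("WT", "dfp"): [10 + b for b in base],
                ("KO", "veh"): [12 + b for b in base],
                ("KO", "dfp"): [12 + b for b in base],
            }
        )
        # SS_A = n_per_level * sum (level mean - grand)^2 = 6*(1+1) = 12
        # SS_E = sum within-cell squares = 4 * 2 = 8; MS_E = 8/8 = 1
        results = {r.effect_name: r for r in factorial_anova(data, factors=("genotype", "treatment"))}
        assert results["genotype"].F == pytest.approx(12.0, abs=1e-10)
        assert results["genotype"].df_num == 1
        assert results["genotype"].df_den == 8
        assert results["treatment"].F == pytest.approx(0.0, abs=1e-10)

    def test_balanced_design_type3_equals_sequential(self, rng):
        data = long_frame(
            {
                (g, t): list(rng.normal(100, 10, 4))
                for g in ("WT", "KO")
                for t in ("veh", "dfp")
            }
        )
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        results = {r.effect_name: r for r in factorial_anova(data, factors=("genotype", "treatment"))}
        seq = sm.stats.anova_lm(
            smf.ols("density ~ C(genotype, Sum) * C(treatment, Sum)", data).fit(), typ=1
        )
        assert results["genotype"].F == pytest.approx(
            float(seq.loc["C(genotype, Sum)", "F"]), abs=1e-8
        )
        assert results["genotype:treatment"].F == pytest.approx(
            float(seq.loc["C(genotype, Sum):C(treatment, Sum)", "F"]), abs=1e-8
        )

    def test_unbalanced_three_way_matches_matrix_oracle(self, rng):
        cells = {}
        sizes = iter([5, 6, 7, 8, 9, 8, 7, 6])
        for g in ("WT", "KO"):
            for t in ("veh", "dfp"):
                for s in ("naive", "PST"):
                    n = next(sizes)
                    cells[(g, t, s)] = list(rng.normal(100, 15, n))
        data = long_frame(cells)
        factors = ("genotype", "treatment", "stress")
        mine = {r.effect_name: r for r in factorial_anova(data, factors=factors)}
        oracle = type3_f_oracle(data, "density", factors)
        assert set(mine) == set(oracle)
        for effect, (f, df_num, df_den) in oracle.items():
            assert mine[effect].F == pytest.approx(f, abs=1e-8)
            assert mine[effect].df_num == df_num
            assert mine[effect].df_den == df_den

    def test_missing_cell_rejected(self):
        data = long_frame(
            {
                ("WT", "veh"): [1.0, 2.0],
                ("WT", "dfp"): [2.0, 3.0],
                ("KO", "veh"): [1.5, 2.5],
            }
        )
        with pytest.raises(ValueError, match="empty design cell"):
            factorial_anova(data, factors=("genotype", "treatment"))

    def test_saturated_model_rejected(self):
        data = long_frame(
            {
                ("WT", "veh"): [1.0],
                ("WT", "dfp"): [2.0],
                ("KO", "veh"): [1.5],
                ("KO", "dfp"): [2.5],
            }
        )
        with pytest.raises(ValueError, match="residual"):
            factorial_anova(data, factors=("genotype", "treatment"))


class TestBonferroni:
    def frame(self, groups):
        rows = [
            {"group": g, "density": v} for g, values in groups.items() for v in values
        ]
        return pd.DataFrame(rows)

    def test_single_comparison_unchanged(self, rng):
        data = self.frame({"a": rng.normal(0, 1, 5), "b": rng.normal(1, 1, 5)})
        (contrast,) = bonferroni_posthoc(data, comparisons=[("a", "b")])
        assert contrast.p_adjusted == pytest.approx(contrast.p)

    def test_multiplication_rule(self, rng):
        data = self.frame({g: rng.normal(0, 1, 6) for g in "abc"})
        contrasts = bonferroni_posthoc(data)
        assert len(contrasts) == 3
        for c in contrasts:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p))
            assert c.p_adjusted >= c.p

    def test_identical_groups_not_significant(self):
        data = self.frame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        (contrast,) = bonferroni_posthoc(data, comparisons=[("a", "b")])
        assert contrast.mean_diff == 0.0
        assert not contrast.significant

    def test_no_comparisons_empty_result(self, rng):
        data = self.frame({"a": rng.normal(0, 1, 4), "b": rng.normal(0, 1, 4)})
        assert bonferroni_posthoc(data, comparisons=[]) == []


class TestPlantedEffectRecovery:
    def test_power_against_planted_genotype_effect(self):
        # 2x2x2 design, n=8/cell, genotype main effect of 3 SEM
        # (SEM = per-cell sd/sqrt(n)): the genotype F detects it with
        # power >= 0.8 over 200 replicates.
        rng = np.random.default_rng(99)
        sd = 12.0
        n = 8
        shift = 3 * sd / np.sqrt(n)
        hits = 0
        reps = 200
        for _ in range(reps):
            cells = {
                (g, t, s): list(rng.normal(100.0 + (shift if g == "KO" else 0.0), sd, n))
                for g in ("WT", "KO")
                for t in ("veh", "dfp")
                for s in ("naive", "PST")
            }
            results = {
                r.effect_name: r
                for r in factorial_anova(long_frame(cells), factors=("genotype", "treatment", "stress"))
            }
            if results["genotype"].p < 0.05:
                hits += 1
        assert hits / reps >= 0.8

    def test_regional_anova_facade_runs_per_region(self, rng):
        rows = []
        for region in ("A", "B"):
            for g in ("WT", "KO"):
                for t in ("veh", "dfp"):
                    for v in rng.normal(100, 10, 4):
                        rows.append(
                            {"region": region, "genotype": g, "treatment": t, "density": v}
                        )
        data = pd.DataFrame(rows)
        results = RegionalAnova(data, factors=("genotype", "treatment")).fit()
        frame = results.effects_frame()
        assert set(frame["region"]) == {"A", "B"}
        assert len(frame) == 2 * 3
        assert "Factorial ANOVA" in results.summary()
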