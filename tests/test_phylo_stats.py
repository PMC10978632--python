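"""BM covariance, GLS phylogenetic means, OLS, ANOVA and Tukey HSD."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insect_gc.formats_io import read_newick
from insect_gc.phylo_stats import (
    AnovaResult,
    bm_covariance,
    ols,
    phylo_mean,
    phylo_mean_per_sco,
    tukey_hsd,
    two_way_anova,
)
from insect_gc.synthetic_data import simulate_bm, simulate_tree


class TestBmCovariance:
    def test_hand_example(self):
        cov = bm_covariance(read_newick("((A:1,B:1):1,C:2);"))
        order = {s: i for i, s in enumerate(cov.species)}
        V = cov.matrix
        assert V[order["A"], order["A"]] == 2
        assert V[order["A"], order["B"]] == 1
        assert V[order["A"], order["C"]] == 0
        assert V[order["C"], order["C"]] == 2

    def test_star_tree_is_scaled_identity(self):
        cov = bm_covariance(read_newick("(A:1,B:1,C:1);"))
        assert np.allclose(cov.matrix, np.eye(3))

    def test_positive_semidefinite_on_simulated_trees(self):
        for seed in range(5):
            tree = simulate_tree(12, 1.0, seed)
            V = bm_covariance(tree).matrix
            eigenvalues = np.linalg.eigvalsh(V)
            assert eigenvalues.min() >= -1e-9 * eigenvalues.max()

    def test_diagonal_dominates_rows(self):
        V = bm_covariance(simulate_tree(10, 1.0, 3)).matrix
        assert (np.diag(V)[:, None] >= V - 1e-12).all()


class TestPhyloMean:
    def test_star_tree_reduces_to_arithmetic_mean(self):
        tree = read_newick("(A:1,B:1,C:1);")
        assert math.isclose(phylo_mean(tree, {"A": 1, "B": 2, "C": 3}), 2.0)

    def test_two_tip_inverse_variance_weighting(self):
        # depths (1, 3): mu = (0/1 + 4/3) / (1 + 1/3) = 1
        tree = read_newick("(A:1,B:3);")
        assert math.isclose(phylo_mean(tree, {"A": 0, "B": 4}), 1.0)

    @given(st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_constant_values_return_constant(self, c):
        tree = read_newick("((A:1,B:1):1,C:2);")
        assert math.isclose(phylo_mean(tree, {"A": c, "B": c, "C": c}), c, abs_tol=1e-9)

    def test_translation_and_scale_equivariance(self):
        tree = simulate_tree(8, 1.0, 11)
        values = simulate_bm(tree, 0.0, 1.0, 12)
        base = phylo_mean(tree, values)
        shifted = phylo_mean(tree, {k: 2 * v + 5 for k, v in values.items()})
        assert math.isclose(shifted, 2 * base + 5, rel_tol=1e-9, abs_tol=1e-9)

    def test_estimate_within_value_range(self):
        tree = simulate_tree(16, 1.0, 2)
        values = simulate_bm(tree, 0.3, 0.05, 3)
        estimate = phylo_mean(tree, values)
        assert min(values.values()) <= estimate <= max(values.values())

    def test_key_mismatch_lists_species(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(KeyError, match="B"):
            phylo_mean(tree, {"A": 1.0})

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_r_nlme_gls(self, tmp_path):
        """Independent oracle: nlme::gls with corBrownian on the same tree."""
        newick = "((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);"
        values = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0}
        script = tmp_path / "gls.R"
        script.write_text(
            'suppressMessages({library(ape); library(nlme)})\n'
            f'tree <- read.tree(text="{newick}")\n'
            'df <- data.frame(y=c(1.0, 2.0, 0.5, 3.0), sp=c("A","B","C","D"))\n'
            'rownames(df) <- df$sp\n'
            'fit <- gls(y ~ 1, data=df, correlation=corBrownian(1, tree, form=~sp))\n'
            'cat(sprintf("%.12f", coef(fit)[1]))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        assert math.isclose(
            phylo_mean(read_newick(newick), values), float(out.stdout), rel_tol=1e-9
        )


class TestPhyloMeanPerSco:
    def test_complete_orthogroup_equals_direct_mean(self):
        tree = simulate_tree(5, 1.0, 4)
        values = {sp: (0.4, 1.0) for sp in tree.tips}
        out = phylo_mean_per_sco(tree, {"OG1": values})
        assert math.isclose(out["OG1"][0], 0.4, abs_tol=1e-9)

    def test_missing_species_pruned(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        values = {"A": (0.1, 1.0), "B": (0.5, 2.0), "C": (0.3, 3.0)}
        out = phylo_mean_per_sco(tree, {"OG1": values})
        pruned = tree.pruned_to(["A", "B", "C"])
        expected = phylo_mean(pruned, {s: v[0] for s, v in values.items()})
        assert math.isclose(out["OG1"][0], expected)

    def test_too_few_species_skipped(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        out = phylo_mean_per_sco(tree, {"OG1": {"A": (1, 1), "B": (2, 2)}})
        assert out == {}


class TestOls:
    def test_exact_line(self):
        fit = ols([0, 1, 2, 3], [1, 3, 5, 7])
        assert math.isclose(fit.slope, 2) and math.isclose(fit.intercept, 1)
        assert math.isclose(fit.r_squared, 1)

    def test_hand_least_squares(self):
        fit = ols([1, 2, 3], [1, 3, 2])
        assert math.isclose(fit.slope, 0.5)
        assert math.isclose(fit.r_squared, 0.25)

    def test_null_slope_within_three_se(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        fit = ols(x, y)
        assert abs(fit.slope) < 3 * fit.stderr

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ols([1, 1, 1], [1, 2, 3])


def anova_projection_oracle(values: np.ndarray):
    """Brute-force two-way ANOVA via projection matrices on the additive
    design (one observation per cell, no interaction)."""
    a, b = values.shape
    y = values.ravel()
    # full additive design: intercept + row dummies + column dummies
    X_full = [np.ones(a * b)]
    for i in range(1, a):
        X_full.append(np.repeat(np.eye(a)[i], b))
    for j in range(1, b):
        X_full.append(np.tile(np.eye(b)[j], a))
    X_full = np.column_stack(X_full)

    def rss(X):
        proj = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(((y - proj) ** 2).sum())

    rss_full = rss(X_full)
    rss_no_a = rss(X_full[:, [0] + list(range(a, a + b - 1))])
    rss_no_b = rss(X_full[:, : a])
    df_e = (a - 1) * (b - 1)
    mse = rss_full / df_e
    f_a = ((rss_no_a - rss_full) / (a - 1)) / mse
    f_b = ((rss_no_b - rss_full) / (b - 1)) / mse
    return f_a, f_b


class TestTwoWayAnova:
    def test_hand_sums_of_squares(self):
        result = two_way_anova(pd.DataFrame([[1, 2], [3, 5]]))
        assert math.isclose(result.f_a, 25)
        assert math.isclose(result.f_b, 9)
        assert math.isclose(result.mse, 0.25)

    def test_all_cells_equal_is_undefined(self):
        result = two_way_anova(pd.DataFrame([[2.0, 2.0], [2.0, 2.0]]))
        assert math.isnan(result.f_a) and math.isnan(result.f_b)

    def test_factor_a_only_dependence(self):
        result = two_way_anova(pd.DataFrame([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0]]))
        assert result.f_b == 0.0

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            values = rng.normal(size=(3, 4))
            result = two_way_anova(pd.DataFrame(values))
            f_a, f_b = anova_projection_oracle(values)
            assert math.isclose(result.f_a, f_a, rel_tol=1e-10)
            assert math.isclose(result.f_b, f_b, rel_tol=1e-10)

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            two_way_anova(pd.DataFrame([[1.0, np.nan], [2.0, 3.0]]))


class TestTukeyHsd:
    def make_anova(self, means_a, mse, df_b, df_resid):
        return AnovaResult(
            factor_a="A", factor_b="B", f_a=1, f_b=1, df_a=len(means_a) - 1,
            df_b=df_b, df_resid=df_resid, p_a=0.5, p_b=0.5, mse=mse,
            grand_mean=float(np.mean(list(means_a.values()))),
            means_a=means_a, means_b={},
        )

    def test_identical_means_give_p_one(self):
        result = two_way_anova(pd.DataFrame([[1.0, 2.0], [1.1, 1.9]]))
        table = tukey_hsd(result, "factor_a")
        row = table.iloc[0]
        assert math.isclose(row["difference"], 0.0)
        assert math.isclose(row["p_adj"], 1.0)

    def test_p_decreases_with_separation(self):
        ps = []
        for sep in [0.5, 1.0, 2.0, 4.0]:
            anova = self.make_anova({"x": 0.0, "y": sep}, mse=0.1, df_b=3, df_resid=6)
            ps.append(float(tukey_hsd(anova, "A")["p_adj"].iloc[0]))
        assert ps == sorted(ps, reverse=True)

    def test_q_statistic_and_monte_carlo_p(self):
        """3 levels, 4 observations per level, means (0, 0, 1), MSE = 0.1,
        df = 6: q for the (0, 1) pair is 1/sqrt(0.1/4) ~ 6.325; the adjusted
        p is checked against a Monte Carlo studentized-range oracle."""
        anova = self.make_anova({"a": 0.0, "b": 0.0, "c": 1.0}, mse=0.1, df_b=3, df_resid=6)
        table = tukey_hsd(anova, "A")
        row = table[(table.level_1 == "a") & (table.level_2 == "c")].iloc[0]
        assert math.isclose(row["q"], 1 / math.sqrt(0.1 / 4), rel_tol=1e-12)

        rng = np.random.default_rng(123)
        n_mc = 200_000
        z = rng.normal(size=(n_mc, 3))
        ranges = z.max(axis=1) - z.min(axis=1)
        s = np.sqrt(rng.chisquare(6, size=n_mc) / 6)
        p_mc = float((ranges / s >= row["q"]).mean())
        assert abs(row["p_adj"] - p_mc) < 0.005

    def test_too_few_levels_rejected(self):
        anova = self.make_anova({"only": 1.0}, mse=0.1, df_b=3, df_resid=6)
        with pytest.raises(ValueError):
            tukey_hsd(anova, "A")
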