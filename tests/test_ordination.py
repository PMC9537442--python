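"""Ordination, variance partitioning and ANOVA against independent oracles."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from landconn import anova_factorial, cca, rda, variance_partition


def one_way_r2_oracle(y, labels):
    """Classical between/total sum-of-squares ratio via group means."""
    y = np.asarray(y, float)
    grand = y.mean()
    between = sum(
        (y[labels == g].mean() - grand) ** 2 * (labels == g).sum()
        for g in np.unique(labels)
    )
    total = ((y - grand) ** 2).sum()
    return between / total


class TestRDA:
    def test_perfect_fit(self):
        f = pd.DataFrame({"a": ["x", "x", "y", "y", "z", "z"]})
        coef = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]])
        Y = pd.get_dummies(f["a"]).to_numpy(float) @ coef
        res = rda(Y, f)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-12)

    def test_null_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(7)
        f = pd.DataFrame({"a": rng.choice(list("abcd"), 2000)})
        Y = rng.normal(size=(2000, 3))
        assert abs(rda(Y, f).adjusted_r_squared) < 0.02

    def test_one_way_r2_matches_group_means_oracle(self, rng):
        y = rng.normal(size=14) + np.repeat([0.0, 1.5], 7)
        labels = np.repeat(np.array(["a", "b"]), 7)
        res = rda(y, pd.DataFrame({"g": labels}), standardize=False)
        assert res.r_squared == pytest.approx(one_way_r2_oracle(y, labels), abs=1e-10)

    def test_inertia_decomposition(self, rng):
        Y = rng.normal(size=(30, 3))
        f = pd.DataFrame({"a": rng.choice(list("abc"), 30), "b": rng.choice(list("uv"), 30)})
        res = rda(Y, f)
        assert (
            res.eigenvalues_constrained.sum() + res.eigenvalues_unconstrained.sum()
        ) == pytest.approx(res.total_inertia, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues_constrained) <= 1e-12)

    def test_collinear_columns_dropped_with_warning(self, rng):
        Y = rng.normal(size=(10, 2))
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.warns(UserWarning, match="collinear"):
            res = rda(Y, X)
        assert res.rank == 1


class TestCCA:
    def test_identical_rows_zero_inertia(self):
        Y = np.tile([1.0, 2.0, 3.0], (4, 1))
        res = cca(Y, pd.DataFrame({"a": ["x", "x", "y", "y"]}))
        assert res.total_inertia == pytest.approx(0.0)
        assert res.eigenvalues_constrained.size == 0

    def test_saturated_binary_design(self):
        # 2x2 contingency-style table, one perfectly discriminating factor
        Y = np.array([[10.0, 0.0], [0.0, 10.0]])
        res = cca(Y, pd.DataFrame({"a": ["u", "v"]}))
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            cca(np.array([[1.0, -0.5]]), np.array([[1.0]]))

    def test_total_inertia_is_chi_square_statistic(self, rng):
        Y = rng.integers(1, 20, size=(6, 3)).astype(float)
        res = cca(Y, pd.DataFrame({"a": list("aabbcc")}))
        # independent oracle: Pearson chi-square / grand total
        tot = Y.sum()
        exp = np.outer(Y.sum(1), Y.sum(0)) / tot
        chi2 = ((Y - exp) ** 2 / exp).sum()
        assert res.total_inertia == pytest.approx(chi2 / tot, abs=1e-10)


@pytest.fixture(scope="module")
def vegan_results(tmp_path_factory):
    rng = np.random.default_rng(42)
    n = 24
    f1 = rng.choice(list("abc"), n)
    f2 = rng.choice(list("uv"), n)
    Y = rng.normal(size=(n, 3)) + (f1 == "a")[:, None] * np.array([1.0, 0.5, 0.0])
    Ypos = Y - Y.min(axis=0)
    d = tmp_path_factory.mktemp("vegan")
    np.savetxt(d / "Y.csv", Y, delimiter=",")
    np.savetxt(d / "Ypos.csv", Ypos, delimiter=",")
    pd.DataFrame({"f1": f1, "f2": f2}).to_csv(d / "X.csv", index=False)
    script = textwrap.dedent("""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.csv('Y.csv', header=FALSE))
        Ypos <- as.matrix(read.csv('Ypos.csv', header=FALSE))
        X <- read.csv('X.csv', colClasses='factor')
        r <- rda(Y ~ f1 + f2, data=X, scale=TRUE)
        cc <- cca(Ypos ~ f1 + f2, data=X)
        out <- list(
          rda_prop = unname(sum(r$CCA$eig) / r$tot.chi),
          rda_adj = unname(RsquareAdj(r)$adj.r.squared),
          cca_prop = unname(sum(cc$CCA$eig) / cc$tot.chi),
          cca_eig1 = unname(cc$CCA$eig[1])
        )
        cat(jsonlite::toJSON(out, digits=12))
    """)
    (d / "check.R").write_text(script)
    proc = subprocess.run(
        ["Rscript", "check.R"], cwd=d, capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    return json.loads(proc.stdout), Y, Ypos, pd.DataFrame({"f1": f1, "f2": f2})


class TestVegansCrossCheck:
    """Independent check of RDA/CCA against the R vegan implementation."""

    def test_rda_matches_vegan(self, vegan_results):
        ref, Y, _, X = vegan_results
        res = rda(Y, X)
        assert res.proportion_constrained == pytest.approx(ref["rda_prop"][0], abs=1e-8)
        assert res.adjusted_r_squared == pytest.approx(ref["rda_adj"][0], abs=1e-8)

    def test_cca_matches_vegan(self, vegan_results):
        ref, _, Ypos, X = vegan_results
        res = cca(Ypos, X)
        assert res.proportion_constrained == pytest.approx(ref["cca_prop"][0], abs=1e-8)
        assert res.eigenvalues_constrained[0] == pytest.approx(ref["cca_eig1"][0], abs=1e-8)


class TestVariancePartition:
    @staticmethod
    def balanced_factors():
        A = np.repeat(["a", "b"], 8)
        B = np.tile(np.repeat(["u", "v"], 4), 2)
        return A, B

    def test_orthogonal_additive_noise_free(self):
        A, B = self.balanced_factors()
        y = (A == "a") * 1.0 + (B == "u") * 2.0
        part = variance_partition(
            y[:, None],
            {"GA": pd.DataFrame({"A": A}), "GB": pd.DataFrame({"B": B})},
            adjusted=False,
        )
        assert part.components[("GA", "GB")] == pytest.approx(0.0, abs=1e-10)
        assert part.unique("GA") == pytest.approx(0.2, abs=1e-10)
        assert part.unique("GB") == pytest.approx(0.8, abs=1e-10)
        assert part.residual == pytest.approx(0.0, abs=1e-10)

    def test_components_sum_to_one(self, rng):
        Y = rng.normal(size=(40, 3))
        groups = {
            "G1": pd.DataFrame({"a": rng.choice(list("ab"), 40)}),
            "G2": pd.DataFrame({"b": rng.choice(list("uvw"), 40)}),
            "G3": pd.DataFrame({"c": rng.choice(list("xy"), 40)}),
        }
        part = variance_partition(Y, groups)
        total = sum(part.components.values()) + part.residual
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_group_order_invariance(self, rng):
        Y = rng.normal(size=(30, 2))
        a = pd.DataFrame({"a": rng.choice(list("ab"), 30)})
        b = pd.DataFrame({"b": rng.choice(list("uv"), 30)})
        p1 = variance_partition(Y, {"GA": a, "GB": b})
        p2 = variance_partition(Y, {"GB": b, "GA": a})
        for key, val in p1.components.items():
            assert p2.components[tuple(sorted(key))] == pytest.approx(val, abs=1e-10)

    def test_overlapping_groups_rejected(self, rng):
        Y = rng.normal(size=(10, 2))
        a = pd.DataFrame({"a": rng.choice(list("ab"), 10)})
        with pytest.raises(ValueError):
            variance_partition(Y, {"G1": a, "G2": a})

    def test_single_group_unique_equals_marginal(self, rng):
        Y = rng.normal(size=(30, 2))
        a = pd.DataFrame({"a": rng.choice(list("abc"), 30)})
        b = pd.DataFrame({"b": rng.choice(list("uv"), 30)})
        part = variance_partition(Y, {"GA": a, "GB": b})
        # unique(GA) = R2(GA,GB) - R2(GB)
        expected = part.subset_r2[("GA", "GB")] - part.subset_r2[("GB",)]
        assert part.unique("GA") == pytest.approx(expected, abs=1e-10)


class TestAnovaFactorial:
    def test_constant_response_zero_ss(self):
        f = pd.DataFrame({"A": list("aabb"), "B": list("uvuv")})
        tab = anova_factorial(np.full(4, 3.0), f)
        assert np.allclose(tab.loc[["A", "B"], "sum_sq"], 0.0, atol=1e-20)

    def test_one_way_f_matches_oracle(self, rng):
        y = rng.normal(size=15) + np.repeat([0, 1, 3], 5)
        f = pd.DataFrame({"g": np.repeat(list("abc"), 5)})
        tab = anova_factorial(y, f)
        # textbook one-way F from group means
        groups = [y[i * 5 : (i + 1) * 5] for i in range(3)]
        ssb = sum(5 * (g.mean() - y.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / 12)
        assert tab.loc["g", "F"] == pytest.approx(f_oracle, rel=1e-10)

    def test_additive_balanced_design_has_zero_interaction(self):
        A = np.repeat(["a", "b"], 6)
        B = np.tile(np.repeat(["u", "v", "w"], 2), 2)
        y = (A == "a") * 2.0 + (B == "u") * 1.0 + (B == "v") * 0.5
        tab = anova_factorial(y, pd.DataFrame({"A": A, "B": B}))
        assert tab.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_two_way(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        A = np.repeat(["a", "b"], 12)
        B = np.tile(np.repeat(["u", "v", "w"], 4), 2)
        y = rng.normal(size=24) + (A == "a") * 1.0 + (B == "u") * 0.5
        df = pd.DataFrame({"y": y, "A": A, "B": B})
        ref = sm.stats.anova_lm(smf.ols("y ~ C(A) * C(B)", data=df).fit(), typ=1)
        tab = anova_factorial(y, df[["A", "B"]])
        assert tab.loc["A", "sum_sq"] == pytest.approx(ref.loc["C(A)", "sum_sq"], rel=1e-8)
        assert tab.loc["B", "sum_sq"] == pytest.approx(ref.loc["C(B)", "sum_sq"], rel=1e-8)
        assert tab.loc["A:B", "sum_sq"] == pytest.approx(
            ref.loc["C(A):C(B)", "sum_sq"], rel=1e-8
        )
        assert tab.loc["A:B", "F"] == pytest.approx(ref.loc["C(A):C(B)", "F"], rel=1e-8)

    def test_unbalanced_warns(self, rng):
        f = pd.DataFrame({"A": ["a", "a", "a", "b", "b"], "B": ["u", "v", "u", "v", "v"]})
        with pytest.warns(UserWarning, match="unbalanced"):
            anova_factorial(rng.normal(size=5), f)
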