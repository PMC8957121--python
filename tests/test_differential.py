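import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbmseesaw import (
    ContrastSpec,
    GbmError,
    MethLevelTable,
    bh_fdr,
    diff_expression,
    diff_methylation,
    size_factors,
)

CONTRAST = ContrastSpec("ctl", "trt")


def bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * n / j for j in range(rank_i, n + 1)), 1.0
        )
    return q


def make_levels(meth, cov, samples):
    meth = pd.DataFrame(meth, columns=samples)
    cov = pd.DataFrame(cov, columns=samples)
    meth.index = cov.index = pd.Index([f"g{i}" for i in range(len(meth))], name="gene_id")
    pct = 100.0 * meth / cov.where(cov > 0)
    return MethLevelTable(meth=meth, cov=cov, pct=pct)


class TestBhFdr:
    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.5]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.5]
        )

    def test_single_and_tied_pvalues(self):
        assert bh_fdr([0.2]).tolist() == [0.2]
        assert bh_fdr([0.3, 0.3, 0.3]).tolist() == pytest.approx([0.3, 0.3, 0.3])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[[0, 2]].tolist() == pytest.approx([0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(GbmError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 200))
            p = rng.random(n)
            ours = bh_fdr(p)
            assert np.allclose(ours, bh_brute_force(p))
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])

    def test_q_at_least_p_and_threshold_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 0.1).sum() <= (p <= 0.1).sum()


class TestSizeFactors:
    def test_closed_form_two_columns(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                         index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        sf = size_factors(m)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]},
                         index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        assert np.allclose(size_factors(m), 1.0)

    def test_scaling_one_column_scales_factor_ratios(self):
        # scaling a column also scales the per-gene geometric means, so the
        # exact equivariance is in the factor ratios (and in the normalized
        # counts), not in any single factor
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(1, 100, (50, 3)), columns=["a", "b", "c"],
                         index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"))
        base = size_factors(m)
        m3 = m.copy()
        m3["b"] = m3["b"] * 3
        scaled = size_factors(m3)
        assert scaled["b"] / scaled["a"] == pytest.approx(3 * base["b"] / base["a"])
        assert scaled["c"] / scaled["a"] == pytest.approx(base["c"] / base["a"])
        norm_base = m.div(base, axis=1)
        norm_scaled = m3.div(scaled, axis=1)
        assert np.allclose(norm_scaled / norm_base, (norm_scaled / norm_base).iloc[0, 0])

    def test_fallback_when_no_gene_positive_everywhere(self):
        m = pd.DataFrame({"a": [10, 0], "b": [0, 10]},
                         index=pd.Index(["g1", "g2"], name="gene_id"))
        sf = size_factors(m)
        assert (sf > 0).all()


class TestDiffMethylation:
    def test_identical_conditions_yield_null(self):
        levels = make_levels(
            meth={"c1": [5], "c2": [5], "t1": [5], "t2": [5]},
            cov={"c1": [50], "c2": [50], "t1": [50], "t2": [50]},
            samples=["c1", "c2", "t1", "t2"],
        )
        groups = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}
        out = diff_methylation(levels, groups, CONTRAST)
        assert out.loc["g0", "meth_diff"] == 0.0
        assert out.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_pooled_percent_difference(self):
        levels = make_levels(
            meth={"c1": [4], "c2": [6], "t1": [12], "t2": [8]},
            cov={"c1": [50], "c2": [50], "t1": [50], "t2": [50]},
            samples=["c1", "c2", "t1", "t2"],
        )
        groups = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}
        out = diff_methylation(levels, groups, CONTRAST)
        # pooled: ctl 10/100, trt 20/100 -> +10 percentage points
        assert out.loc["g0", "meth_diff"] == pytest.approx(10.0)
        assert out.loc["g0", "log2_meth_ratio"] == pytest.approx(
            np.log2((20.5 / 101) / (10.5 / 101))
        )

    def test_lrt_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        groups = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}
        meth = rng.integers(0, 30, size=(25, 4))
        cov = meth + rng.integers(1, 30, size=(25, 4))
        levels = make_levels(
            {s: meth[:, i] for i, s in enumerate(groups)},
            {s: cov[:, i] for i, s in enumerate(groups)},
            list(groups),
        )
        ours = diff_methylation(levels, groups, CONTRAST)
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        for i in range(25):
            y = np.column_stack([meth[i], cov[i] - meth[i]])
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, X[:, :1], family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            expect = stats.chi2.sf(max(lrt, 0.0), 1)
            assert ours["p_value"].iloc[i] == pytest.approx(expect, abs=1e-6)

    def test_single_sample_case_against_oracles(self):
        # 10/100 vs 20/100, one sample per condition
        levels = make_levels(
            meth={"c1": [10], "t1": [20]}, cov={"c1": [100], "t1": [100]},
            samples=["c1", "t1"],
        )
        out = diff_methylation(
            levels, {"c1": "ctl", "t1": "trt"}, CONTRAST, min_samples_per_condition=1
        )
        # brute-force binomial LRT at the pooled MLEs
        def ll(m, c, p):
            return m * np.log(p) + (c - m) * np.log(1 - p)
        lrt = 2 * (ll(10, 100, 0.1) + ll(20, 100, 0.2) - ll(30, 200, 0.15))
        expect = stats.chi2.sf(lrt, 1)
        assert out.loc["g0", "p_value"] == pytest.approx(expect)
        fisher = stats.fisher_exact([[10, 90], [20, 80]])[1]
        assert 0.1 < out.loc["g0", "p_value"] / fisher < 10  # same order of magnitude

    def test_label_swap_negates_effects_keeps_pvalues(self):
        rng = np.random.default_rng(4)
        groups = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}
        meth = rng.integers(0, 20, size=(40, 4))
        cov = meth + rng.integers(1, 20, size=(40, 4))
        levels = make_levels(
            {s: meth[:, i] for i, s in enumerate(groups)},
            {s: cov[:, i] for i, s in enumerate(groups)},
            list(groups),
        )
        fwd = diff_methylation(levels, groups, CONTRAST)
        rev = diff_methylation(levels, groups, ContrastSpec("trt", "ctl"))
        assert np.allclose(fwd["meth_diff"], -rev["meth_diff"], atol=1e-9)
        assert np.allclose(fwd["log2_meth_ratio"], -rev["log2_meth_ratio"], atol=1e-9)
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-9)

    def test_separation_is_flagged_with_finite_p(self):
        levels = make_levels(
            meth={"c1": [0], "c2": [0], "t1": [30], "t2": [30]},
            cov={"c1": [30], "c2": [30], "t1": [30], "t2": [30]},
            samples=["c1", "c2", "t1", "t2"],
        )
        groups = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}
        out = diff_methylation(levels, groups, CONTRAST)
        assert bool(out.loc["g0", "separated"])
        assert 0 <= out.loc["g0", "p_value"] < 1e-6

    def test_condition_without_eligible_samples_left_untested(self):
        levels = make_levels(
            meth={"c1": [5], "c2": [5], "t1": [5], "t2": [5]},
            cov={"c1": [50], "c2": [50], "t1": [3], "t2": [2]},
            samples=["c1", "c2", "t1", "t2"],
        )
        levels.pct[levels.cov < 10] = np.nan
        groups = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}
        out = diff_methylation(levels, groups, CONTRAST)
        assert not out.loc["g0", "tested"]
        assert np.isnan(out.loc["g0", "p_value"]) and np.isnan(out.loc["g0", "q_value"])

    def test_overdispersion_correction_never_inflates_significance(self):
        rng = np.random.default_rng(5)
        groups = {"c1": "ctl", "c2": "ctl", "c3": "ctl",
                  "t1": "trt", "t2": "trt", "t3": "trt"}
        meth = rng.integers(0, 40, size=(60, 6))
        cov = meth + rng.integers(1, 40, size=(60, 6))
        levels = make_levels(
            {s: meth[:, i] for i, s in enumerate(groups)},
            {s: cov[:, i] for i, s in enumerate(groups)},
            list(groups),
        )
        plain = diff_methylation(levels, groups, CONTRAST, overdispersion="none")
        corrected = diff_methylation(levels, groups, CONTRAST, overdispersion="pearson")
        assert (corrected["p_value"] >= plain["p_value"] - 1e-12).all()


class TestDiffExpression:
    def _counts(self, arr, samples):
        return pd.DataFrame(
            arr, columns=samples,
            index=pd.Index([f"g{i}" for i in range(len(arr))], name="gene_id"),
        )

    GROUPS = {"c1": "ctl", "c2": "ctl", "t1": "trt", "t2": "trt"}

    def test_identical_conditions_yield_null(self):
        counts = self._counts([[50, 60, 50, 60], [10, 20, 10, 20]],
                              ["c1", "c2", "t1", "t2"])
        out = diff_expression(counts, self.GROUPS, CONTRAST)
        assert out["log2_fold_change"].abs().max() == pytest.approx(0.0)
        assert (out["p_value"] > 0.99).all()

    def test_fourfold_mean_difference_is_two_log2_units(self):
        # balanced rows keep all size factors at 1
        counts = self._counts(
            [[10, 10, 40, 40], [40, 40, 10, 10]], ["c1", "c2", "t1", "t2"]
        )
        out = diff_expression(counts, self.GROUPS, CONTRAST, pseudocount=0)
        assert out.loc["g0", "log2_fold_change"] == pytest.approx(2.0)
        assert out.loc["g1", "log2_fold_change"] == pytest.approx(-2.0)

    def test_low_count_genes_left_untested(self):
        counts = self._counts([[1, 0, 2, 1], [100, 90, 110, 95]],
                              ["c1", "c2", "t1", "t2"])
        out = diff_expression(counts, self.GROUPS, CONTRAST, min_total=10)
        assert not out.loc["g0", "tested"] and np.isnan(out.loc["g0", "p_value"])
        assert out.loc["g1", "tested"]

    def test_label_swap_negates_lfc_keeps_pvalues(self):
        rng = np.random.default_rng(6)
        counts = self._counts(rng.integers(0, 500, (80, 4)), ["c1", "c2", "t1", "t2"])
        fwd = diff_expression(counts, self.GROUPS, CONTRAST)
        rev = diff_expression(counts, self.GROUPS, ContrastSpec("trt", "ctl"))
        m = fwd["tested"]
        assert np.allclose(fwd.loc[m, "log2_fold_change"],
                           -rev.loc[m, "log2_fold_change"], atol=1e-9)
        assert np.allclose(fwd.loc[m, "p_value"], rev.loc[m, "p_value"], atol=1e-9)

    def test_recovers_planted_fold_changes_with_small_bias(self):
        rng = np.random.default_rng(7)
        n_genes, n = 4000, 6
        lfc = rng.choice([-1.0, 1.0], n_genes)
        mu1 = np.full(n_genes, 100.0)
        mu2 = mu1 * 2.0**lfc
        alpha = 0.2
        y1 = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu1[:, None]), (n_genes, n))
        y2 = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu2[:, None]), (n_genes, n))
        samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        groups = {s: ("ctl" if s.startswith("c") else "trt") for s in samples}
        counts = self._counts(np.hstack([y1, y2]), samples)
        out = diff_expression(counts, groups, CONTRAST)
        bias = (out["log2_fold_change"] - lfc)[out["tested"]]
        assert abs(bias.mean()) < 0.1

    def test_q_never_below_p(self):
        rng = np.random.default_rng(8)
        counts = self._counts(rng.integers(0, 300, (200, 4)), ["c1", "c2", "t1", "t2"])
        out = diff_expression(counts, self.GROUPS, CONTRAST)
        m = out["tested"]
        assert (out.loc[m, "q_value"] >= out.loc[m, "p_value"] - 1e-12).all()

    def test_single_replicate_condition_rejected(self):
        counts = self._counts([[5, 6, 7]], ["c1", "c2", "t1"])
        with pytest.raises(GbmError, match=">= 2"):
            diff_expression(counts, {"c1": "ctl", "c2": "ctl", "t1": "trt"}, CONTRAST)
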