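"""NB Wald differential expression: size factors, dispersion, test, DEG call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import pcitnet as pn
from .test_preprocess import make_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_counts(np.tile([[10], [100], [7]], (1, 4)))
        np.testing.assert_allclose(pn.size_factors(cm).to_numpy(), 1.0)

    def test_doubled_sample_closed_form(self):
        """B = 2A with genes [10, 100]: median-of-ratios prop. to [1, 2],
        normalized to geometric mean 1: [1/sqrt(2), sqrt(2)]."""
        cm = make_counts(np.array([[10, 20], [100, 200]]))
        np.testing.assert_allclose(
            pn.size_factors(cm).to_numpy(), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_single_sample_factor_is_one(self):
        counts = pd.DataFrame({"s0": [5, 9]}, index=pd.Index(["g0", "g1"], name="gene_id"))
        cm = pn.CountMatrix(counts=counts, groups=pd.Series({"s0": "FH"}))
        np.testing.assert_allclose(pn.size_factors(cm).to_numpy(), [1.0])

    def test_no_common_positive_gene_is_an_error(self):
        cm = make_counts(np.array([[1, 0], [0, 1]]))
        with pytest.raises(pn.ValidationError, match="filter"):
            pn.size_factors(cm)


class TestDispersion:
    def test_formula_arithmetic(self):
        """Normalized counts with mean 10 and pooled variance 30 give
        alpha = (30 - 10) / 100 = 0.2; built by direct construction."""
        # one gene, one group of many samples with sample variance v, mean m
        rng = np.random.default_rng(0)
        x = rng.normal(10, np.sqrt(30), 2000)
        x = np.clip(np.round(x), 0, None).astype(int)
        m = (x / 1.0).mean()
        v = x.var(ddof=1)
        expected = (v - m) / m**2
        cm = make_counts(x.reshape(1, -1), groups=["FH"] * 1000 + ["SFH"] * 1000)
        factors = pd.Series(1.0, index=cm.sample_ids)
        alpha = pn.estimate_dispersion(cm, factors).iloc[0]
        # pooled-within-group variance differs from total variance only via
        # the two group means, negligible here
        assert alpha == pytest.approx(expected, rel=0.01)

    def test_constant_gene_sits_at_floor(self):
        cm = make_counts(np.full((1, 6), 17))
        factors = pd.Series(1.0, index=cm.sample_ids)
        assert pn.estimate_dispersion(cm, factors).iloc[0] == 1e-8

    def test_poisson_gene_is_near_floor(self):
        rng = np.random.default_rng(1)
        cm = make_counts(
            rng.poisson(50, size=(40, 400)), groups=["FH"] * 200 + ["SFH"] * 200
        )
        factors = pd.Series(1.0, index=cm.sample_ids)
        alpha = pn.estimate_dispersion(cm, factors)
        assert np.median(alpha) < 0.005  # variance ~ mean => alpha ~ 0

    def test_mean_difference_does_not_inflate_dispersion(self):
        """Pooling within groups: a planted shift between groups must not
        count as biological variance."""
        rng = np.random.default_rng(2)
        a = rng.poisson(50, 300)
        b = rng.poisson(200, 300)
        cm = make_counts(
            np.concatenate([a, b]).reshape(1, -1),
            groups=["FH"] * 300 + ["SFH"] * 300,
        )
        factors = pd.Series(1.0, index=cm.sample_ids)
        assert pn.estimate_dispersion(cm, factors).iloc[0] < 0.01

    def test_single_sample_group_is_an_error(self):
        cm = make_counts(np.ones((2, 3), dtype=int), groups=["FH", "SFH", "SFH"])
        with pytest.raises(pn.ValidationError, match="2 samples"):
            pn.estimate_dispersion(cm, pd.Series(1.0, index=cm.sample_ids))


class TestWald:
    def test_identical_group_means(self):
        cm = make_counts(np.tile([[30], [60]], (1, 8)))
        res = pn.wald_test(cm)
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_doubled_mean_gives_unit_log2fc_without_pseudocount(self):
        base = np.array([[100] * 4 + [200] * 4])
        cm = make_counts(np.vstack([base, base[:, ::-1]]),
                         groups=["FH"] * 4 + ["SFH"] * 4)
        # disable normalization effects: both genes mirror each other, so
        # size factors are 1; pc=0 isolates the ratio definition
        res = pn.wald_test(cm, pseudocount=0.0)
        assert res["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_group_swap_negates_log2fc_and_keeps_p(self, sim_small):
        cm, _ = sim_small
        res = pn.wald_test(cm, positive_group="SFH")
        swapped = pn.wald_test(cm, positive_group="FH")
        np.testing.assert_array_equal(
            res["log2fc"].to_numpy(), -swapped["log2fc"].to_numpy()
        )
        np.testing.assert_array_equal(
            res["p_value"].to_numpy(), swapped["p_value"].to_numpy()
        )

    def test_column_scaling_invariance_after_normalization(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(100, size=(30, 10))
        cm = make_counts(x, groups=["FH"] * 5 + ["SFH"] * 5)
        scaled = x.copy()
        scaled[:, 0] *= 7
        cm2 = make_counts(scaled, groups=["FH"] * 5 + ["SFH"] * 5)
        r1 = pn.wald_test(cm, pseudocount=0.0)
        r2 = pn.wald_test(cm2, pseudocount=0.0)
        np.testing.assert_allclose(
            r1["log2fc"].to_numpy(), r2["log2fc"].to_numpy(), atol=1e-9
        )

    def test_null_rate_matches_t_reference(self):
        """With per-gene MoM dispersion estimated on 13 residual df and a
        normal reference, the null Wald statistic is t(13)-distributed to
        first order; the p<0.05 exceedance is 2*P(t13 > 1.96) ~ 0.0715."""
        rates = []
        for seed in range(4):
            cm, _ = pn.simulate_counts(
                pn.null_config(n_genes=800, seed=500 + seed)
            )
            res = pn.wald_test(cm)
            rates.append((res["p_value"] < 0.05).mean())
        expected = 2 * stats.t.sf(stats.norm.ppf(0.975), df=13)
        assert np.mean(rates) == pytest.approx(expected, abs=0.012)

    def test_planted_deg_recovery(self, sim_small):
        """At |log2FC|=2, n=8/7, dispersion 0.05 the planted DEGs must be
        recovered with >= 80% sensitivity at padj<=0.05, |lfc|>=0.5."""
        cm, truth = sim_small
        res = pn.de_analysis(cm)
        sensitivity = res.loc[truth.deg_genes, "is_deg"].mean()
        assert sensitivity >= 0.8
        # and the direction matches the planted sign
        called = res.loc[truth.deg_genes]
        called = called[called["is_deg"]]
        planted_sign = np.sign(truth.genes.loc[called.index, "log2fc"])
        assert (np.sign(called["log2fc"]) == planted_sign).all()


class TestBH:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            pn.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(pn.bh_adjust([0.03]), [0.03])
        np.testing.assert_allclose(pn.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(pn.ValidationError):
            pn.bh_adjust([0.5, 1.2])

    @given(
        ps=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_manual_step_up_and_dominates_p(self, ps):
        """Cross-check against an independent manual step-up computation."""
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            manual[i] = running
        ours = pn.bh_adjust(p)
        np.testing.assert_allclose(ours, manual, rtol=1e-12)
        assert np.all(ours >= p - 1e-15)


class TestCallDegs:
    def test_boundary_values_pass_inclusively(self):
        res = pd.DataFrame(
            {
                "log2fc": [0.5, 0.49, 3.0],
                "padj": [0.05, 0.04, 0.06],
            },
            index=["a", "b", "c"],
        )
        out = pn.call_degs(res)
        assert out.loc["a", "is_deg"]  # both thresholds exactly met
        assert not out.loc["b", "is_deg"]  # fails fold-change bound
        assert not out.loc["c", "is_deg"]  # fails padj bound
        assert out.loc["a", "direction"] == "up_in_SFH"

    def test_direction_follows_sign(self):
        res = pd.DataFrame(
            {"log2fc": [-2.0, 2.0], "padj": [0.01, 0.01]}, index=["d", "u"]
        )
        out = pn.call_degs(res)
        assert out.loc["d", "direction"] == "down_in_SFH"
        assert out.loc["u", "direction"] == "up_in_SFH"
        assert pn.deg_set(out) == {"d", "u"}

    def test_requires_padj(self):
        with pytest.raises(pn.ValidationError, match="padj"):
            pn.call_degs(pd.DataFrame({"log2fc": [1.0]}))
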