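"""Negative-binomial Wald test, normalization, dispersion and BH machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vdegkit as vk
from vdegkit.errors import ConfigError, DataError


def nb_counts(rng, mu, alpha, n):
    if alpha <= 0:
        return rng.poisson(mu[:, None] * np.ones(n))
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + mu[:, None]), size=(len(mu), n))


def two_group_design(n=3):
    cols = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    return pd.DataFrame(
        {"condition": ["C"] * n + ["T"] * n, "day": [4] * 2 * n,
         "replicate": list(range(n)) * 2},
        index=cols,
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10], "b": [5, 10], "c": [5, 10]})
        assert np.allclose(vk.size_factors(counts), 1.0)

    def test_doubled_column_gives_two_to_one_ratio(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = vk.size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_deterministic(self, small_sim):
        counts, *_ = small_sim
        pd.testing.assert_series_equal(vk.size_factors(counts), vk.size_factors(counts))

    def test_no_common_nonzero_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [3, 0]})
        with pytest.raises(DataError, match="pseudo_reference"):
            vk.size_factors(counts)

    def test_pseudo_reference_fallback_handles_sparse_matrices(self):
        counts = pd.DataFrame({"a": [0, 10, 20], "b": [10, 0, 40], "c": [20, 40, 0]})
        f = vk.size_factors(counts, pseudo_reference=True)
        assert (f > 0).all()


class TestEstimateDispersion:
    def test_poisson_data_yields_near_zero_dispersion(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(4, 1, 2000)
        n = 10
        counts = pd.DataFrame(nb_counts(rng, mu, 0.0, 2 * n),
                              columns=two_group_design(n).index)
        f = vk.size_factors(counts)
        disp = vk.estimate_dispersion(counts, two_group_design(n), f)
        assert disp.median() <= 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(4, 1, 2000)
        counts = pd.DataFrame(nb_counts(rng, mu, 0.1, 6),
                              columns=two_group_design(3).index)
        f = vk.size_factors(counts)
        disp = vk.estimate_dispersion(counts, two_group_design(3), f)
        assert 0.05 <= disp.median() <= 0.2

    def test_constant_counts_give_zero_genewise_estimate(self):
        counts = pd.DataFrame({c: [7, 13] for c in two_group_design(3).index})
        f = vk.size_factors(counts)
        disp = vk.estimate_dispersion(
            counts, two_group_design(3), f, n_prior=0.0, floor_at_prior=False
        )
        assert (disp <= 1e-8).all()


class TestWaldTest:
    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(4, 1, 2000)
        design = two_group_design(3)
        counts = pd.DataFrame(nb_counts(rng, mu, 0.1, 6), columns=design.index)
        f = vk.size_factors(counts)
        disp = vk.estimate_dispersion(counts, design, f)
        tab = vk.wald_test(counts, design, vk.ContrastSpec("x", ("T", 4), ("C", 4)), f, disp)
        from scipy import stats

        ks = stats.kstest(tab.loc[tab.tested, "pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_recovers_planted_log2fc(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(5, 0.5, 500)
        design = two_group_design(3)
        # plant log2FC = 2 in a tenth of the genes so size factors stay honest
        shift = np.ones(500)
        shift[:50] = 4.0
        c0 = nb_counts(rng, mu, 0.1, 3)
        c1 = nb_counts(rng, mu * shift, 0.1, 3)
        counts = pd.DataFrame(np.hstack([c0, c1]), columns=design.index)
        f = vk.size_factors(counts)
        disp = vk.estimate_dispersion(counts, design, f)
        tab = vk.wald_test(counts, design, vk.ContrastSpec("x", ("T", 4), ("C", 4)), f, disp)
        assert tab["log2FC"].iloc[:50].mean() == pytest.approx(2.0, abs=0.3)

    def test_swapping_groups_negates_lfc_and_keeps_p(self, small_sim, small_de):
        counts, design, *_ = small_sim
        factors, dispersions, _ = small_de
        fwd = vk.wald_test(counts, design, vk.ContrastSpec("f", ("T", 4), ("C", 4)),
                           factors, dispersions)
        rev = vk.wald_test(counts, design, vk.ContrastSpec("r", ("C", 4), ("T", 4)),
                           factors, dispersions)
        t = fwd["tested"]
        assert np.allclose(fwd.loc[t, "log2FC"], -rev.loc[t, "log2FC"])
        assert np.allclose(fwd.loc[t, "pvalue"], rev.loc[t, "pvalue"])

    def test_all_zero_genes_are_flagged_untested(self, small_sim, small_de):
        counts, design, *_ = small_sim
        factors, dispersions, _ = small_de
        counts = counts.copy()
        counts.iloc[0] = 0
        tab = vk.wald_test(counts, design, vk.ContrastSpec("x", ("T", 4), ("C", 4)),
                           factors, dispersions)
        assert not tab.iloc[0]["tested"] and np.isnan(tab.iloc[0]["pvalue"])


class TestAdjustBh:
    def test_step_up_example(self):
        assert np.allclose(vk.adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert vk.adjust_bh(np.array([0.2]))[0] == pytest.approx(0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_raw(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        ours = vk.adjust_bh(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)
        assert (ours >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            vk.adjust_bh(np.array([0.5, 1.5]))


class TestCallDegs:
    def _table(self, lfc, padj):
        return pd.DataFrame({"log2FC": [lfc], "padj": [padj], "tested": [True]},
                            index=["g"])

    @pytest.mark.parametrize(
        "lfc,padj,included",
        [
            (1.0, 0.01, True),    # |log2FC| boundary is inclusive
            (3.0, 0.05, False),   # padj boundary is strict
            (0.9, 1e-10, False),
            (-1.2, 0.01, True),
        ],
    )
    def test_threshold_boundaries(self, lfc, padj, included):
        degset = vk.call_degs(self._table(lfc, padj))
        assert ("g" in degset) is included
        if included:
            assert degset.signs["g"] == (1 if lfc > 0 else -1)

    def test_sets_shrink_as_thresholds_tighten(self, small_de):
        _, _, tables = small_de
        table = tables["TC"][4]
        loose = vk.call_degs(table, lfc_min=1.0, padj_max=0.05)
        tight_lfc = vk.call_degs(table, lfc_min=1.5, padj_max=0.05)
        tight_p = vk.call_degs(table, lfc_min=1.0, padj_max=0.01)
        assert tight_lfc.genes <= loose.genes
        assert tight_p.genes <= loose.genes

    def test_scale_invariance_of_calls(self, small_sim):
        # doubling one sample's counts is absorbed by the size factors
        counts, design, *_ = small_sim
        scaled = counts.copy()
        scaled["T4_r1"] = scaled["T4_r1"] * 2
        def calls(c):
            f = vk.size_factors(c)
            d = vk.estimate_dispersion(c, design, f)
            t = vk.wald_test(c, design, vk.ContrastSpec("x", ("T", 4), ("C", 4)), f, d)
            return vk.call_degs(t).genes
        a, b = calls(counts), calls(scaled)
        assert a == b
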