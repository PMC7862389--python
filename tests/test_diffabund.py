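"""Normalization, dispersion, NB Wald test, BH, shrinkage and concordance."""

import numpy as np
import pandas as pd
import pytest

from metacompare.diffabund import (
    DifferentialAbundance,
    bh_adjust,
    concordance_analysis,
    estimate_dispersion,
    nb_wald_test,
    normalize_counts,
    shrink_lfc,
    size_factors,
    synthetic_results_from_categories,
)

from conftest import nb_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"a": [3, 10, 7], "b": [3, 10, 7]})
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_column(self):
        c = pd.DataFrame({"a": [10, 20, 40], "b": [20, 40, 80]})
        sf = size_factors(c)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_geometric_mean_near_one_all_positive(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.integers(1, 1000, (200, 8)))
        sf = size_factors(c)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_genera_excluded_from_reference(self):
        # the zero-containing genus must not affect the factors
        base = pd.DataFrame({"a": [10, 20], "b": [20, 40]})
        with_zero = pd.DataFrame({"a": [10, 20, 0], "b": [20, 40, 999]})
        assert np.allclose(size_factors(base), size_factors(with_zero))

    def test_no_all_positive_genus_errors(self):
        c = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="reference"):
            size_factors(c)

    def test_normalization_removes_depth(self):
        c1 = pd.DataFrame({"a": [10, 20, 40]})
        c = pd.DataFrame({"a": [10, 20, 40], "b": [30, 60, 120]})
        norm = normalize_counts(c)
        assert np.allclose(norm["a"], norm["b"], rtol=1e-9)


class TestDispersion:
    def test_poisson_counts_give_small_alpha(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.uniform(np.log(50), np.log(2000), 300))
        counts = nb_counts(rng, mu, 0.0, 50)
        groups = pd.Series(["A"] * 25 + ["B"] * 25, index=counts.columns)
        disp = estimate_dispersion(counts, size_factors(counts), groups)
        assert disp.median() <= 0.01

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(6)
        mu = np.exp(rng.uniform(np.log(50), np.log(2000), 400))
        counts = nb_counts(rng, mu, 0.5, 100)
        groups = pd.Series(["A"] * 50 + ["B"] * 50, index=counts.columns)
        disp = estimate_dispersion(counts, size_factors(counts), groups)
        assert ((disp > 0.3) & (disp < 0.7)).mean() >= 0.9

    def test_all_zero_genus_floored(self):
        rng = np.random.default_rng(7)
        counts = nb_counts(rng, np.full(50, 100.0), 0.1, 10)
        counts.iloc[0] = 0
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=counts.columns)
        disp = estimate_dispersion(counts, size_factors(counts), groups)
        assert disp.iloc[0] == pytest.approx(1e-8)

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"a": [5], "b": [6], "c": [7]}, index=["g"]).T.T
        counts = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        groups = pd.Series(["A", "A", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), groups)


class TestWald:
    def test_identical_groups_give_null(self):
        block = pd.DataFrame({"s1": [10, 100], "s2": [20, 80]})
        counts = pd.concat([block, block.rename(columns={"s1": "s3", "s2": "s4"})],
                           axis=1)
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_wald_test(counts, sf, pd.Series(0.1, index=counts.index), groups)
        assert np.allclose(res["lfc"], 0.0, atol=1e-8)
        assert np.allclose(res["pvalue"], 1.0, atol=1e-6)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        mu = np.exp(rng.uniform(np.log(5), np.log(2000), 2000))
        counts = nb_counts(rng, mu, 0.1, 20)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.columns)
        sf = size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        res = nb_wald_test(counts, sf, disp, groups)
        p = res["pvalue"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_true_effect_detected_with_sign(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = np.exp(rng.uniform(np.log(20), np.log(2000), 200))
            mu[0] = 500.0
            mu_b = mu.copy()
            mu_b[0] = 2000.0  # true LFC = +2
            counts = pd.concat(
                [nb_counts(rng, mu, 0.1, 10, "a"), nb_counts(rng, mu_b, 0.1, 10, "b")],
                axis=1,
            )
            groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.columns)
            sf = size_factors(counts)
            disp = estimate_dispersion(counts, sf, groups)
            res = nb_wald_test(counts, sf, disp, groups)
            padj = bh_adjust(res["pvalue"])
            if padj.iloc[0] < 0.05 and res["lfc"].iloc[0] > 0:
                hits += 1
        assert hits >= 9

    def test_all_zero_genus_gets_nan_p(self):
        rng = np.random.default_rng(3)
        counts = nb_counts(rng, np.full(20, 100.0), 0.1, 8)
        counts.iloc[0] = 0
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        sf = size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        res = nb_wald_test(counts, sf, disp, groups)
        assert np.isnan(res["pvalue"].iloc[0])

    def test_one_group_all_zero_flagged_boundary(self):
        rng = np.random.default_rng(4)
        counts = nb_counts(rng, np.full(20, 200.0), 0.05, 8)
        counts.iloc[0, :4] = 0  # absent in group A, present in B
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        sf = size_factors(counts)
        disp = estimate_dispersion(counts, sf, groups)
        res = nb_wald_test(counts, sf, disp, groups)
        assert bool(res["boundary"].iloc[0])
        assert res["lfc"].iloc[0] > 0  # strongly up in the non-zero group

    def test_agrees_with_pydeseq2_on_strong_effects(self):
        """Independent cross-check: strongly changed genera get the same
        calls and similar fold changes from the reference implementation."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(8)
        mu = np.exp(rng.uniform(np.log(50), np.log(2000), 100))
        mu_b = mu.copy()
        mu_b[:10] *= 8.0  # true LFC = +3 for the first ten genera
        counts = pd.concat(
            [nb_counts(rng, mu, 0.05, 8, "a"), nb_counts(rng, mu_b, 0.05, 8, "b")],
            axis=1,
        )
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=counts.columns)
        res = DifferentialAbundance(counts, groups).fit().frame

        meta = pd.DataFrame({"condition": groups})
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stat.summary()
        ref = stat.results_df

        strong = counts.index[:10]
        assert (res.loc[strong, "padj"] < 0.05).all()
        assert (ref.loc[strong, "padj"] < 0.05).all()
        assert np.allclose(
            res.loc[strong, "lfc"], ref.loc[strong, "log2FoldChange"], atol=0.35
        )


class TestBH:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.005, 0.04, 0.9], [0.015, 0.06, 0.9]),
        ],
    )
    def test_step_up_hand_values(self, pvals, expected):
        adj = bh_adjust(pd.Series(pvals))
        assert np.allclose(adj, expected)

    def test_nan_excluded_from_family(self):
        adj = bh_adjust(pd.Series([0.01, np.nan, 0.02]))
        # m = 2, not 3
        assert adj.iloc[0] == pytest.approx(0.02)
        assert np.isnan(adj.iloc[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(pd.Series([0.5, 1.5]))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = pd.Series(rng.uniform(size=100))
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestShrinkage:
    def test_tiny_se_keeps_mle(self):
        lfc = pd.Series([2.0, -1.0, 0.5, 3.0, -2.5])
        se = pd.Series(1e-6, index=lfc.index)
        assert np.allclose(shrink_lfc(lfc, se), lfc, atol=1e-3)

    def test_pure_noise_shrinks_to_zero(self):
        rng = np.random.default_rng(1)
        se = pd.Series(np.full(200, 2.0))
        lfc = pd.Series(rng.normal(0, 2.0, 200))  # all spread explained by SE
        shrunk = shrink_lfc(lfc, se)
        assert np.abs(shrunk).mean() < 0.1 * np.abs(lfc).mean()

    def test_never_increases_magnitude_or_flips_sign(self):
        rng = np.random.default_rng(2)
        lfc = pd.Series(rng.normal(0, 2, 500))
        se = pd.Series(rng.uniform(0.1, 3.0, 500))
        shrunk = shrink_lfc(lfc, se)
        assert (np.abs(shrunk) <= np.abs(lfc) + 1e-12).all()
        assert ((np.sign(shrunk) == np.sign(lfc)) | (lfc == 0)).all()

    def test_posterior_mean_formula(self):
        # with known tau2, shrunk = lfc * tau2/(tau2 + se2); verify via a
        # constructed set where the moment-matched tau2 is known exactly
        lfc = pd.Series([2.0, -2.0, 2.0, -2.0])
        se = pd.Series([1.0, 1.0, 1.0, 1.0])
        # var(lfc, ddof=0) = 4, mean(se^2) = 1 -> tau2 = 3
        shrunk = shrink_lfc(lfc, se)
        assert np.allclose(shrunk, lfc * 3 / 4)


class TestConcordance:
    def test_hand_signs_two_of_three(self):
        idx = pd.Index(["g1", "g2", "g3"], name="genus")
        a = pd.DataFrame({"lfcShrunk": [1.0, 1.0, -1.0], "lfc": [1, 1, -1],
                          "padj": [0.01] * 3}, index=idx)
        b = pd.DataFrame({"lfcShrunk": [2.0, -1.0, -3.0], "lfc": [2, -1, -3],
                          "padj": [0.01] * 3}, index=idx)
        conc = concordance_analysis(a, b)
        row = conc.table.loc["both"]
        assert (row["concordant"], row["total"]) == (2, 3)
        assert row["percentage"] == pytest.approx(66.7, abs=0.05)

    def test_identical_significant_results_fully_concordant(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"g{i}" for i in range(50)], name="genus")
        lfc = rng.normal(0, 2, 50)
        a = pd.DataFrame({"lfcShrunk": lfc, "lfc": lfc, "padj": 0.001}, index=idx)
        conc = concordance_analysis(a, a.copy())
        assert conc.table.loc["both", "percentage"] == 100.0
        assert conc.r == pytest.approx(1.0)

    def test_zero_lfc_counts_discordant(self):
        idx = pd.Index(["g1"], name="genus")
        a = pd.DataFrame({"lfcShrunk": [0.0], "lfc": [0.0], "padj": [0.01]}, index=idx)
        b = pd.DataFrame({"lfcShrunk": [0.0], "lfc": [0.0], "padj": [0.01]}, index=idx)
        conc = concordance_analysis(a, b)
        assert conc.table.loc["both", "concordant"] == 0

    def test_only_common_genera_used(self):
        ia = pd.Index(["g1", "g2"], name="genus")
        ib = pd.Index(["g2", "g3"], name="genus")
        a = pd.DataFrame({"lfcShrunk": [1, 1], "lfc": [1, 1], "padj": [0.01, 0.01]},
                         index=ia)
        b = pd.DataFrame({"lfcShrunk": [1, 1], "lfc": [1, 1], "padj": [0.01, 0.01]},
                         index=ib)
        conc = concordance_analysis(a, b)
        assert conc.n_common == 1

    def test_empty_common_set_rejected(self):
        a = pd.DataFrame({"lfcShrunk": [1], "lfc": [1], "padj": [0.01]},
                         index=pd.Index(["g1"], name="genus"))
        b = pd.DataFrame({"lfcShrunk": [1], "lfc": [1], "padj": [0.01]},
                         index=pd.Index(["g2"], name="genus"))
        with pytest.raises(ValueError, match="common"):
            concordance_analysis(a, b)

    def test_category_totals_partition_common_genera(self):
        spec = {"both": (7, 10), "16S-only": (2, 5), "shotgun-only": (9, 12),
                "neither": (3, 8)}
        a, b = synthetic_results_from_categories(spec, seed=1)
        conc = concordance_analysis(a, b)
        assert conc.table["total"].sum() == conc.n_common == 35
        for cat, (cc, tot) in spec.items():
            assert conc.table.loc[cat, "concordant"] == cc
            assert conc.table.loc[cat, "total"] == tot


def test_model_results_summary_runs(small_dataset):
    pset, _ = small_dataset
    model = DifferentialAbundance.from_profile_set(pset, "shotgun", "compartment")
    results = model.fit()
    text = results.summary()
    assert "significant" in text
    assert set(results.frame.columns) >= {"baseMean", "lfc", "lfcShrunk", "se",
                                          "pvalue", "padj"}
    f = results.frame.dropna(subset=["padj"])
    assert (f["padj"] >= f["pvalue"] - 1e-12).all()
    assert (f["lfcShrunk"].abs() <= f["lfc"].abs() + 1e-12).all()
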