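"""Normalization, dispersion, NB GLM, Wald/LRT and PCA behaviour, checked
against closed forms, independent simulations and pydeseq2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_count_matrix
from ribotome.counts import (Design, DesignError, bh_adjust, build_design,
                             contrast_vector, estimate_dispersions,
                             estimate_size_factors, filter_low_counts,
                             fit_nb_glm, lrt_interaction, pca_variance,
                             wald_contrast)


def nb_counts(rng, mean, alpha, size):
    """Independent NB generator (mean/dispersion parameterization)."""
    if alpha < 1e-8:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simple_cm(rng, n_genes=50, mean=200.0, alpha=0.05, n_pairs=3,
              conditions=None):
    conditions = conditions or ["naive", "dpi2", "dpi10", "dpi42"]
    n = 2 * n_pairs * len(conditions)
    counts = np.stack([nb_counts(rng, mean, alpha, n)
                       for _ in range(n_genes)])
    return make_count_matrix(counts, conditions, n_pairs)


class TestFilter:
    def test_row_sum_threshold(self):
        counts = np.zeros((3, 24), dtype=int)
        counts[0, 0] = 9
        counts[1, 0] = 10
        counts[2, :10] = 10
        cm = make_count_matrix(counts)
        kept = filter_low_counts(cm, 10)
        assert list(kept.gene_ids) == ["g00002", "g00003"]

    def test_all_zero_gene_removed_with_order_preserved(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(5, 24))
        counts[2] = 0
        cm = make_count_matrix(counts)
        kept = filter_low_counts(cm)
        assert list(kept.gene_ids) == ["g00001", "g00002", "g00004", "g00005"]

    def test_empty_result_warns(self):
        cm = make_count_matrix(np.ones((2, 24), dtype=int))
        with pytest.warns(UserWarning):
            filter_low_counts(cm, min_total=1000)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(1).poisson(100, size=30)
        cm = make_count_matrix(np.tile(col[:, None], 24))
        sf = estimate_size_factors(cm)
        assert np.allclose(sf.factors, 1.0)

    def test_doubled_column_ratio_is_two(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=(40, 4)) + 1
        counts = np.repeat(base, 1, axis=1)
        counts = np.concatenate([counts] * 6, axis=1)[:, :24]
        counts[:, 1] = counts[:, 0] * 2
        sf = estimate_size_factors(make_count_matrix(counts))
        assert sf.factors.iloc[1] / sf.factors.iloc[0] == pytest.approx(2.0)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(80, size=(30, 24)) + 1
        cm = make_count_matrix(counts)
        sf1 = estimate_size_factors(cm)
        perm = rng.permutation(30)
        cm2 = cm.subset_genes(cm.gene_ids[perm])
        sf2 = estimate_size_factors(cm2)
        assert np.allclose(sf1.factors, sf2.factors)

    def test_sample_scaling_scales_factor(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(80, size=(30, 24)) + 1
        sf1 = estimate_size_factors(make_count_matrix(counts))
        scaled = counts.copy()
        scaled[:, 5] *= 3
        sf2 = estimate_size_factors(make_count_matrix(scaled))
        ratio = sf2.factors / sf1.factors
        # geometric-mean renormalization spreads the 3x over all samples
        assert ratio.iloc[5] / ratio.iloc[0] == pytest.approx(3.0)

    def test_requires_zero_free_gene(self):
        counts = np.eye(24, dtype=int) * 5
        with pytest.raises(ValueError, match="zero-free"):
            estimate_size_factors(make_count_matrix(counts))


class TestDispersion:
    def test_poisson_genes_get_small_alpha(self):
        rng = np.random.default_rng(10)
        cm = simple_cm(rng, n_genes=200, mean=300.0, alpha=0.0)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf, moderate=False)
        assert (alpha <= 0.05).mean() >= 0.90

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(11)
        cm = simple_cm(rng, n_genes=200, mean=500.0, alpha=0.5, n_pairs=25)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf)
        assert 0.4 <= alpha.mean() <= 0.6

    def test_constant_zero_gene_floored(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(100, size=(30, 24))
        counts[7] = 0
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf, moderate=False)
        assert alpha.iloc[7] == pytest.approx(1e-8)


def two_group_fit(rng, n_genes, effect_log2, alpha, n_per_group=12,
                  mean=300.0):
    """Fit intercept+group on independently generated two-group NB data."""
    n = 2 * n_per_group
    group = np.array([0.0, 1.0] * n_per_group)
    means = mean * 2.0 ** (group * effect_log2)
    counts = np.stack([
        np.concatenate([nb_counts(rng, m, alpha, 1) for m in means])
        for _ in range(n_genes)])
    cm = make_count_matrix(counts, ["naive"], n_per_group)
    # unit size factors: every gene carries the planted shift, which RLE
    # would (correctly) absorb as a composition change
    from ribotome.counts import SizeFactors
    sf = SizeFactors(factors=pd.Series(1.0, index=cm.counts.columns),
                     reference=pd.Series(dtype=float))
    a = pd.Series(np.full(n_genes, max(alpha, 1e-8)), index=cm.gene_ids)
    design = Design(np.column_stack([np.ones(n), group]),
                    ["intercept", "fraction[OL]"], interaction=True)
    return fit_nb_glm(cm, sf, a, design), cm, sf, a


class TestNbGlm:
    def test_null_fraction_coefficient_near_zero(self):
        rng = np.random.default_rng(20)
        fit, *_ = two_group_fit(rng, 200, 0.0, 0.1)
        beta = fit.coef["fraction[OL]"]
        se = np.sqrt(fit.cov[:, 1, 1])
        assert ((beta.abs() < 3 * se).mean()) >= 0.95

    def test_planted_fraction_effect_recovered(self):
        rng = np.random.default_rng(21)
        fit, *_ = two_group_fit(rng, 200, 1.0, 0.1)
        assert 0.9 <= fit.coef["fraction[OL]"].mean() <= 1.1

    def test_poisson_limit_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        fit, cm, sf, _ = two_group_fit(rng, 5, 0.7, 0.0, n_per_group=8)
        X = fit.design.matrix
        for i, g in enumerate(cm.gene_ids):
            res = sm.GLM(cm.counts.loc[g].to_numpy(), X,
                         family=sm.families.Poisson(),
                         offset=np.log(sf.factors.to_numpy())).fit()
            np.testing.assert_allclose(fit.coef.loc[g].to_numpy(),
                                       res.params / np.log(2), atol=1e-4)

    def test_rank_deficient_design_rejected(self):
        samples = make_count_matrix(np.ones((2, 24), dtype=int)).samples
        samples = samples.copy()
        samples["condition"] = "naive"   # all pairs collide with intercept
        with pytest.raises(DesignError, match="aliased"):
            build_design(samples, ["naive", "dpi2", "dpi10", "dpi42"])


class TestWald:
    def test_zero_contrast_rejected(self):
        rng = np.random.default_rng(30)
        fit, *_ = two_group_fit(rng, 5, 0.0, 0.05, n_per_group=4)
        with pytest.raises(DesignError, match="degenerate"):
            wald_contrast(fit, np.zeros(2))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(31)
        fit, *_ = two_group_fit(rng, 5, 0.0, 0.05, n_per_group=4)
        with pytest.raises(DesignError):
            wald_contrast(fit, np.ones(5))

    def test_interaction_effect_recovered(self):
        """A planted differential-enrichment effect of 1.5 log2 units is
        recovered by the interaction contrast."""
        rng = np.random.default_rng(32)
        n_pairs, conditions = 3, ["naive", "dpi2"]
        design_rows = []
        cm0 = make_count_matrix(
            np.zeros((1, 2 * n_pairs * len(conditions)), dtype=int),
            conditions, n_pairs)
        frac = (cm0.samples["fraction"] == "OL").to_numpy(float)
        cond = (cm0.samples["condition"] == "dpi2").to_numpy(float)
        mu = 400.0 * 2.0 ** (1.0 * frac + 0.5 * cond + 1.5 * frac * cond)
        counts = np.stack([
            np.array([nb_counts(rng, m, 0.05, 1)[0] for m in mu])
            for _ in range(200)])
        cm = make_count_matrix(counts, conditions, n_pairs)
        from ribotome.counts import SizeFactors
        sf = SizeFactors(factors=pd.Series(1.0, index=cm.counts.columns),
                         reference=pd.Series(dtype=float))
        alpha = pd.Series(np.full(200, 0.05), index=cm.gene_ids)
        design = build_design(cm.samples, conditions, pair_term=False)
        fit = fit_nb_glm(cm, sf, alpha, design)
        c = contrast_vector(design, {"fraction[OL]:condition[dpi2]": 1.0})
        res = wald_contrast(fit, c)
        assert 1.35 <= res["log2fc"].mean() <= 1.65


class TestLrt:
    def _fits(self, rng, effect=0.0, n_genes=100, n_per_group=12):
        fit_full, cm, sf, a = two_group_fit(rng, n_genes, effect, 0.1,
                                            n_per_group)
        reduced = Design(np.ones((2 * n_per_group, 1)), ["intercept"],
                         interaction=False)
        fit_red = fit_nb_glm(cm, sf, a, reduced)
        return fit_full, fit_red

    def test_identical_designs_rejected(self):
        rng = np.random.default_rng(40)
        fit, *_ = two_group_fit(rng, 5, 0.0, 0.05, n_per_group=4)
        with pytest.raises(DesignError, match="nested"):
            lrt_interaction(fit, fit)

    def test_power_on_planted_effect(self):
        rng = np.random.default_rng(41)
        fit_full, fit_red = self._fits(rng, effect=2.0, n_genes=100,
                                       n_per_group=3)
        res = lrt_interaction(fit_full, fit_red)
        assert res["pvalue"].median() < 0.01

    def test_wald_lrt_asymptotic_agreement(self):
        """Signed sqrt(LRT) tracks the Wald statistic at large n."""
        rng = np.random.default_rng(42)
        fit_full, fit_red = self._fits(rng, effect=0.3, n_genes=200,
                                       n_per_group=100)
        lrt = lrt_interaction(fit_full, fit_red)
        wald = wald_contrast(fit_full, np.array([0.0, 1.0]))
        signed = np.sign(wald["stat"]) * np.sqrt(lrt["stat"])
        r = np.corrcoef(signed, wald["stat"])[0, 1]
        assert r > 0.99


class TestBh:
    def test_stepup_hand_computation(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_single_p(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_missing_stays_missing(self):
        q = bh_adjust(pd.Series([0.01, np.nan, 0.5]))
        assert np.isnan(q.iloc[1]) and np.isfinite(q.iloc[0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sorted_order(self, pvals):
        p = np.sort(np.asarray(pvals))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestPca:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(50)
        base = rng.poisson(200, size=30) + 1
        counts = np.tile(base[:, None], 24)
        # a block of genes shifts in half the samples: rank-1 structure
        # that normalization cannot absorb
        counts[:8, 12:] = counts[:8, 12:] * 8
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        res = pca_variance(cm, sf, k=3)
        assert res.variance_fraction.iloc[0] > 0.99

    def test_variance_fractions_conserved(self):
        rng = np.random.default_rng(51)
        counts = rng.poisson(100, size=(60, 24)) + 1
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        res = pca_variance(cm, sf, k=24)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_clipped_with_warning(self):
        rng = np.random.default_rng(52)
        cm = make_count_matrix(rng.poisson(100, size=(30, 24)) + 1)
        sf = estimate_size_factors(cm)
        with pytest.warns(UserWarning, match="clipped"):
            res = pca_variance(cm, sf, k=99)
        assert res.scores.shape[1] <= 24

    def test_fraction_separation_on_synthetic_mixture(self, small_experiment):
        _, cm, _ = small_experiment
        cm_f = filter_low_counts(cm)
        sf = estimate_size_factors(cm_f)
        res = pca_variance(cm_f, sf, k=2)
        sign = np.sign(res.scores["PC1"])
        frac = cm_f.samples.set_index("sample_id")["fraction"]
        ol_signs = sign[frac == "OL"]
        tot_signs = sign[frac == "total"]
        assert len(set(ol_signs)) == 1 and len(set(tot_signs)) == 1
        assert ol_signs.iloc[0] != tot_signs.iloc[0]


class TestAgainstDeseq2:
    def test_fraction_lfc_matches_pydeseq2(self):
        """Independent cross-check: our NB-GLM fraction log2 fold changes
        track DESeq2's on the same small dataset."""
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(60)
        n_genes, n_per_group = 150, 6
        effects = rng.normal(0, 1, n_genes)
        group = np.array([0.0, 1.0] * n_per_group)
        counts = np.stack([
            np.concatenate([nb_counts(rng, 200.0 * 2 ** (e * g), 0.05, 1)
                            for g in group])
            for e in effects])
        cm = make_count_matrix(counts, ["naive"], n_per_group)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf)
        design = Design(np.column_stack([np.ones(2 * n_per_group), group]),
                        ["intercept", "fraction[OL]"], interaction=True)
        fit = fit_nb_glm(cm, sf, alpha, design)

        meta = pd.DataFrame({"fraction": np.where(group > 0, "OL", "total")},
                            index=cm.counts.columns)
        dds = DeseqDataSet(counts=cm.counts.T.copy(), metadata=meta,
                           design="~fraction", quiet=True)
        dds.deseq2()
        # pydeseq2 stores coefficients in natural log; flip the level
        # orientation and convert to log2
        lfc_ds = pd.Series(
            dds.varm["LFC"]["fraction[T.total]"] * (-1.0 / np.log(2)),
            index=dds.var_names)
        ours = fit.coef["fraction[OL]"]
        diff = (ours - lfc_ds.loc[ours.index]).abs()
        assert diff.median() < 0.1
        assert np.corrcoef(ours, lfc_ds.loc[ours.index])[0, 1] > 0.98
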