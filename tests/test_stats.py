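"""Statistical primitives: chi-square, Welch, FDR, rank-sum, DEG, screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nichemap.stats import (
    bh_fdr,
    chi2_2x2_yates,
    deg_analysis,
    niche_correlation_screen,
    welch_t_from_summary,
    wilcoxon_rank_sum,
)


class TestChi2Yates:
    def test_niche_ec_enrichment_table(self):
        # EC fraction in the WT HSC niche vs overall population
        _, p = chi2_2x2_yates(21, 233, 5876, 106516)
        assert round(p, 3) == 0.042

    def test_ko_niche_table_highly_significant(self):
        _, p = chi2_2x2_yates(153, 397, 12309, 125319)
        assert p < 0.001

    def test_proportional_table_not_significant(self):
        stat, p = chi2_2x2_yates(10, 10, 100, 100)
        assert stat < 0.5 and p > 0.5

    def test_matches_scipy_contingency(self):
        table = [[37, 63], [140, 260]]
        stat, p = chi2_2x2_yates(37, 63, 140, 260)
        ref = sps.chi2_contingency(table, correction=True)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2_yates(0, 0, 5, 5)

    def test_agrees_with_permutation_oracle(self):
        # conditional Monte-Carlo null (fixed margins, hypergeometric draws)
        a, b, c, d = 30, 70, 52, 48
        stat, p = chi2_2x2_yates(a, b, c, d)
        rng = np.random.default_rng(0)
        n1, m1, n = a + b, a + c, a + b + c + d
        sims = rng.hypergeometric(m1, n - m1, n1, size=200_000)
        stats_sim = np.array(
            [chi2_2x2_yates(x, n1 - x, m1 - x, n - n1 - m1 + x)[0] for x in np.unique(sims)]
        )
        counts = np.array([(sims == x).sum() for x in np.unique(sims)])
        p_mc = counts[stats_sim >= stat - 1e-12].sum() / sims.size
        assert p / 2 <= p_mc <= p * 2


class TestWelch:
    def test_hsc_abundance_contrast(self):
        # planted vs control HSC abundance summary statistics
        _, _, p = welch_t_from_summary(0.848, 0.183, 3, 0.334, 0.301, 4)
        assert round(p, 2) == 0.04

    def test_identical_groups(self):
        t, _, p = welch_t_from_summary(1.0, 0.5, 5, 1.0, 0.5, 5)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_equal_variance_equal_n_matches_pooled(self):
        t, df, p = welch_t_from_summary(2.0, 1.0, 8, 1.2, 1.0, 8)
        assert df == pytest.approx(14.0)
        ref = sps.ttest_ind_from_stats(2.0, 1.0, 8, 1.2, 1.0, 8, equal_var=True)
        assert p == pytest.approx(ref.pvalue)

    def test_matches_direct_test_on_matching_samples(self):
        rng = np.random.default_rng(1)
        for m1, s1, n1, m2, s2, n2 in [(0.9, 0.2, 5, 0.4, 0.35, 7)]:
            x = rng.normal(size=n1)
            x = (x - x.mean()) / x.std(ddof=1) * s1 + m1
            y = rng.normal(size=n2)
            y = (y - y.mean()) / y.std(ddof=1) * s2 + m2
            t, _, p = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0.1, 1, 2, 0.1, 4)


class TestBHFDR:
    def test_stepup_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        q = bh_fdr([0.3, 0.3, 0.3])
        assert np.allclose(q, 0.3)

    def test_single_p(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_monotone_in_rank_and_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        q = bh_fdr([0.02, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestWilcoxon:
    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3, 1], [1, 1, 2, 3]) == pytest.approx(1.0)

    def test_separated_small_groups_exact(self):
        # all 2 extreme assignments out of C(6,3)=20 -> p = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(0.7, 1, size=35)
        p1 = wilcoxon_rank_sum(x, y)
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def _toy_norm(rng, n_per_rep=80, n_reps=4, n_genes=8, planted=None, planted_reps=None):
    """Two cell groups x replicates; `planted` genes get a 4x shift in group A."""
    cells, rows, groups, reps = [], [], [], []
    for r in range(n_reps):
        for grp, tag in ((0, "A"), (1, "B")):
            lam = np.full(n_genes, 5.0)
            block = rng.poisson(
                np.tile(lam, (n_per_rep, 1))
                * np.where(
                    (np.arange(n_genes)[None, :] == planted) & (grp == 0)
                    & (planted_reps is None or r in planted_reps),
                    4.0,
                    1.0,
                )
            )
            for i in range(n_per_rep):
                cells.append(f"r{r}{tag}{i}")
                rows.append(block[i])
                groups.append(tag)
                reps.append(r)
    norm = pd.DataFrame(rows, index=cells, columns=[f"g{j}" for j in range(n_genes)])
    meta = pd.DataFrame({"group": groups, "rep": reps}, index=cells)
    return norm, meta


class TestDEGAnalysis:
    def test_null_gene_not_significant_and_planted_gene_found(self):
        rng = np.random.default_rng(10)
        norm, meta = _toy_norm(rng, planted=2)
        res = deg_analysis(
            norm,
            meta.index[meta.group == "A"],
            meta.index[meta.group == "B"],
            meta["rep"],
            ([0, 1], [2, 3]),
        )
        assert res.loc["g2", "significant"]
        assert res.loc["g2", "log2_fold_change"] > 1
        assert not res.drop("g2").significant.any()

    def test_effect_in_one_replicate_group_disregarded(self):
        # 4x effect planted only in replicates 0-1 -> unreproducible
        rng = np.random.default_rng(11)
        norm, meta = _toy_norm(rng, planted=2, planted_reps=(0, 1))
        res = deg_analysis(
            norm,
            meta.index[meta.group == "A"],
            meta.index[meta.group == "B"],
            meta["rep"],
            ([0, 1], [2, 3]),
        )
        assert not res.loc["g2", "significant"]
        assert res.loc["g2", "p_group2"] >= 0.1 or not res.loc["g2", "direction_consistent"]

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(12)
        norm, meta = _toy_norm(rng, n_per_rep=5, n_reps=2)
        with pytest.raises(ValueError, match="disjoint"):
            deg_analysis(norm, norm.index[:5], norm.index[:5], meta["rep"], ([0], [1]))

    def test_empty_replicate_group_rejected(self):
        rng = np.random.default_rng(13)
        norm, meta = _toy_norm(rng, n_per_rep=5, n_reps=2)
        with pytest.raises(ValueError):
            deg_analysis(
                norm,
                meta.index[meta.group == "A"],
                meta.index[meta.group == "B"],
                meta["rep"],
                ([], [0, 1]),
            )


class TestCorrelationScreen:
    def test_marker_identical_gene_reported_with_r_one(self):
        rng = np.random.default_rng(20)
        n = 100
        marker = rng.poisson(5.0, n).astype(float)
        df = pd.DataFrame(
            {"Fstl1": marker, "shadow": marker, "noise": rng.poisson(5.0, n)}
        )
        out = niche_correlation_screen(df, {"AEC": ["Fstl1"]}, ["shadow", "noise"])
        row = out[out.niche_gene == "shadow"]
        assert len(row) == 1 and row.iloc[0].r == pytest.approx(1.0)
        assert row.iloc[0].cell_type == "AEC"

    def test_planted_correlation_recovered_under_right_type(self):
        rng = np.random.default_rng(21)
        n = 300
        base = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "Fstl1": base + rng.normal(scale=1.0, size=n),
                "Stab2": rng.normal(size=n),
                "geneX": base + rng.normal(scale=1.0, size=n),
            }
        )
        out = niche_correlation_screen(
            df, {"AEC": ["Fstl1"], "SEC": ["Stab2"]}, ["geneX"]
        )
        hits = out[(out.niche_gene == "geneX") & (out.cell_type == "AEC")]
        assert len(hits) == 1 and hits.iloc[0].r > 0.3
        assert not ((out.niche_gene == "geneX") & (out.cell_type == "SEC")).any()

    def test_constant_vector_skipped(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0], "flat": [5.0] * 4})
        out = niche_correlation_screen(df, {"T": ["m"]}, ["flat"])
        assert out.empty

    def test_too_few_cells_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3"):
            niche_correlation_screen(df, {"T": ["a"]}, ["b"])
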