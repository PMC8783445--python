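"""RPKM, two-group tests, BH adjustment, DE pipeline, PCA and z-scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microloh.rnaseq import (
    ExpressionMatrix,
    bh_adjust,
    differential_expression,
    oneway_f,
    paired_t,
    pca_scores,
    rpkm,
    welch_t,
    zscore_rows,
)
from microloh.synth.expression import simulate_expression


def _matrix(counts, lengths=None, groups=None, pairs=None, libs=None):
    counts = pd.DataFrame(counts)
    if lengths is None:
        lengths = pd.Series(1_000.0, index=counts.index)
    if groups is None:
        half = counts.shape[1] // 2
        groups = pd.Series(["a"] * half + ["b"] * half, index=counts.columns)
    return ExpressionMatrix(
        counts=counts, gene_lengths=lengths, groups=groups, pairs=pairs,
        library_sizes=libs,
    )


class TestRpkm:
    def test_textbook_formula(self):
        m = _matrix(
            {"s1": [10], "s2": [10]},
            lengths=pd.Series([1_000.0]),
            groups=pd.Series(["a", "b"], index=["s1", "s2"]),
            libs=pd.Series([1e6, 2e6], index=["s1", "s2"]),
        )
        vals = rpkm(m)
        assert vals.loc[0, "s1"] == pytest.approx(10.0)
        # doubling the library size halves RPKM
        assert vals.loc[0, "s2"] == pytest.approx(5.0)

    def test_zero_counts_zero_rpkm(self):
        m = _matrix({"s1": [0, 5], "s2": [0, 5]},
                    groups=pd.Series(["a", "b"], index=["s1", "s2"]))
        assert rpkm(m).loc[0].eq(0).all()

    def test_nonpositive_gene_length_rejected(self):
        with pytest.raises(ValueError):
            _matrix({"s1": [1], "s2": [1]}, lengths=pd.Series([0.0]),
                    groups=pd.Series(["a", "b"], index=["s1", "s2"]))


class TestGroupTests:
    def test_identical_groups_p_one(self):
        m = _matrix({f"s{i}": [5, 7] for i in range(6)})
        p = welch_t(m)
        assert np.allclose(p, 1.0)

    def test_welch_matches_textbook_computation(self):
        """3 vs 3, means 10/20, sd 1: t and Welch-Satterthwaite df by hand."""
        a, b = np.array([9.0, 10.0, 11.0]), np.array([19.0, 20.0, 21.0])
        m = _matrix({
            "a1": [a[0]], "a2": [a[1]], "a3": [a[2]],
            "b1": [b[0]], "b2": [b[1]], "b3": [b[2]],
        })
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert welch_t(m).iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_null_welch_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.normal(100, 10, size=(10_000, 10)),
            columns=[f"s{i}" for i in range(10)],
        ).clip(lower=0)
        m = _matrix(counts)
        p = welch_t(m)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_paired_t_uses_pairing(self):
        counts = {f"x{i}": [10 + i] for i in range(4)} | {f"y{i}": [12 + i] for i in range(4)}
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=[f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)])
        pairs = pd.Series([f"p{i}" for i in range(4)] * 2, index=groups.index)
        m = _matrix(counts, groups=groups, pairs=pairs)
        # constant within-pair difference of 2 -> paired test is degenerate-strong
        diffs = np.array([2.0] * 4)
        assert paired_t(m).iloc[0] < 1e-6 or np.isnan(paired_t(m).iloc[0])

    def test_paired_t_requires_complete_pairs(self):
        counts = {f"x{i}": [1] for i in range(2)} | {f"y{i}": [2] for i in range(2)}
        groups = pd.Series(["a", "a", "b", "b"], index=list(counts))
        pairs = pd.Series(["p0", "p1", "p0", "p2"], index=list(counts))
        with pytest.raises(ValueError):
            paired_t(_matrix(counts, groups=groups, pairs=pairs))

    def test_f_test_three_groups_matches_scipy(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(20, 9)),
                              columns=[f"s{i}" for i in range(9)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=counts.columns)
        m = _matrix(counts, groups=groups)
        p = oneway_f(m)
        expected = stats.f_oneway(
            counts.iloc[:, :3], counts.iloc[:, 3:6], counts.iloc[:, 6:], axis=1
        ).pvalue
        np.testing.assert_allclose(p.values, expected)


def _bh_bruteforce(p):
    """Independent step-up oracle straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = [
            p[j] * m / (list(order).index(j) + 1)
            for j in order[rank_idx:]
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for n in (1, 2, 17, 100, 1_000):
            p = rng.uniform(0, 1, size=n)
            np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)

    def test_q_at_least_p_and_monotone_in_rank(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDifferentialExpression:
    def test_planted_degs_recovered_with_high_sensitivity(self):
        m = simulate_expression(seed=0)
        result = differential_expression(m)
        sig = set(result.significant_genes)
        planted = set(m.truth["planted_degs"])
        sensitivity = len(sig & planted) / len(planted)
        assert sensitivity >= 0.95

    def test_null_simulation_controls_fdr(self):
        m = simulate_expression(n_planted_deg=0, allele_rule=False, seed=1)
        result = differential_expression(m, fdr=0.05)
        # no true positives exist; any discovery is false
        assert int(result.table["significant"].sum()) <= 3

    def test_allzero_genes_dropped_from_testing(self):
        m = simulate_expression(n_genes=100, n_planted_deg=5, seed=2)
        m.counts.iloc[10] = 0
        result = differential_expression(m)
        assert result.n_dropped_allzero >= 1
        assert m.counts.index[10] not in result.table.index

    def test_log2fc_sign_follows_group_order(self):
        m = simulate_expression(seed=3)
        result = differential_expression(m)
        # receptor gene: EYFP_neg mean is twice EYFP_pos -> positive log2fc
        assert result.table.loc["Cx3cr1", "log2fc"] > 0.5
        # reporter genes absent in EYFP_neg -> strongly negative
        assert result.table.loc["Eyfp", "log2fc"] < -2

    def test_paired_and_welch_agree_in_ranking(self):
        m = simulate_expression(seed=4)
        pw = differential_expression(m, paired=False).table["p"]
        pp = differential_expression(m, paired=True).table["p"]
        joint = pd.concat([pw.rank(), pp.rank()], axis=1).dropna()
        rho = joint.corr(method="spearman").iloc[0, 1]
        assert rho > 0.7


class TestDosageRules:
    def test_receptor_rpkm_ratio_and_silent_reporters(self):
        m = simulate_expression(n_pairs=5, seed=5)
        vals = rpkm(m)
        neg = m.groups[m.groups == "EYFP_neg"].index
        pos = m.groups[m.groups == "EYFP_pos"].index
        ratio = vals.loc["Cx3cr1", neg].mean() / vals.loc["Cx3cr1", pos].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)
        assert (m.counts.loc["Cre", neg] == 0).all()
        assert (m.counts.loc["Eyfp", neg] == 0).all()
        assert (m.counts.loc[["Cre", "Eyfp"], pos] > 0).to_numpy().any()

    def test_no_planted_no_effect_groups_exchangeable(self):
        m = simulate_expression(n_planted_deg=0, effect_log2fc=0.0,
                                allele_rule=False, seed=6)
        result = differential_expression(m)
        assert int(result.table["significant"].sum()) <= 3


class TestPcaZscore:
    def test_zscore_rows_standardized_and_constant_excluded(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(10, 3, size=(30, 8)))
        values.iloc[4] = 7.0  # constant row
        z, excluded = zscore_rows(values)
        assert list(excluded) == [4]
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0)

    def test_duplicated_groups_separate_on_pc1(self):
        rng = np.random.default_rng(6)
        base_a = rng.poisson(200, size=50)
        base_b = rng.poisson(200, size=50)
        counts = pd.DataFrame(
            {f"a{i}": base_a + rng.poisson(2, 50) for i in range(4)}
            | {f"b{i}": base_b + rng.poisson(2, 50) for i in range(4)}
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
        m = _matrix(counts, groups=groups)
        scores = pca_scores(m, n_components=2)
        a_scores = scores.loc[[f"a{i}" for i in range(4)], "PC1"]
        b_scores = scores.loc[[f"b{i}" for i in range(4)], "PC1"]
        gap = abs(a_scores.mean() - b_scores.mean())
        spread = max(a_scores.std(), b_scores.std())
        assert gap > 10 * spread

    def test_prefilter_restricts_gene_set(self):
        m = simulate_expression(n_genes=200, n_planted_deg=10, seed=7)
        p = welch_t(m)
        scores_all = pca_scores(m)
        scores_filtered = pca_scores(m, prefilter_p=p, p_cutoff=0.05)
        assert scores_filtered.shape == scores_all.shape  # same samples either way
        with pytest.raises(ValueError):
            pca_scores(m, prefilter_p=pd.Series(1.0, index=m.counts.index))
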