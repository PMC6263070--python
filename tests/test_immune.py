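import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from combosig import synthdata as sd
from combosig.formats import ExpressionMatrix
from combosig.immune import (
    genewise_permutation_test,
    module_score,
    score_group_tests,
    spearman,
    stratify_infiltration,
)


def make_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            scale="log2")


class TestModuleScore:
    def test_single_gene_set_is_that_genes_zscore(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 10))
        m = make_matrix(X)
        score = module_score(m, ["G002"])
        x = X[2]
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-12)

    def test_mean_across_samples_near_zero(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(50, 20)))
        score = module_score(m, [f"G{i:03d}" for i in range(10)])
        assert abs(score.mean()) < 1e-12

    def test_zero_variance_members_dropped_then_error(self):
        X = np.ones((3, 4))
        X[2] = [1.0, 2.0, 3.0, 4.0]
        m = make_matrix(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            score = module_score(m, ["G000", "G002"])
        assert np.isfinite(score).all()
        with pytest.raises(ValueError, match="zero variance"):
            module_score(m, ["G000", "G001"])

    def test_planted_module_activity_recovered(self):
        model = sd.CohortModel(n_samples=500, n_genes=400,
                               immune_idx=np.arange(30), ifn_idx=np.arange(30, 60))
        matrix, truth = sd.simulate_cohort(model, seed=5)
        genes = matrix.gene_ids
        score = module_score(matrix, [genes[i] for i in range(30)])
        rho, _ = spearman(score.to_numpy(), truth["infiltration"].to_numpy())
        assert rho > 0.9


class TestStratify:
    def test_exact_template_copies_recovered(self):
        rng = np.random.default_rng(2)
        templates = rng.normal(size=(12, 3)) * 2
        X = np.repeat(templates, 3, axis=1)  # 9 samples, 3 per template
        m = make_matrix(X)
        labels = stratify_infiltration(m, m.gene_ids, k=3)
        truth = np.repeat([0, 1, 2], 3)
        assert adjusted_rand_score(truth, labels.cat.codes.to_numpy()) == 1.0

    def test_generator_mixture_recovered(self):
        model = sd.CohortModel(n_samples=300, n_genes=300,
                               immune_idx=np.arange(40), ifn_idx=np.arange(40, 70),
                               noise_sd=0.5)
        matrix, truth = sd.simulate_cohort(model, seed=6)
        immune_set = [matrix.gene_ids[i] for i in range(40)]
        labels = stratify_infiltration(matrix, immune_set, k=3)
        ari = adjusted_rand_score(truth["group"], labels.astype(str))
        assert ari >= 0.9

    def test_group_means_strictly_increasing(self):
        model = sd.CohortModel(n_samples=150, n_genes=200,
                               immune_idx=np.arange(30), ifn_idx=np.arange(30, 60))
        matrix, _ = sd.simulate_cohort(model, seed=7)
        immune_set = [matrix.gene_ids[i] for i in range(30)]
        labels = stratify_infiltration(matrix, immune_set, k=3)
        score = module_score(matrix, immune_set)
        means = score.groupby(labels, observed=True).mean()
        assert means["low"] < means["medium"] < means["high"]

    def test_k_exceeding_samples_rejected(self):
        m = make_matrix(np.random.default_rng(8).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="k exceeds"):
            stratify_infiltration(m, m.gene_ids, k=5)


class TestGroupTests:
    def test_equal_means_and_variances_capped_at_one(self):
        scores = pd.Series([1.0, 2.0, 3.0] * 3, index=[f"s{i}" for i in range(9)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=scores.index)
        res = score_group_tests(scores, groups)
        assert res.f == 0.0 and res.p == 1.0
        assert (res.pairwise["p_adj"] == 1.0).all()

    def test_three_group_direct_formula_oracle(self):
        vals = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [5.0, 7.0, 9.0]}
        scores = pd.Series(sum(vals.values(), []), index=[f"s{i}" for i in range(9)])
        groups = pd.Series(sum([[k] * 3 for k in vals], []), index=scores.index)
        res = score_group_tests(scores, groups)
        f_ref, p_ref = stats.f_oneway(*vals.values())
        assert res.f == pytest.approx(f_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        for _, row in res.pairwise.iterrows():
            _, p_raw = stats.ttest_ind(vals[row["group_a"]], vals[row["group_b"]])
            assert row["p_raw"] == pytest.approx(p_raw, abs=1e-10)
            assert row["p_adj"] == pytest.approx(min(1.0, p_raw * 3), abs=1e-10)

    def test_two_groups_bonferroni_factor_one(self):
        scores = pd.Series([1.0, 2.0, 5.0, 6.0], index=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=scores.index)
        res = score_group_tests(scores, groups)
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(
            res.pairwise["p_raw"].iloc[0]
        )

    def test_singleton_group_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = pd.Series(["x", "x", "y"], index=scores.index)
        with pytest.raises(ValueError, match="singleton"):
            score_group_tests(scores, groups)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([4.0, 4.0, 6.0, 2.0, 7.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        rho_ref = (rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc))
        assert spearman(x, y)[0] == pytest.approx(rho_ref, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGenewisePermutation:
    def _cohort(self, seed=0, loading_ifn=0.8, n=120, g=200):
        model = sd.CohortModel(n_samples=n, n_genes=g,
                               immune_idx=np.arange(25), ifn_idx=np.arange(25, 50),
                               loading_ifn=loading_ifn)
        matrix, truth = sd.simulate_cohort(model, seed=seed)
        genes = matrix.gene_ids
        immune_set = [genes[i] for i in range(25)]
        ifn_set = [genes[i] for i in range(25, 50)]
        return matrix, immune_set, ifn_set

    def test_planted_association_hits_p_floor(self):
        matrix, immune_set, ifn_set = self._cohort()
        imm = module_score(matrix, immune_set)
        res = genewise_permutation_test(matrix, ifn_set, imm, n_perm=500, seed=1,
                                        exclude=immune_set)
        assert res.p == pytest.approx(1 / 501)
        assert res.rho > 0.5

    def test_exhaustive_small_background_binomial_tolerance(self):
        # tiny background: 6 genes, target size 2 -> only C(6,2)=15 null sets,
        # so the sampled p must sit near the exact enumeration value
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 30))
        m = make_matrix(X)
        genes = m.gene_ids
        immune_set = genes[:2]
        target = genes[2:4]
        background = genes[2:8]  # includes target; 6 genes, C(6,2)=15 null sets
        imm = module_score(m, immune_set)
        res = genewise_permutation_test(m, target, imm, n_perm=6000, seed=4,
                                        exclude=immune_set)
        rho_obs = res.rho
        mags = []
        for pair in itertools.combinations(range(2, 8), 2):
            score = module_score(m, [genes[i] for i in pair])
            mags.append(spearman(score.to_numpy(), imm.to_numpy())[0])
        exact = np.mean([v >= rho_obs - 1e-12 for v in mags])
        exact_p = (1 + exact * 6000) / 6001  # sampled estimator's expectation
        se = np.sqrt(exact * (1 - exact) / 6000)
        assert abs(res.p - exact_p) < 4 * se + 1e-3

    def test_background_smaller_than_target_rejected(self):
        matrix, immune_set, ifn_set = self._cohort()
        almost_all = matrix.gene_ids[:190]
        with pytest.raises(ValueError, match="background"):
            genewise_permutation_test(matrix, ifn_set,
                                      module_score(matrix, immune_set),
                                      n_perm=10, seed=0, exclude=almost_all)

    def test_sample_reordering_invariance(self):
        matrix, immune_set, ifn_set = self._cohort(seed=5)
        imm = module_score(matrix, immune_set)
        res1 = genewise_permutation_test(matrix, ifn_set, imm, n_perm=300, seed=6,
                                         exclude=immune_set)
        perm = np.random.default_rng(7).permutation(matrix.shape[1])
        shuffled = ExpressionMatrix(matrix.frame.iloc[:, perm], scale="log2")
        res2 = genewise_permutation_test(shuffled, ifn_set, imm[shuffled.sample_ids],
                                         n_perm=300, seed=6, exclude=immune_set)
        assert res1.p == res2.p
        assert res1.rho == pytest.approx(res2.rho, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        # zero ifn loading: every background gene is unrelated to
        # infiltration, so random targets give uniform p
        matrix, immune_set, _ = self._cohort(seed=8, loading_ifn=0.0)
        imm = module_score(matrix, immune_set)
        background = matrix.gene_ids[60:]
        rng = np.random.default_rng(9)
        ps = []
        for seed in range(40):
            target = list(rng.choice(background, size=10, replace=False))
            res = genewise_permutation_test(matrix, target, imm, n_perm=99,
                                            seed=seed, exclude=immune_set)
            ps.append(res.p)
        assert 0.15 < np.mean(ps) < 0.85
        assert min(ps) < 0.35 and max(ps) > 0.65

    def test_sample_unit_alternative(self):
        matrix, immune_set, ifn_set = self._cohort(seed=10)
        imm = module_score(matrix, immune_set)
        res = genewise_permutation_test(matrix, ifn_set, imm, n_perm=200, seed=11,
                                        exclude=immune_set, unit="samples")
        assert res.unit == "samples" and 1 / 201 <= res.p <= 1.0
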