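"""Differential expression: OLS oracle equivalence, specificity calls,
ridge behavior, and the two gene-set procedures."""

import numpy as np
import pandas as pd
import pytest

from cardiosplice.de import (classify_specific, fisher_isoformDE_geneset,
                             fit_linear_de, fit_ridge_de, gsea_effectsize_ttest)
from cardiosplice.experiments import (conditional_mle_enumeration,
                                      enumerate_small_tables, ols_oracle_study)
from cardiosplice.io import FeatureMatrix, GeneSet
from cardiosplice.stats import fisher_2x2, ols_per_feature


def _samples(n1, n2, seed=0):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "subject_id": [f"u{i}" for i in range(n)],
        "tissue": ["iPSC-CVPC"] * n1 + ["adult_heart"] * n2,
        "sex": rng.choice(["F", "M"], n),
        "total_reads": rng.integers(10**7, 10**8, n),
        "pct_autosomal": rng.uniform(0.7, 0.9, n),
        "pct_mito": rng.uniform(0.02, 0.2, n),
    })


class TestLinearDE:
    def test_exact_effect_without_noise(self):
        samples = _samples(10, 10, seed=3)
        group = (samples["tissue"] == "iPSC-CVPC").to_numpy(float)
        y = 2.0 * group  # covariates present but Y depends only on T
        norm = FeatureMatrix(pd.DataFrame([y], index=["f"],
                                          columns=samples["sample_id"]),
                             "normalized")
        de = fit_linear_de(norm, samples, "iPSC-CVPC", "adult_heart")
        assert de["beta"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        res = ols_oracle_study(seed=5, n_designs=10)
        assert res["max"] < 1e-8

    def test_rank_deficient_design_rejected(self):
        samples = _samples(10, 10)
        samples["pct_autosomal"] = 0.8  # constant column
        norm = FeatureMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(3, 20)),
                                          index=list("abc"),
                                          columns=samples["sample_id"]),
                             "normalized")
        with pytest.raises(ValueError, match="rank"):
            fit_linear_de(norm, samples, "iPSC-CVPC", "adult_heart")

    def test_too_few_samples_rejected(self):
        samples = _samples(3, 3)
        norm = FeatureMatrix(pd.DataFrame(np.ones((1, 6)) + np.arange(6),
                                          index=["f"],
                                          columns=samples["sample_id"]),
                             "normalized")
        with pytest.raises(ValueError):
            fit_linear_de(norm, samples, "iPSC-CVPC", "adult_heart")


class TestClassifySpecific:
    @pytest.mark.parametrize("mean1,mean2,p_adj,expected", [
        (15.0, 3.0, 1e-10, "DE_only"),        # log2(16/4) = 2 exactly: strict >
        (63.0, 3.0, 1e-10, "tissue1_specific"),  # log2(64/4) = 4
        (63.0, 3.0, 0.2, "not_DE"),           # not significant regardless
        (3.0, 63.0, 1e-10, "tissue2_specific"),
    ])
    def test_boundaries(self, mean1, mean2, p_adj, expected):
        samples = _samples(4, 4)
        vals = np.r_[np.full(4, mean1), np.full(4, mean2)]
        tpm = FeatureMatrix(pd.DataFrame([vals], index=["f"],
                                         columns=samples["sample_id"]), "tpm")
        de = pd.DataFrame({"feature_id": ["f"], "beta": [1.0], "se": [0.1],
                           "p": [p_adj], "p_adj": [p_adj]})
        out = classify_specific(de, tpm, samples, "iPSC-CVPC", "adult_heart")
        assert out["cls"].iloc[0] == expected
        assert out["log2_ratio"].iloc[0] == pytest.approx(
            np.log2((mean1 + 1) / (mean2 + 1)))


class TestRidge:
    def _norm_and_design(self, n=60, p_extra=True, seed=0):
        rng = np.random.default_rng(seed)
        samples = _samples(n // 2, n // 2, seed=seed)
        group = (samples["tissue"] == "iPSC-CVPC").to_numpy(float)
        Y = rng.normal(size=(30, n)) + group * rng.normal(size=(30, 1))
        norm = FeatureMatrix(pd.DataFrame(Y, index=[f"f{i:02d}" for i in range(30)],
                                          columns=samples["sample_id"]),
                             "normalized")
        props = None
        if p_extra:
            props = pd.DataFrame(rng.dirichlet(np.ones(6) * 3, size=n),
                                 index=samples["sample_id"],
                                 columns=[f"ct{k}" for k in range(6)])
        return norm, samples, group, props

    def test_collinear_proportions_stay_finite(self):
        norm, samples, group, props = self._norm_and_design()
        with pytest.warns(UserWarning):
            # proportions sum to one: OLS would be singular with an intercept
            out = fit_ridge_de(norm, samples, group, proportions=props)
        assert np.isfinite(out[["beta", "se", "p"]].to_numpy()).all()

    def test_shrinkage_monotone_in_lambda(self):
        norm, samples, group, _ = self._norm_and_design(p_extra=False)
        norms = []
        for lam in [0.0, 1.0, 10.0, 100.0, 1e4]:
            out = fit_ridge_de(norm, samples, group, lam=lam)
            norms.append(np.linalg.norm(out["beta"]))
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.1 * norms[0]

    def test_lambda_zero_equals_ols_on_standardized_design(self):
        from cardiosplice.experiments import ridge_limit_study
        res = ridge_limit_study(seed=2, n_features=50)
        assert res["lambda0_max_abs_diff"] < 1e-8
        assert res["gcv_finite"]

    def test_planted_proportion_association_detected(self):
        rng = np.random.default_rng(7)
        n = 110
        samples = _samples(55, 55, seed=7)
        props = pd.DataFrame(rng.dirichlet(np.ones(6) * 3, size=n),
                             index=samples["sample_id"],
                             columns=[f"ct{k}" for k in range(6)])
        y = 1.5 * props["ct0"].to_numpy() + rng.normal(0, 0.25, n)
        norm = FeatureMatrix(pd.DataFrame([y], index=["f"],
                                          columns=samples["sample_id"]),
                             "normalized")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = fit_ridge_de(norm, samples, None, proportions=props)
        row = out[(out["coefficient"] == "ct0")]
        assert row["p_adj"].iloc[0] < 0.05


class TestGeneSetProcedures:
    def test_shifted_set_detected(self):
        rng = np.random.default_rng(0)
        effects = pd.Series(rng.normal(size=2000),
                            index=[f"g{i}" for i in range(2000)])
        members = set(effects.index[:50])
        effects.loc[list(members)] += 1.0
        res = gsea_effectsize_ttest(effects, [GeneSet("S", "GO", members)])
        assert res["p"].iloc[0] < 1e-10

    def test_set_equal_to_universe_skipped(self):
        effects = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning, match="skipped"):
            res = gsea_effectsize_ttest(effects,
                                        [GeneSet("S", "GO", {"a", "b", "c"})])
        assert len(res) == 0

    def test_fisher_balanced_table(self):
        sets = [GeneSet("S", "GO", {f"a{i}" for i in range(10)}
                        | {f"b{i}" for i in range(10)})]
        g1 = {f"a{i}" for i in range(10)} | {f"x{i}" for i in range(10)}
        g2 = {f"b{i}" for i in range(10)} | {f"y{i}" for i in range(10)}
        res = fisher_isoformDE_geneset(g1, g2, sets)
        assert res["statistic"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_fisher_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_isoformDE_geneset(set(), {"a"}, [])


class TestExactTestOracle:
    def test_conditional_mle_matches_enumeration_on_small_tables(self):
        # spot-check here; the exhaustive small-table sweep runs separately
        for tab in [(9, 1, 1, 9), (3, 2, 2, 3), (5, 0, 2, 5), (0, 5, 5, 0),
                    (2, 2, 2, 2), (1, 4, 3, 2)]:
            or_i, p_i = fisher_2x2(tab)
            or_r, p_r = conditional_mle_enumeration(tab)
            assert p_i == pytest.approx(p_r, abs=1e-10)
            if np.isfinite(or_r) and or_r > 0:
                assert or_i == pytest.approx(or_r, rel=1e-4)
            else:
                assert or_i == or_r or (np.isinf(or_i) and np.isinf(or_r))

    def test_enumeration_covers_all_tables(self):
        tabs = list(enumerate_small_tables(4))
        assert len(tabs) == len(set(tabs))
        assert all(sum(t) <= 4 for t in tabs)
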