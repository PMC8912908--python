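"""RBP-panel PCA, PC-space distances, the effect-size location test, and
the fetal-reversion statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiosplice.heart_failure import (group_distances, joint_rbp_pca,
                                        rbp_effectsize_location_test,
                                        reversion_statistic)
from cardiosplice.io import FeatureMatrix


def _tpm_matrix(seed=0, n_rbp=20, n_samples=30):
    rng = np.random.default_rng(seed)
    ids = [f"R{i:02d}" for i in range(n_rbp)]
    df = pd.DataFrame(rng.lognormal(3, 1, size=(n_rbp, n_samples)),
                      index=ids, columns=[f"s{i}" for i in range(n_samples)])
    return FeatureMatrix(df, "tpm"), ids


class TestJointPCA:
    def test_duplicated_samples_get_identical_coordinates(self):
        tpm, ids = _tpm_matrix()
        dup = tpm.values.copy()
        dup["s0_copy"] = dup["s0"]
        pcs, _, _ = joint_rbp_pca(FeatureMatrix(dup, "tpm"), ids)
        assert np.allclose(pcs.loc["s0"], pcs.loc["s0_copy"])

    def test_variance_explained_non_increasing_and_bounded(self):
        tpm, ids = _tpm_matrix()
        _, var_exp, _ = joint_rbp_pca(tpm, ids)
        assert (np.diff(var_exp) <= 1e-12).all()
        assert var_exp.sum() <= 1.0 + 1e-9

    def test_rank_two_matrix_has_no_third_component(self):
        rng = np.random.default_rng(1)
        ids = [f"R{i:02d}" for i in range(15)]
        u = rng.normal(size=(15, 2))
        v = rng.normal(size=(2, 40))
        w = u @ v
        w -= w.min()  # rank-2 on the log2(TPM+1) scale the PCA actually sees
        df = pd.DataFrame(2.0 ** w - 1.0, index=ids,
                          columns=[f"s{i}" for i in range(40)])
        _, var_exp, _ = joint_rbp_pca(FeatureMatrix(df, "tpm"), ids)
        assert var_exp[2] < 1e-10

    def test_too_few_rbps_rejected(self):
        tpm, ids = _tpm_matrix(n_rbp=5)
        with pytest.raises(ValueError, match="RBPs"):
            joint_rbp_pca(tpm, ids)


def _hf_samples(n_pairs=4):
    rows = []
    for k in range(n_pairs):
        for tissue in ("HF_pre", "HF_post"):
            rows.append((f"hf{k}_{tissue}", f"subj{k}", tissue))
    for i in range(6):
        rows.append((f"ipsc{i}", f"hu{i}", "iPSC-CVPC"))
    for i in range(6):
        rows.append((f"heart{i}", f"hv{i}", "adult_heart"))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue"])


class TestGroupDistances:
    def _pcs(self, samples, pre_at, post_at, spread=0.0, K=3, seed=0):
        rng = np.random.default_rng(seed)
        coords = {}
        for _, s in samples.iterrows():
            if s["tissue"] == "iPSC-CVPC":
                center = np.array([10.0, 0, 0])
            elif s["tissue"] == "adult_heart":
                center = np.array([-10.0, 0, 0])
            elif s["tissue"] == "HF_pre":
                center = pre_at
            else:
                center = post_at
            coords[s["sample_id"]] = center + rng.normal(0, spread, 3)
        return pd.DataFrame(coords, index=["PC1", "PC2", "PC3"]).T

    def test_constructed_geometry_detected(self):
        samples = _hf_samples(6)
        pcs = self._pcs(samples, np.array([10.0, 0, 0]),
                        np.array([-10.0, 0, 0]), spread=0.5)
        res = group_distances(pcs, samples, K=3)
        p_ipsc = res.paired.set_index("target").loc["iPSC-CVPC"]
        p_heart = res.paired.set_index("target").loc["adult_heart"]
        assert p_ipsc["p"] < 0.01 and p_heart["p"] < 0.01
        assert np.sign(p_ipsc["mean_pre_minus_post"]) == -1
        assert np.sign(p_heart["mean_pre_minus_post"]) == 1

    def test_identical_pre_post_coordinates(self):
        samples = _hf_samples(3)
        pcs = self._pcs(samples, np.zeros(3), np.zeros(3), spread=0.0)
        res = group_distances(pcs, samples, K=3)
        assert (res.paired["p"] == 1.0).all()
        assert (res.paired["mean_pre_minus_post"] == 0).all()

    def test_unpaired_subject_excluded(self):
        samples = _hf_samples(3)
        samples = samples[samples["sample_id"] != "hf0_HF_post"]
        pcs = self._pcs(samples, np.zeros(3), np.ones(3), spread=0.1)
        with pytest.warns(UserWarning, match="subj0"):
            res = group_distances(pcs, samples, K=3)
        assert "subj0" not in set(res.per_sample["subject_id"])

    def test_distances_invariant_under_rotation(self):
        samples = _hf_samples(4)
        pcs = self._pcs(samples, np.array([3.0, 1, 0]),
                        np.array([-2.0, 0, 1]), spread=0.3)
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = pd.DataFrame(pcs.to_numpy() @ Q, index=pcs.index,
                               columns=pcs.columns)
        a = group_distances(pcs, samples, K=3).per_sample["mean_distance"]
        b = group_distances(rotated, samples, K=3).per_sample["mean_distance"]
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_k_exceeding_pcs_rejected(self):
        samples = _hf_samples(2)
        pcs = self._pcs(samples, np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError, match="K"):
            group_distances(pcs, samples, K=10)

    def test_paired_t_matches_hand_computed_fixture(self):
        # 3 subjects with pre/post mean distances to one target group
        pre, post = np.array([5.0, 6.0, 7.5]), np.array([4.0, 5.5, 6.0])
        t_ref, p_ref = sps.ttest_rel(pre, post)
        d = pre - post
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t_ref == pytest.approx(t_hand, abs=1e-10)
        p_hand = 2 * sps.t.sf(abs(t_hand), 2)
        assert p_ref == pytest.approx(p_hand, abs=1e-10)


class TestLocationTest:
    def test_symmetric_effects_give_p_one(self):
        res = rbp_effectsize_location_test([0.5, -0.5, 1.2, -1.2])
        assert res["mean"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_identical_nonzero_effects_degenerate(self):
        res = rbp_effectsize_location_test([0.5] * 10)
        assert res["degenerate"] and res["p"] < 1e-300

    def test_shifted_effects_detected(self):
        rng = np.random.default_rng(0)
        hits = sum(rbp_effectsize_location_test(
            rng.normal(0.3, 0.5, 122))["p"] < 0.05 for _ in range(100))
        assert hits >= 95

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValueError):
            rbp_effectsize_location_test([1.0, 2.0])


class TestReversion:
    def _de(self, ids, beta, sig):
        return pd.DataFrame({"feature_id": ids, "beta": beta,
                             "p_adj": np.where(sig, 0.0, 1.0)})

    def test_identical_de_runs_give_perfect_correlation(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(200)]
        beta = rng.normal(size=200)
        sig = rng.random(200) < 0.3
        de = self._de(ids, beta, sig)
        res = reversion_statistic(de, de)
        assert res.effect_correlation == pytest.approx(1.0)
        assert res.n_same_trend == int(sig.sum())

    def test_empty_universe_rejected(self):
        a = self._de(["x"], [1.0], [True])
        b = self._de(["y"], [1.0], [True])
        with pytest.raises(ValueError):
            reversion_statistic(a, b)

    def test_null_labels_give_or_near_one(self):
        from cardiosplice.experiments import reversion_null_study
        res = reversion_null_study(seed=3, n_seeds=30)
        assert res["frac_in_band"] >= 0.9

    def test_table_margins_consistent(self):
        rng = np.random.default_rng(1)
        ids = [f"i{k}" for k in range(500)]
        a = self._de(ids, rng.normal(size=500), rng.random(500) < 0.3)
        b = self._de(ids, rng.normal(size=500), rng.random(500) < 0.4)
        res = reversion_statistic(a, b)
        A, B, C, D = res.table
        assert A + B == res.n_hf_de
        assert A + B + C + D == res.n_universe
        assert A == res.n_same_trend
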