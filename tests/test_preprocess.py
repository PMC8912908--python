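"""Filtering rules, isoform usage, rank-normalization and the read-length
blacklist."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from cardiosplice.io import FeatureMatrix
from cardiosplice import preprocess as pp


def _tpm(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return FeatureMatrix(df.astype(float), "tpm")


class TestGeneFilter:
    def test_boundary_is_inclusive_at_exactly_ten_percent(self):
        # TPM = 1 in exactly 10 of 100 samples: retained
        row = np.zeros(100)
        row[:10] = 1.0
        m = _tpm({"g": row})
        kept, rep = pp.filter_expressed_genes(m)
        assert "g" in kept.feature_ids
        assert rep.n_expressed == 1

    def test_all_zero_gene_dropped(self):
        m = _tpm({"g0": np.zeros(20), "g1": np.ones(20)})
        kept, _ = pp.filter_expressed_genes(m)
        assert kept.feature_ids == ["g1"]

    def test_ceil_of_sample_fraction(self):
        # 20 samples: need ceil(0.1*20)=2 passing samples
        two = np.zeros(20); two[:2] = 5
        one = np.zeros(20); one[:1] = 5
        kept, _ = pp.filter_expressed_genes(_tpm({"two": two, "one": one}))
        assert kept.feature_ids == ["two"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = _tpm(pd.DataFrame(rng.lognormal(size=(30, 15))))
        once, _ = pp.filter_expressed_genes(m)
        twice, _ = pp.filter_expressed_genes(once)
        assert once.feature_ids == twice.feature_ids


def _two_isoform_ann(genes):
    """Tiny annotation: {gene: [isoform ids]} with dummy exons."""
    from cardiosplice.io import ExonRecord, GeneRecord, TranscriptAnnotation
    g, t, e, tg = {}, {}, {}, {}
    pos = 0
    for gid, tids in genes.items():
        g[gid] = GeneRecord(gid, gid, "+", list(tids))
        for tid in tids:
            eid = f"{tid}_e"
            e[eid] = ExonRecord(eid, "chr1", pos, pos + 100, "+")
            t[tid] = [eid]
            tg[tid] = gid
            pos += 300
    return TranscriptAnnotation(g, t, e, tg)


class TestIsoformUsage:
    def test_partition(self):
        ann = _two_isoform_ann({"g": ["t1", "t2"]})
        iso = _tpm({"t1": [3.0], "t2": [1.0]})
        usage, silent = pp.compute_isoform_usage(iso, ann)
        assert usage.values.loc["t1"].iloc[0] == pytest.approx(0.75)
        assert usage.values.loc["t2"].iloc[0] == pytest.approx(0.25)
        assert not silent.to_numpy().any()

    def test_zero_denominator_flagged_as_zero(self):
        ann = _two_isoform_ann({"g": ["t1", "t2"]})
        usage, silent = pp.compute_isoform_usage(_tpm({"t1": [0.0], "t2": [0.0]}), ann)
        assert (usage.values.to_numpy() == 0).all()
        assert silent.to_numpy().all()

    def test_single_isoform_gene_usage_one(self):
        ann = _two_isoform_ann({"g": ["t1"]})
        usage, _ = pp.compute_isoform_usage(_tpm({"t1": [7.0]}), ann)
        assert usage.values.loc["t1"].iloc[0] == 1.0

    def test_unknown_isoform_rejected(self):
        ann = _two_isoform_ann({"g": ["t1"]})
        with pytest.raises(ValueError, match="tX"):
            pp.compute_isoform_usage(_tpm({"tX": [1.0]}), ann)


class TestIsoformFilter:
    def test_usage_exactly_at_threshold_dropped(self):
        # strict >: usage 0.10 everywhere fails
        ann = _two_isoform_ann({"g": ["t1", "t2"]})
        u = FeatureMatrix(pd.DataFrame({0: [0.10, 0.90]},
                                       index=["t1", "t2"]).astype(float), "usage")
        kept, _ = pp.filter_expressed_isoforms(u, ann)
        assert kept.feature_ids == []  # t1 fails, so gene drops below 2 isoforms

    def test_gene_with_one_passing_isoform_removed_entirely(self):
        ann = _two_isoform_ann({"g": ["t1", "t2"], "h": ["t3", "t4"]})
        df = pd.DataFrame({0: [0.05, 0.95, 0.5, 0.5]},
                          index=["t1", "t2", "t3", "t4"]).astype(float)
        kept, _ = pp.filter_expressed_isoforms(FeatureMatrix(df, "usage"), ann)
        assert kept.feature_ids == ["t3", "t4"]

    def test_balanced_isoforms_retained(self):
        ann = _two_isoform_ann({"g": ["t1", "t2"]})
        df = pd.DataFrame(np.full((2, 10), 0.5), index=["t1", "t2"]).astype(float)
        kept, rep = pp.filter_expressed_isoforms(FeatureMatrix(df, "usage"), ann)
        assert set(kept.feature_ids) == {"t1", "t2"}
        assert rep.n_expressed == 2


class TestInverseNormalTransform:
    def test_closed_form_three_samples(self):
        m = FeatureMatrix(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]},
                                       index=["f"]), "tpm")
        out, flagged = pp.inverse_normal_transform(m)
        expect = norm.ppf([1 / 6, 3 / 6, 5 / 6])
        assert np.allclose(out.values.loc["f"], expect)
        assert np.allclose(expect[0], -0.9674, atol=5e-4)
        assert len(flagged) == 0

    @given(st.lists(st.integers(min_value=-100, max_value=100), min_size=4,
                    max_size=20, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_invariance_under_monotone_transform(self, vals):
        df = pd.DataFrame([vals], index=["f"], dtype=float)
        a, _ = pp.inverse_normal_transform(FeatureMatrix(df, "normalized"))
        b, _ = pp.inverse_normal_transform(
            FeatureMatrix(np.exp(df / 50.0), "normalized"))
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_constant_feature_maps_to_zeros_with_flag(self):
        df = pd.DataFrame([[2.0] * 5], index=["f"])
        out, flagged = pp.inverse_normal_transform(FeatureMatrix(df, "tpm"))
        assert (out.values.to_numpy() == 0).all()
        assert list(flagged) == ["f"]


class TestReadLengthBlacklist:
    def test_identical_matrices_give_empty_blacklist(self):
        rng = np.random.default_rng(0)
        m = _tpm(pd.DataFrame(rng.lognormal(size=(10, 50))))
        assert pp.read_length_blacklist(m, m) == set()

    def test_constant_shift_blacklists_exactly_that_gene(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(size=(10, 50))
        full = _tpm(pd.DataFrame(base, index=[f"g{i}" for i in range(10)]))
        shifted = base.copy()
        shifted[3] += 5.0
        trimmed = _tpm(pd.DataFrame(shifted, index=full.feature_ids))
        assert pp.read_length_blacklist(full, trimmed) == {"g3"}

    def test_gene_blacklisted_through_its_isoform(self):
        ann = _two_isoform_ann({"g": ["t1", "t2"]})
        rng = np.random.default_rng(2)
        base = rng.lognormal(size=(2, 50))
        full = _tpm(pd.DataFrame(base, index=["t1", "t2"]))
        shifted = base.copy()
        shifted[1] += 5.0
        trimmed = _tpm(pd.DataFrame(shifted, index=["t1", "t2"]))
        assert pp.read_length_blacklist(full, trimmed, ann=ann) == {"g"}

    def test_mismatched_columns_rejected(self):
        a = _tpm(pd.DataFrame(np.ones((2, 3))), samples=["a", "b", "c"])
        b = _tpm(pd.DataFrame(np.ones((2, 3))), samples=["a", "b", "d"])
        with pytest.raises(ValueError):
            pp.read_length_blacklist(a, b)


def test_usage_rows_sum_to_one_where_gene_expressed(cohort):
    from cardiosplice.preprocess import compute_isoform_usage
    usage, silent = compute_isoform_usage(cohort.iso_tpm, cohort.annotation)
    gene_of = pd.Series({t: cohort.annotation.gene_of(t)
                         for t in usage.feature_ids})
    sums = usage.values.groupby(gene_of).sum()
    expressed = ~silent.groupby(gene_of).all()
    assert np.allclose(sums.to_numpy()[expressed.to_numpy()], 1.0, atol=1e-9)
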