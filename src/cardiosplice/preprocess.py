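"""Expression filtering, isoform-usage computation, rank-based normalization,
and the read-length blacklist.

Filtering conventions follow the published thresholds literally: a gene is
"expressed" with TPM >= 1 in at least 10% of samples (inclusive, ceil of the
sample fraction); an isoform is "expressed" with usage strictly > 10% in at
least 10% of samples, and a gene must keep at least two expressed isoforms
to enter isoform analyses at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FeatureMatrix, TranscriptAnnotation
from .stats import bonferroni_adjust, rank_inverse_normal


@dataclass
class FilterReport:
    n_input: int
    n_expressed: int
    criterion: str
    pass_flags: pd.Series  # indexed by feature_id, bool

    def __post_init__(self):
        assert self.n_expressed <= self.n_input
        assert int(self.pass_flags.sum()) == self.n_expressed


def filter_expressed_genes(tpm: FeatureMatrix, min_tpm: float = 1.0,
                           min_frac: float = 0.10) -> tuple[FeatureMatrix, FilterReport]:
    """Keep genes with TPM >= ``min_tpm`` in at least ceil(min_frac * n) samples."""
    if tpm.kind != "tpm":
        raise ValueError("filter_expressed_genes expects a TPM matrix")
    if tpm.values.empty:
        raise ValueError("empty matrix")
    n = tpm.values.shape[1]
    need = math.ceil(min_frac * n)
    flags = (tpm.values >= min_tpm).sum(axis=1) >= need
    kept = FeatureMatrix(tpm.values.loc[flags], "tpm")
    report = FilterReport(
        n_input=len(flags), n_expressed=int(flags.sum()),
        criterion=f"TPM >= {min_tpm} in >= {need}/{n} samples",
        pass_flags=flags,
    )
    return kept, report


def compute_isoform_usage(iso_tpm: FeatureMatrix, ann: TranscriptAnnotation
                          ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Isoform usage = isoform TPM / gene TPM sum; 0 where the gene is silent.

    Returns the usage matrix and a boolean frame flagging zero-denominator
    (gene unexpressed) entries.
    """
    missing = [f for f in iso_tpm.feature_ids if f not in ann.transcript_gene]
    if missing:
        raise ValueError(f"isoforms absent from annotation: {missing[:10]}")
    gene_of = pd.Series({f: ann.transcript_gene[f] for f in iso_tpm.feature_ids})
    gene_sum = iso_tpm.values.groupby(gene_of).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        usage = iso_tpm.values / gene_sum
    silent = gene_sum == 0
    usage = usage.where(~silent, 0.0)
    return FeatureMatrix(usage, "usage"), silent


def filter_expressed_isoforms(usage: FeatureMatrix, ann: TranscriptAnnotation,
                              min_usage: float = 0.10, min_frac: float = 0.10
                              ) -> tuple[FeatureMatrix, FilterReport]:
    """Keep isoforms with usage > ``min_usage`` (strict) in >= ceil(min_frac*n)
    samples, then drop every gene retaining fewer than two expressed isoforms."""
    if usage.kind != "usage":
        raise ValueError("filter_expressed_isoforms expects a usage matrix")
    n = usage.values.shape[1]
    need = math.ceil(min_frac * n)
    flags = (usage.values > min_usage).sum(axis=1) >= need
    gene_of = pd.Series({f: ann.transcript_gene[f] for f in usage.feature_ids})
    n_per_gene = flags.groupby(gene_of).transform("sum")
    keep = flags & (n_per_gene >= 2)
    kept = FeatureMatrix(usage.values.loc[keep], "usage")
    report = FilterReport(
        n_input=len(flags), n_expressed=int(keep.sum()),
        criterion=(f"usage > {min_usage} in >= {need}/{n} samples; "
                   "genes need >= 2 expressed isoforms"),
        pass_flags=keep,
    )
    return kept, report


def inverse_normal_transform(m: FeatureMatrix) -> tuple[FeatureMatrix, pd.Index]:
    """Per-feature rank inverse-normal transform (offset 0.5, average ties).

    Output is rank-invariant: any strictly monotone per-feature transform of
    the input yields identical output.  Constant features map to zero and are
    returned in the flagged index.
    """
    if m.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to normalize")
    out = np.empty(m.values.shape)
    flagged = []
    for i, (fid, row) in enumerate(m.values.iterrows()):
        out[i], degenerate = rank_inverse_normal(row.to_numpy())
        if degenerate:
            flagged.append(fid)
    norm = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return FeatureMatrix(norm, "normalized"), pd.Index(flagged)


def read_length_blacklist(full: FeatureMatrix, trimmed: FeatureMatrix,
                          alpha: float = 0.05,
                          ann: TranscriptAnnotation | None = None) -> set[str]:
    """Genes whose quantification shifts with read length.

    Per feature, a paired t-test across matched samples between the
    full-length and trimmed quantifications; Bonferroni-adjusted p < alpha
    blacklists the feature.  When an annotation is given, isoform features are
    mapped to their genes and a gene is blacklisted if it or ANY of its
    isoforms is significant.
    """
    if list(full.sample_ids) != list(trimmed.sample_ids):
        raise ValueError("sample columns differ between matrices")
    common = [f for f in full.feature_ids if f in set(trimmed.feature_ids)]
    a = full.values.loc[common].to_numpy()
    b = trimmed.values.loc[common].to_numpy()
    diff = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_rel(a, b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # constant nonzero shift: t-test degenerate (sd of diff = 0) but a real shift
    degenerate_shift = (diff.std(axis=1) == 0) & (np.abs(diff.mean(axis=1)) > 0)
    p[degenerate_shift] = 0.0
    p[(diff == 0).all(axis=1)] = 1.0
    p_adj = bonferroni_adjust(p)
    hits = {common[i] for i in np.flatnonzero(p_adj < alpha)}
    if ann is None:
        return hits
    genes = set()
    for f in hits:
        genes.add(ann.transcript_gene.get(f, f))
    return genes
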