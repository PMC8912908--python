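"""Heart-failure stage: joint PCA on the RNA-binding-protein panel,
PC-space distances with paired tests, the RBP effect-size location test,
and the fetal-reversion isoform statistic.

The failing heart is compared geometrically (are pre-LVAD samples closer to
the fetal-like group than post-LVAD samples?) and combinatorially (are
isoforms differentially used in heart failure enriched for the fetal-adult
switch set, with matching direction?).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FeatureMatrix
from .stats import fisher_2x2


def joint_rbp_pca(tpm: FeatureMatrix, rbp_genes: list[str],
                  n_components: int = 10):
    """PCA of all samples on z-scored log2(TPM+1) of the RBP panel.

    RBPs absent from the matrix or constant across samples are dropped with
    a warning.  Component signs are fixed so the largest-|loading| RBP of
    each component has a positive loading; scores are then deterministic.
    Returns (scores DataFrame samples x PCs, variance_explained fractions,
    loadings DataFrame).
    """
    present = [g for g in rbp_genes if g in set(tpm.feature_ids)]
    if len(present) < 10:
        raise ValueError(f"only {len(present)} RBPs present; need >= 10")
    X = np.log2(tpm.values.loc[present].to_numpy() + 1.0)   # rbp x sample
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant RBPs: {[p for p, k in zip(present, keep) if not k]}")
        X, present = X[keep], [p for p, k in zip(present, keep) if k]
        sd = sd[keep]
    Z = ((X - X.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x rbp
    n = Z.shape[0]
    U, d, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    k = min(n_components, len(d))
    # sign convention: largest-|loading| RBP positive per component
    for j in range(len(d)):
        i = np.abs(Vt[j]).argmax()
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * d[:k]
    var_exp = d ** 2 / (d ** 2).sum()
    pcs = pd.DataFrame(scores, index=tpm.sample_ids,
                       columns=[f"PC{j + 1}" for j in range(k)])
    loadings = pd.DataFrame(Vt[:k].T, index=present, columns=pcs.columns)
    return pcs, var_exp[:k], loadings


@dataclass
class DistanceSummary:
    per_sample: pd.DataFrame       # hf sample x target tissue mean distance
    paired: pd.DataFrame           # per target: mean pre-post difference, t, p


def group_distances(pcs: pd.DataFrame, samples: pd.DataFrame,
                    targets=("iPSC-CVPC", "adult_heart", "adult_arteria"),
                    K: int = 10) -> DistanceSummary:
    """Mean Euclidean distance of each heart-failure sample to every sample
    of each healthy group in top-``K`` PC space, with a paired t-test of the
    pre-vs-post difference per target group."""
    if K > pcs.shape[1]:
        raise ValueError(f"K={K} exceeds available PCs ({pcs.shape[1]})")
    coords = pcs.iloc[:, :K]
    hf = samples[samples["tissue"].isin(["HF_pre", "HF_post"])]
    counts = hf.groupby("subject_id")["tissue"].nunique()
    complete = set(counts[counts == 2].index)
    dropped = set(hf["subject_id"]) - complete
    if dropped:
        warnings.warn(f"unpaired heart-failure subjects excluded: {sorted(dropped)}")
    hf = hf[hf["subject_id"].isin(complete)]
    rows = []
    for _, s in hf.iterrows():
        x = coords.loc[s["sample_id"]].to_numpy()
        for target in targets:
            ids = samples.loc[samples["tissue"] == target, "sample_id"]
            if not len(ids):
                continue
            d = np.sqrt(((coords.loc[list(ids)].to_numpy() - x) ** 2).sum(axis=1))
            rows.append((s["sample_id"], s["subject_id"], s["tissue"], target,
                         float(d.mean())))
    per = pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue",
                                      "target", "mean_distance"])
    paired_rows = []
    for target in targets:
        sub = per[per["target"] == target].pivot(index="subject_id",
                                                 columns="tissue",
                                                 values="mean_distance")
        if not {"HF_pre", "HF_post"} <= set(sub.columns):
            continue
        diff = (sub["HF_pre"] - sub["HF_post"]).to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(sub["HF_pre"], sub["HF_post"])
        paired_rows.append((target, float(diff.mean()), float(t), float(p)))
    paired = pd.DataFrame(paired_rows, columns=["target", "mean_pre_minus_post",
                                                "t", "p"])
    return DistanceSummary(per, paired)


def rbp_effectsize_location_test(effects: np.ndarray | pd.Series) -> dict:
    """One-sample two-sided t-test of per-RBP effect sizes against zero."""
    x = np.asarray(effects, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 RBP effects")
    if x.std(ddof=1) == 0:
        # all effects identical: the location is exactly the common value
        p = 1.0 if x[0] == 0 else np.finfo(float).tiny
        return {"mean": float(x.mean()), "t": np.inf * np.sign(x[0]),
                "p": p, "degenerate": True}
    t, p = sps.ttest_1samp(x, 0.0)
    return {"mean": float(x.mean()), "t": float(t), "p": float(p),
            "degenerate": False}


@dataclass
class ReversionResult:
    n_universe: int
    n_hf_de: int
    n_same_trend: int
    table: tuple
    odds_ratio: float
    p: float
    effect_correlation: float


def reversion_statistic(de_hf: pd.DataFrame, de_ipsc: pd.DataFrame,
                        alpha: float = 0.05) -> ReversionResult:
    """Enrichment of the fetal switch program among heart-failure DE isoforms.

    Both inputs are isoform-level DE frames (feature_id, beta, p_adj) from
    the same contrast target (vs healthy adult heart); the isoform universe
    is their intersection.  The 2x2 classifies every isoform by (HF-DE at
    FDR < alpha) x (iPSC-DE at FDR < alpha AND sign-matched to the HF
    effect); sign agreement uses the estimated HF effect whether or not
    significant, so the table is a genuine independence test (odds ratio 1
    under a null with no shared program).  Also reports the Pearson
    correlation of the two effect-size vectors over the universe.
    """
    a_idx = de_hf.set_index("feature_id")
    b_idx = de_ipsc.set_index("feature_id")
    universe = a_idx.index.intersection(b_idx.index)
    if not len(universe):
        raise ValueError("empty isoform universe")
    a_idx, b_idx = a_idx.loc[universe], b_idx.loc[universe]
    hf_de = a_idx["p_adj"].to_numpy() < alpha
    ipsc_de = b_idx["p_adj"].to_numpy() < alpha
    same_sign = np.sign(a_idx["beta"].to_numpy()) == np.sign(b_idx["beta"].to_numpy())
    fetal_col = ipsc_de & same_sign
    A = int((hf_de & fetal_col).sum())
    B = int((hf_de & ~fetal_col).sum())
    C = int((~hf_de & fetal_col).sum())
    D = int((~hf_de & ~fetal_col).sum())
    or_, p = fisher_2x2((A, B, C, D))
    r = float(np.corrcoef(a_idx["beta"], b_idx["beta"])[0, 1])
    return ReversionResult(len(universe), int(hf_de.sum()), A, (A, B, C, D),
                           or_, p, r)
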