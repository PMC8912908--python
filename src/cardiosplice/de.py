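"""Covariate-adjusted differential expression and usage.

Pairwise tissue contrasts use OLS on rank-normalized values with four
technical covariates (sex, z-scored library size, fraction of autosomal
reads, fraction of mitochondrial reads).  Contrasts that must coexist with
cell-type proportions -- which sum to one and are therefore collinear with
the intercept -- use ridge regression with a generalized-cross-validation
penalty instead.  Specificity calls combine a Bonferroni-significant
coefficient with a > 4-fold ratio of group means on the original scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from scipy import stats as sps

from .io import FeatureMatrix, GeneSet
from .stats import (bh_adjust, bonferroni_adjust, fisher_2x2, ols_per_feature)

COVARIATES = ("sex", "total_reads", "pct_autosomal", "pct_mito")

#: pseudocounts for log2 ratios of group means on the original scale
PSEUDOCOUNT_TPM = 1.0
PSEUDOCOUNT_USAGE = 0.01


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def design_matrix(samples: pd.DataFrame, group: np.ndarray | None,
                  extra: pd.DataFrame | None = None) -> tuple[np.ndarray, list[str]]:
    """Design: intercept, optional group indicator, technical covariates,
    optional extra regressors (e.g. cell-type proportions)."""
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    if group is not None:
        cols.append(np.asarray(group, dtype=float))
        names.append("group")
    cols.append((samples["sex"] == "M").to_numpy(dtype=float))
    cols.append(_zscore(samples["total_reads"].to_numpy(dtype=float)))
    cols.append(samples["pct_autosomal"].to_numpy(dtype=float))
    cols.append(samples["pct_mito"].to_numpy(dtype=float))
    names += ["sex", "total_reads", "pct_autosomal", "pct_mito"]
    if extra is not None:
        for c in extra.columns:
            cols.append(extra[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def fit_linear_de(norm: FeatureMatrix, samples: pd.DataFrame,
                  tissue1: str, tissue2: str) -> pd.DataFrame:
    """Per-feature OLS contrast of ``tissue1`` minus ``tissue2``.

    Returns a frame with columns feature_id, comparison, beta, se, p, p_adj
    (Bonferroni over tested features), sorted by feature_id.
    """
    sel = samples[samples["tissue"].isin([tissue1, tissue2])]
    Y = norm.values[sel["sample_id"]].to_numpy()
    group = (sel["tissue"] == tissue1).to_numpy(dtype=float)
    X, names = design_matrix(sel, group)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError(f"too few samples (n={X.shape[0]}) for {X.shape[1]} columns")
    beta, se, p = ols_per_feature(Y, X, names.index("group"))
    out = pd.DataFrame({
        "feature_id": norm.feature_ids,
        "comparison": f"{tissue1}_vs_{tissue2}",
        "beta": beta, "se": se, "p": p,
    }).sort_values("feature_id", kind="stable").reset_index(drop=True)
    out["p_adj"] = bonferroni_adjust(out["p"].to_numpy())
    return out


def classify_specific(de: pd.DataFrame, original: FeatureMatrix,
                      samples: pd.DataFrame, tissue1: str, tissue2: str,
                      lr_thresh: float = 2.0, alpha: float = 0.05,
                      pseudocount: float | None = None) -> pd.DataFrame:
    """Attach group means, log2 ratio and the specificity class.

    Means are computed on the ORIGINAL scale (TPM or usage), never the
    normalized scale.  ``tissue1_specific`` requires p_adj < alpha AND
    log2 ratio strictly > lr_thresh; symmetric for tissue2.
    """
    if pseudocount is None:
        pseudocount = PSEUDOCOUNT_TPM if original.kind == "tpm" else PSEUDOCOUNT_USAGE
    s1 = samples.loc[samples["tissue"] == tissue1, "sample_id"]
    s2 = samples.loc[samples["tissue"] == tissue2, "sample_id"]
    m = original.values.loc[de["feature_id"]]
    mean1 = m[list(s1)].mean(axis=1).to_numpy()
    mean2 = m[list(s2)].mean(axis=1).to_numpy()
    lr = np.log2((mean1 + pseudocount) / (mean2 + pseudocount))
    out = de.copy()
    out["mean1"], out["mean2"], out["log2_ratio"] = mean1, mean2, lr
    sig = out["p_adj"].to_numpy() < alpha
    cls = np.where(~sig, "not_DE",
          np.where(lr > lr_thresh, "tissue1_specific",
          np.where(lr < -lr_thresh, "tissue2_specific", "DE_only")))
    out["cls"] = cls
    return out


# ---------------------------------------------------------------------------
# ridge regression with GCV
# ---------------------------------------------------------------------------

LAMBDA_GRID = np.logspace(-4, 4, 25)


def fit_ridge_de(norm: FeatureMatrix, samples: pd.DataFrame,
                 group: np.ndarray | None,
                 proportions: pd.DataFrame | None = None,
                 lam: float | str = "auto",
                 coef_names: list[str] | None = None) -> pd.DataFrame:
    """Ridge contrast with collinear regressors (e.g. cell-type proportions).

    Predictors (all but the intercept) are standardized and Y centered, so
    the intercept drops out of the penalized solve; effects are reported on
    the standardized-predictor scale.  The penalty is chosen per feature by
    generalized cross-validation on a 25-point log grid 1e-4..1e4 (``lam``
    may also be a fixed number; 0 gives the OLS limit).  Standard errors use
    the linear-smoother sandwich sigma^2 (X'X+lI)^-1 X'X (X'X+lI)^-1 with
    sigma^2 = RSS / (n - tr(H) - 1), and p-values are two-sided normal.
    Returns a long frame: one row per (feature, coefficient of interest) with
    Bonferroni adjustment per coefficient family.
    """
    sel = samples
    if norm.values.shape[1] != len(sel):
        raise ValueError("matrix columns must match the sample table")
    if len(sel) < 10:
        raise ValueError("need at least 10 samples for ridge DE")
    extra = proportions.loc[sel["sample_id"]].reset_index(drop=True) if proportions is not None else None
    X_raw, names = design_matrix(sel.reset_index(drop=True), group, extra)
    X = X_raw[:, 1:]  # drop intercept; standardize the rest
    names = names[1:]
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant predictors: {[n for n, k in zip(names, keep) if not k]}")
        X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
        sd = sd[keep]
    Xs = (X - X.mean(axis=0)) / sd
    Y = norm.values[sel["sample_id"]].to_numpy()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    n, p = Xs.shape
    U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
    Z = U.T @ Yc.T                      # p x F
    ynorm2 = (Yc ** 2).sum(axis=1)      # F

    if lam == "auto":
        grid = LAMBDA_GRID
        gcv = np.empty((len(grid), Yc.shape[0]))
        for gi, lv in enumerate(grid):
            shrink = d ** 2 / (d ** 2 + lv)
            rss = ynorm2 - 2 * (shrink[:, None] * Z ** 2).sum(0) \
                  + ((shrink ** 2)[:, None] * Z ** 2).sum(0)
            edf = shrink.sum() + 1.0
            gcv[gi] = (rss / n) / (1.0 - edf / n) ** 2
        choice = gcv.argmin(axis=0)
        if (choice == 0).any() or (choice == len(grid) - 1).any():
            warnings.warn("GCV chose a boundary lambda for some features")
        lam_per_feature = grid[choice]
    else:
        lam_per_feature = np.full(Yc.shape[0], float(lam))

    F = Yc.shape[0]
    beta = np.empty((F, p))
    se = np.empty((F, p))
    V = Vt.T
    for lv in np.unique(lam_per_feature):
        idx = np.flatnonzero(lam_per_feature == lv)
        filt = d / (d ** 2 + lv)
        beta[idx] = ((V * filt) @ Z[:, idx]).T
        shrink = d ** 2 / (d ** 2 + lv)
        rss = ynorm2[idx] - 2 * (shrink[:, None] * Z[:, idx] ** 2).sum(0) \
              + ((shrink ** 2)[:, None] * Z[:, idx] ** 2).sum(0)
        dof = n - shrink.sum() - 1.0
        sigma2 = np.maximum(rss, 0.0) / max(dof, 1.0)
        var_unit = ((V ** 2) * (d ** 2 / (d ** 2 + lv) ** 2)).sum(axis=1)  # p
        se[idx] = np.sqrt(sigma2[:, None] * var_unit[None, :])

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.norm.sf(np.abs(z))

    if coef_names is None:
        coef_names = [nm for nm in names if nm == "group" or
                      (proportions is not None and nm in proportions.columns)]
    rows = []
    feats = np.array(norm.feature_ids)
    order = np.argsort(feats, kind="stable")
    for nm in coef_names:
        j = names.index(nm)
        padj = bonferroni_adjust(pvals[:, j])
        for i in order:
            rows.append((feats[i], nm, beta[i, j], se[i, j], pvals[i, j],
                         padj[i], lam_per_feature[i]))
    return pd.DataFrame(rows, columns=["feature_id", "coefficient", "beta",
                                       "se", "p", "p_adj", "lambda"])


# ---------------------------------------------------------------------------
# gene-set procedures
# ---------------------------------------------------------------------------

def gsea_effectsize_ttest(effects: pd.Series, sets: list[GeneSet]) -> pd.DataFrame:
    """Per gene set, Welch t-test of in-set vs out-of-set effect sizes; BH."""
    universe = set(effects.index)
    rows = []
    for gs in sets:
        members = gs.members & universe
        if len(members) < 2 or len(universe) - len(members) < 2:
            warnings.warn(f"gene set {gs.name!r} skipped (degenerate split)")
            continue
        inside = effects.loc[list(members)].to_numpy()
        outside = effects.loc[list(universe - members)].to_numpy()
        t, p = sps.ttest_ind(inside, outside, equal_var=False)
        rows.append((gs.name, gs.collection, float(t), float(p), len(members)))
    out = pd.DataFrame(rows, columns=["name", "collection", "statistic", "p", "n_in_set"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def fisher_isoformDE_geneset(genes_specific: set[str], genes_no_de: set[str],
                             sets: list[GeneSet]) -> pd.DataFrame:
    """Fisher 2x2 per gene set: (has specific isoform vs no DE isoform) x
    (in set vs not); genes with DE-but-not-specific isoforms are excluded
    upstream.  BH over sets; OR is the conditional MLE."""
    if not genes_specific or not genes_no_de:
        raise ValueError("both gene groups must be nonempty")
    if genes_specific & genes_no_de:
        raise ValueError("gene groups must be disjoint")
    rows = []
    for gs in sets:
        a = len(genes_specific & gs.members)
        c = len(genes_no_de & gs.members)
        if a + c == 0:
            warnings.warn(f"gene set {gs.name!r} disjoint from both groups; skipped")
            continue
        b = len(genes_specific) - a
        d = len(genes_no_de) - c
        or_, p = fisher_2x2((a, b, c, d))
        rows.append((gs.name, gs.collection, or_, p, a + c))
    out = pd.DataFrame(rows, columns=["name", "collection", "statistic", "p", "n_in_set"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
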