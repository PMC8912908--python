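"""Cell-type deconvolution of bulk RNA-seq: marker finding from labeled
single-cell counts, signature-matrix construction, mixture estimation via
nu-SVR (with an NNLS fallback), and proportion-expression association.

The support-vector route follows the published CIBERSORT core: jointly
z-scored signature and mixture, linear-kernel nu-SVR over nu in
{0.25, 0.5, 0.75} picking the lowest-RMSE fit, negative coefficients
truncated to zero, and renormalization to the simplex.  No quantile
mapping is applied anywhere.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from .io import FeatureMatrix
from .stats import bonferroni_adjust, ols_per_feature


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Depth-scale each cell to ``scale`` counts, then log1p."""
    depth = counts.sum(axis=1)
    return np.log1p(counts.div(depth, axis=0) * scale)


def find_markers(sc_counts: pd.DataFrame, labels: pd.Series,
                 min_pct: float = 0.2, min_log2fc: float = 0.1,
                 alpha: float = 0.1) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per cell type.

    Keeps genes with a positive shift, detected in >= ``min_pct`` of in-type
    cells, log2 fold change >= ``min_log2fc`` (ratio of expm1-means + 1),
    and Bonferroni-adjusted p < ``alpha``.  Types with < 2 cells are
    excluded with a warning.
    """
    logn = log_normalize(sc_counts)
    rows = []
    for ct in sorted(labels.unique()):
        mask = (labels == ct).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"cell type {ct!r} has < 2 cells; excluded")
            continue
        inside = logn.loc[mask]
        outside = logn.loc[~mask]
        pct_in = (sc_counts.loc[mask] > 0).mean(axis=0)
        pct_out = (sc_counts.loc[~mask] > 0).mean(axis=0)
        mean_in = np.expm1(inside).mean(axis=0) + 1.0
        mean_out = np.expm1(outside).mean(axis=0) + 1.0
        lfc = np.log2(mean_in / mean_out)
        candidates = logn.columns[(lfc >= min_log2fc) & (pct_in >= min_pct)]
        if not len(candidates):
            continue
        stat = sps.mannwhitneyu(inside[candidates], outside[candidates],
                                alternative="greater", axis=0)
        p = np.asarray(stat.pvalue, dtype=float)
        p_adj = np.minimum(p * logn.shape[1], 1.0)   # Bonferroni over all genes
        for g, pv, pa in zip(candidates, p, p_adj):
            rows.append((g, ct, float(pct_in[g]), float(pct_out[g]),
                         float(lfc[g]), pv, pa))
    out = pd.DataFrame(rows, columns=["gene_id", "cell_type", "pct_in",
                                      "pct_out", "log2fc", "p", "p_adj"])
    return out[out["p_adj"] < alpha].reset_index(drop=True)


def build_signature(sc_counts: pd.DataFrame, labels: pd.Series,
                    markers: pd.DataFrame) -> pd.DataFrame:
    """Marker-gene x cell-type mean of depth-normalized (un-logged) expression."""
    if not len(markers):
        raise ValueError("marker table is empty")
    genes = sorted(set(markers["gene_id"]))
    missing = [g for g in genes if g not in sc_counts.columns]
    if missing:
        raise ValueError(f"markers absent from counts: {missing[:10]}")
    norm = sc_counts.div(sc_counts.sum(axis=1), axis=0) * 1e4
    sig = norm[genes].groupby(labels).mean().T
    sig.index.name = "gene_id"
    return sig


def _solve_nusvr(sig_z: np.ndarray, y_z: np.ndarray, nus=(0.25, 0.5, 0.75)):
    from sklearn.svm import NuSVR
    best = None
    for nu in nus:
        model = NuSVR(nu=nu, kernel="linear", C=1.0)
        model.fit(sig_z, y_z)
        coef = model.coef_.ravel()
        rmse = float(np.sqrt(((sig_z @ coef + model.intercept_ - y_z) ** 2).mean()))
        if best is None or rmse < best[1]:
            best = (coef, rmse, nu)
    return best


def estimate_proportions(bulk: FeatureMatrix, signature: pd.DataFrame,
                         method: str = "nusvr") -> pd.DataFrame:
    """Per-sample cell-type fractions from bulk expression restricted to
    signature genes.

    For each sample the signature matrix and the mixture vector are z-scored
    (signature by its overall mean/sd, the mixture by its own), a
    linear-model fit (nu-SVR or NNLS) produces raw coefficients, negatives
    are truncated to zero and the rest renormalized to sum to one.
    Returns a DataFrame (samples x cell types) with rmse/nu diagnostics in
    ``.attrs["diagnostics"]``.
    """
    if signature.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    genes = [g for g in signature.index if g in set(bulk.feature_ids)]
    if not genes:
        raise ValueError("no signature genes present in bulk matrix")
    sig = signature.loc[genes]
    sig_z = ((sig - sig.to_numpy().mean()) / sig.to_numpy().std()).to_numpy()
    rows, diags = [], []
    for sid in bulk.sample_ids:
        y = bulk.values.loc[genes, sid].to_numpy(dtype=float)
        if not np.any(y):
            raise ValueError(f"all-zero mixture column {sid!r}")
        y_z = (y - y.mean()) / y.std()
        if method == "nusvr":
            coef, rmse, nu = _solve_nusvr(sig_z, y_z)
            diags.append((sid, rmse, nu))
        elif method == "nnls":
            # signed intercept via a +1/-1 column pair; proportions stay >= 0
            ones = np.ones(len(y_z))
            A = np.column_stack([sig_z, ones, -ones])
            coef, rnorm = nnls(A, y_z)
            coef = coef[:-2]
            diags.append((sid, float(rnorm), np.nan))
        else:
            raise ValueError(f"unknown method {method!r}")
        coef = np.maximum(coef, 0.0)
        total = coef.sum()
        if total == 0:
            coef = np.full_like(coef, 1.0 / len(coef))
        else:
            coef = coef / total
        rows.append(coef)
    props = pd.DataFrame(rows, index=bulk.sample_ids, columns=signature.columns)
    props.attrs["diagnostics"] = pd.DataFrame(
        diags, columns=["sample_id", "rmse", "nu"])
    return props


def proportion_association(norm: FeatureMatrix, samples: pd.DataFrame,
                           proportions: pd.DataFrame) -> pd.DataFrame:
    """Per feature and cell type, OLS of normalized expression on one
    proportion regressor plus the technical covariates; Bonferroni per
    cell-type family.  Constant proportion columns are skipped."""
    from .de import design_matrix
    sel = samples.reset_index(drop=True)
    Y = norm.values[sel["sample_id"]].to_numpy()
    out = []
    for ct in proportions.columns:
        prop = proportions.loc[sel["sample_id"], ct].to_numpy()
        if np.ptp(prop) == 0:
            warnings.warn(f"constant proportion column {ct!r}; skipped")
            continue
        X, names = design_matrix(sel, prop)
        beta, se, p = ols_per_feature(Y, X, names.index("group"))
        df = pd.DataFrame({"feature_id": norm.feature_ids, "cell_type": ct,
                           "beta": beta, "se": se, "p": p})
        df = df.sort_values("feature_id", kind="stable").reset_index(drop=True)
        df["p_adj"] = bonferroni_adjust(df["p"].to_numpy())
        out.append(df)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()
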