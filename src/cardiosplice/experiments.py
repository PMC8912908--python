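"""Validation studies on synthetic ground truth.

Each function runs one self-contained experiment -- a calibration, a
recovery, or an oracle-equivalence check -- using the package's own
machinery on generated cohorts, and returns plain numbers.  The analysis
drivers, the test suite and the reproduction script all call these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import classify_specific, fit_linear_de, fit_ridge_de, gsea_effectsize_ttest
from .deconvolve import (build_signature, estimate_proportions, find_markers)
from .eclip import threshold_sweep
from .heart_failure import reversion_statistic
from .io import ExonRecord, FeatureMatrix, GeneRecord, GeneSet, PeakSet, \
    TranscriptAnnotation, samples_to_frame
from .preprocess import filter_expressed_genes, filter_expressed_isoforms, \
    compute_isoform_usage, inverse_normal_transform
from .simulate import SimConfig, make_splice_profiles, simulate_cohort, \
    simulate_splice_sets
from .splicing import positional_tests, splice_profiles
from .stats import fisher_2x2


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------------------
# OLS oracle equivalence
# ---------------------------------------------------------------------------

def ols_oracle_study(seed: int = 0, n_designs: int = 100,
                     n_features: int = 50, n_samples: int = 60) -> dict:
    """Compare fit_linear_de against a direct per-feature normal-equations
    solve (independent loop: lstsq + explicit covariance + t survival
    function) on random designs.  Returns max absolute discrepancies."""
    rng = np.random.default_rng(seed)
    worst = {"beta": 0.0, "se": 0.0, "p": 0.0}
    for _ in range(n_designs):
        n1 = n_samples // 2
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "subject_id": [f"u{i}" for i in range(n_samples)],
            "tissue": ["iPSC-CVPC"] * n1 + ["adult_heart"] * (n_samples - n1),
            "sex": rng.choice(["F", "M"], n_samples),
            "total_reads": rng.integers(10**7, 10**8, n_samples),
            "pct_autosomal": rng.uniform(0.7, 0.9, n_samples),
            "pct_mito": rng.uniform(0.02, 0.2, n_samples),
        })
        Y = rng.normal(size=(n_features, n_samples)) \
            + rng.normal(size=(n_features, 1)) * (samples["tissue"] == "iPSC-CVPC").to_numpy()
        norm = FeatureMatrix(pd.DataFrame(Y, index=[f"f{i:03d}" for i in range(n_features)],
                                          columns=samples["sample_id"]), "normalized")
        de = fit_linear_de(norm, samples, "iPSC-CVPC", "adult_heart")
        de = de.set_index("feature_id").loc[norm.feature_ids]
        # independent oracle: explicit design, per-feature lstsq
        sex = (samples["sex"] == "M").to_numpy(float)
        tr = samples["total_reads"].to_numpy(float)
        tr = (tr - tr.mean()) / tr.std()
        X = np.column_stack([np.ones(n_samples),
                             (samples["tissue"] == "iPSC-CVPC").to_numpy(float),
                             sex, tr, samples["pct_autosomal"], samples["pct_mito"]])
        dof = n_samples - X.shape[1]
        xtx_inv = np.linalg.inv(X.T @ X)
        for j in range(n_features):
            b = np.linalg.lstsq(X, Y[j], rcond=None)[0]
            resid = Y[j] - X @ b
            s2 = resid @ resid / dof
            se = np.sqrt(s2 * xtx_inv[1, 1])
            p = 2 * sps.t.sf(abs(b[1] / se), dof)
            worst["beta"] = max(worst["beta"], abs(b[1] - de["beta"].iloc[j]))
            worst["se"] = max(worst["se"], abs(se - de["se"].iloc[j]))
            worst["p"] = max(worst["p"], abs(p - de["p"].iloc[j]))
    worst["max"] = max(worst.values())
    worst["n"] = n_designs
    return worst


# ---------------------------------------------------------------------------
# type-I error calibration
# ---------------------------------------------------------------------------

def _null_config(seed: int, **kw) -> SimConfig:
    return SimConfig(seed=seed, n_stage_de=0, equal_composition=True, **kw)


def null_calibration_study(seed: int = 0, n_seeds: int = 100,
                           alpha: float = 0.05) -> dict:
    """Null cohorts (no tissue effect, shared composition): fraction of raw
    p < alpha, and the number of seeds with zero Bonferroni-significant
    genes."""
    fracs, clean = [], 0
    for s in _child_seeds(seed, n_seeds):
        cohort = simulate_cohort(_null_config(s))
        samples = cohort.samples_frame()
        sub = samples[samples["tissue"].isin(["iPSC-CVPC", "adult_heart"])]
        genes, _ = filter_expressed_genes(cohort.gene_tpm)
        norm, _ = inverse_normal_transform(genes.subset_samples(sub["sample_id"]))
        de = fit_linear_de(norm, sub, "iPSC-CVPC", "adult_heart")
        fracs.append(float((de["p"] < alpha).mean()))
        clean += int((de["p_adj"] < alpha).sum() == 0)
    return {"frac_p_lt_alpha": float(np.mean(fracs)),
            "frac_first_seed": fracs[0],
            "n_clean_seeds": clean, "n_seeds": n_seeds,
            "n_features": 2000}


def de_recovery_study(seed: int = 0, alpha: float = 0.05) -> dict:
    """Recovery of 300 planted stage-specific genes (|log2FC| in [2.5, 4],
    40 vs 40 samples, sigma = 0.25) under shared cell composition."""
    cohort = simulate_cohort(SimConfig(seed=seed, equal_composition=True))
    samples = cohort.samples_frame()
    sub = samples[samples["tissue"].isin(["iPSC-CVPC", "adult_heart"])]
    genes, _ = filter_expressed_genes(cohort.gene_tpm)
    norm, _ = inverse_normal_transform(genes.subset_samples(sub["sample_id"]))
    de = fit_linear_de(norm, sub, "iPSC-CVPC", "adult_heart")
    de = classify_specific(de, genes, sub, "iPSC-CVPC", "adult_heart",
                           alpha=alpha).set_index("feature_id")
    planted = cohort.truth.stage_de.index.intersection(de.index)
    specific = de["cls"].isin(["tissue1_specific", "tissue2_specific"])
    sens = float(specific.loc[planted].mean())
    nulls = de.index.difference(planted)
    false_calls = int(specific.loc[nulls].sum())
    return {"sensitivity": sens, "n_planted": int(len(planted)),
            "false_specific": false_calls, "n_null": int(len(nulls))}


# ---------------------------------------------------------------------------
# ridge limit
# ---------------------------------------------------------------------------

def ridge_limit_study(seed: int = 0, n_features: int = 200) -> dict:
    """lambda = 0 must reproduce OLS (on the same standardized design) to
    numerical precision, and the default GCV run must stay finite despite
    proportions summing to one."""
    cohort = simulate_cohort(SimConfig(seed=seed))
    samples = cohort.samples_frame()
    sub = samples[samples["tissue"].isin(["iPSC-CVPC", "adult_heart"])].reset_index(drop=True)
    genes, _ = filter_expressed_genes(cohort.gene_tpm)
    feats = genes.feature_ids[:n_features]
    norm, _ = inverse_normal_transform(
        genes.subset_features(feats).subset_samples(sub["sample_id"]))
    group = (sub["tissue"] == "iPSC-CVPC").to_numpy(float)
    props = cohort.truth.proportions.loc[sub["sample_id"]]

    # collinear case, GCV-chosen penalty: must be finite everywhere
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ridge_auto = fit_ridge_de(norm, sub, group, proportions=props)
    finite = bool(np.isfinite(ridge_auto[["beta", "se"]].to_numpy()).all())

    # full-rank case (no proportions): lambda -> 0 equals OLS
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ridge0 = fit_ridge_de(norm, sub, group, lam=0.0, coef_names=["group"])
    from .de import design_matrix
    X_raw, names = design_matrix(sub, group)
    X = X_raw[:, 1:]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    Xd = np.column_stack([np.ones(len(sub)), Xs])
    dof = Xd.shape[0] - Xd.shape[1]
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    worst = 0.0
    r0 = ridge0.set_index("feature_id")
    for i, f in enumerate(norm.feature_ids):
        y = norm.values.loc[f].to_numpy()
        b = np.linalg.lstsq(Xd, y, rcond=None)[0]
        resid = y - Xd @ b
        se = np.sqrt(resid @ resid / dof * xtx_inv[1, 1])
        worst = max(worst, abs(b[1] - r0.loc[f, "beta"]),
                    abs(se - r0.loc[f, "se"]))
    return {"lambda0_max_abs_diff": float(worst), "gcv_finite": finite,
            "n_features": n_features}


# ---------------------------------------------------------------------------
# exact-test oracle
# ---------------------------------------------------------------------------

def conditional_mle_enumeration(table) -> tuple[float, float]:
    """Brute-force reference for the 2x2 exact test: conditional-MLE odds
    ratio by maximizing the noncentral hypergeometric likelihood (solved on
    the conditional mean equation), and the two-sided Fisher p by direct
    enumeration of tables with fixed margins."""
    a, b, c, d = np.asarray(table, int).ravel()
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    from scipy.special import gammaln

    def logw(u):
        return (gammaln(r1 + 1) - gammaln(u + 1) - gammaln(r1 - u + 1)
                + gammaln(r2 + 1) - gammaln(c1 - u + 1) - gammaln(r2 - c1 + u + 1))

    lw = logw(support)
    # two-sided p at psi = 1 (probabilities <= P(a), with tolerance)
    pr = np.exp(lw - lw.max())
    pr = pr / pr.sum()
    pa = pr[support == a][0]
    p = float(pr[pr <= pa * (1 + 1e-9)].sum())
    if a == lo:
        return 0.0, p
    if a == hi:
        return float("inf"), p

    def mean_minus_a(logpsi):
        w = lw + support * logpsi
        w = np.exp(w - w.max())
        return float((support * w).sum() / w.sum() - a)

    from scipy.optimize import brentq
    logpsi = brentq(mean_minus_a, -50.0, 50.0, xtol=1e-12)
    return float(np.exp(logpsi)), p


def enumerate_small_tables(max_total: int = 12):
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield (a, b, c, n - a - b - c)


def fisher_oracle_study(max_total: int = 12) -> dict:
    """Agreement of the implementation's conditional-MLE OR and exact p with
    the enumeration oracle over every 2x2 table with total <= max_total."""
    worst_or, worst_p, n = 0.0, 0.0, 0
    for tab in enumerate_small_tables(max_total):
        a, b, c, d = tab
        if min(a + b, c + d, a + c, b + d) == 0:
            continue  # degenerate margins: OR undefined by convention
        or_impl, p_impl = fisher_2x2(tab)
        or_ref, p_ref = conditional_mle_enumeration(tab)
        n += 1
        worst_p = max(worst_p, abs(p_impl - p_ref))
        if np.isinf(or_ref) or np.isinf(or_impl):
            if not (np.isinf(or_ref) and np.isinf(or_impl)):
                worst_or = float("inf")
        elif or_ref == 0 or or_impl == 0:
            if not (or_ref == 0 and or_impl == 0):
                worst_or = float("inf")
        else:
            worst_or = max(worst_or, abs(or_impl - or_ref) / max(or_ref, 1.0))
    return {"max_or_rel_diff": worst_or, "max_p_abs_diff": worst_p,
            "n_tables": n}


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

def deconvolution_study(seed: int = 0) -> dict:
    """(1) Noiseless mixtures of true signature columns must be recovered
    almost exactly by both solvers; (2) on the default noisy cohort the full
    marker -> signature -> estimation path must correlate with the true
    proportions per cell type."""
    cohort = simulate_cohort(SimConfig(seed=seed))
    truth = cohort.truth
    rng = np.random.default_rng(seed + 1)
    sig = truth.signatures
    k = sig.shape[1]
    W = rng.dirichlet(np.ones(k) * 2.0, size=12)        # 12 noiseless mixtures
    bulk = FeatureMatrix(pd.DataFrame(
        sig.to_numpy() @ W.T, index=sig.index,
        columns=[f"mix{i}" for i in range(len(W))]), "tpm")
    worst = {}
    for method in ("nnls", "nusvr"):
        est = estimate_proportions(bulk, sig, method=method)
        worst[method] = float(np.abs(est.to_numpy() - W).max())

    markers = find_markers(cohort.sc_counts, cohort.sc_labels)
    signature = build_signature(cohort.sc_counts, cohort.sc_labels, markers)
    est = estimate_proportions(cohort.gene_tpm, signature, method="nusvr")
    healthy = [s.sample_id for s in cohort.samples
               if s.tissue in ("iPSC-CVPC", "adult_heart", "adult_arteria")]
    rs = {}
    for ct in est.columns:
        rs[ct] = float(np.corrcoef(est.loc[healthy, ct],
                                   truth.proportions.loc[healthy, ct])[0, 1])
    # marker recovery against ground truth
    found = {ct: set(markers.loc[markers["cell_type"] == ct, "gene_id"])
             for ct in truth.marker_genes}
    recov = np.mean([len(found.get(ct, set()) & tg) / len(tg)
                     for ct, tg in truth.marker_genes.items()])
    all_true = set().union(*truth.marker_genes.values())
    reported = set(markers["gene_id"])
    false_frac = len(reported - all_true) / max(len(reported), 1)
    return {"noiseless_max_err_nnls": worst["nnls"],
            "noiseless_max_err_nusvr": worst["nusvr"],
            "per_type_pearson_r": rs, "min_pearson_r": min(rs.values()),
            "marker_recovery": float(recov),
            "marker_false_fraction": float(false_frac),
            "n_samples": len(healthy)}


# ---------------------------------------------------------------------------
# eCLIP sweep
# ---------------------------------------------------------------------------

def _toy_gene_universe(n_genes: int):
    """Single-isoform annotation: one gene per 2 kb on one chromosome."""
    genes, transcripts, exons, tg = {}, {}, {}, {}
    bodies = {}
    for i in range(n_genes):
        gid, tid, eid = f"g{i:04d}", f"t{i:04d}", f"e{i:04d}"
        start = 1000 + i * 2000
        exons[eid] = ExonRecord(eid, "chr1", start, start + 1000, "+")
        genes[gid] = GeneRecord(gid, gid, "+", [tid])
        transcripts[tid] = [eid]
        tg[tid] = gid
        bodies[gid] = ("chr1", start, start + 1000)
    return TranscriptAnnotation(genes, transcripts, exons, tg), bodies


def eclip_sweep_study(seed: int = 0, n_per_side: int = 500,
                      p_specific: float = 0.6, p_background: float = 0.3,
                      n_null_seeds: int = 20) -> dict:
    """Planted peak-overlap enrichment (overlap probability 0.6 for genes
    with specific isoforms vs 0.3 for background) and a null placement
    calibration (equal probabilities, mean log2 OR over seeds)."""
    def one(seed_, p_spec, p_bg):
        rng = np.random.default_rng(seed_)
        n = 2 * n_per_side
        ann, bodies = _toy_gene_universe(n)
        gids = sorted(bodies)
        spec, bg = gids[:n_per_side], gids[n_per_side:]
        de = pd.DataFrame({
            "feature_id": [f"t{i:04d}" for i in range(n)],
            "p_adj": [1e-10] * n_per_side + [1.0] * n_per_side,
            "log2_ratio": [3.0] * n_per_side + [0.0] * n_per_side,
        })
        intervals = []
        for g in gids:
            p = p_spec if g in set(spec) else p_bg
            if rng.random() < p:
                chrom, s, e = bodies[g]
                intervals.append((chrom, s + 100, s + 160))
        ps = PeakSet("E0", "RBP0", "K562", intervals)
        sweep = threshold_sweep(de, ann, bodies, [ps])
        row = sweep[(sweep["direction"] == "tissue1")
                    & (sweep["threshold"] == 0.0)].iloc[0]
        return float(row["odds_ratio"]), float(row["log2_or"]), sweep

    or0, _, sweep = one(seed, p_specific, p_background)
    n_points = int((sweep["direction"] == "tissue1").sum())
    null_log2 = []
    p_null = (p_specific + p_background) / 2
    for s in _child_seeds(seed + 1, n_null_seeds):
        _, l2, _ = one(s, p_null, p_null)
        null_log2.append(l2)
    return {"or_at_tau0": or0, "expected_or": (p_specific / (1 - p_specific))
            / (p_background / (1 - p_background)),
            "n_thresholds": n_points,
            "null_mean_log2_or": float(np.mean(null_log2)),
            "n_null_seeds": n_null_seeds}


# ---------------------------------------------------------------------------
# splice positional tests
# ---------------------------------------------------------------------------

def splice_positional_study(seed: int = 0, n_exons: int = 400,
                            n_seeds: int = 100, n_null_seeds: int = 50,
                            g1: float = 0.95, g2: float = 0.70) -> dict:
    """Planted donor+1 composition difference (P(G) = 0.95 vs 0.70) must be
    BH-flagged; identically generated sets must flag at most ~5% of
    positions on average."""
    lo1 = [(1 - g1) / 3] * 4; lo1[2] = g1
    lo2 = [(1 - g2) / 3] * 4; lo2[2] = g2
    prof1 = make_splice_profiles(overrides={("donor", 1): lo1})
    prof2 = make_splice_profiles(overrides={("donor", 1): lo2})
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        sim = simulate_splice_sets(n_exons, prof1, prof2, seed=s)
        profiles = splice_profiles(sim.pair, sim.exons, sim.genome)
        tests = positional_tests(profiles, ci=False)
        row = tests[(tests["side"] == "donor") & (tests["position"] == 1)
                    & (tests["nucleotide"] == "G")]
        hits += int(float(row["p_adj"].iloc[0]) < 0.05)
    null_fracs = []
    prof = make_splice_profiles()
    for s in _child_seeds(seed + 1, n_null_seeds):
        sim = simulate_splice_sets(n_exons, prof, prof, seed=s)
        profiles = splice_profiles(sim.pair, sim.exons, sim.genome)
        tests = positional_tests(profiles, ci=False)
        per_pos = tests.groupby(["side", "position"])["p_adj"].min() < 0.05
        null_fracs.append(float(per_pos.mean()))
    return {"flag_rate": hits / n_seeds, "n_seeds": n_seeds,
            "null_flag_fraction": float(np.mean(null_fracs)),
            "n_null_seeds": n_null_seeds, "n_exons": n_exons}


# ---------------------------------------------------------------------------
# heart-failure reversion
# ---------------------------------------------------------------------------

def _reversion_or_for_cohort(cohort, alpha=0.05):
    samples = cohort.samples_frame()
    usage, _ = compute_isoform_usage(cohort.iso_tpm, cohort.annotation)
    usage_f, _ = filter_expressed_isoforms(usage, cohort.annotation)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {}
        for key, t1, t2 in (("hf", "HF_pre", "adult_heart"),
                            ("ipsc", "iPSC-CVPC", "adult_heart")):
            sub = samples[samples["tissue"].isin([t1, t2])].reset_index(drop=True)
            norm, _ = inverse_normal_transform(usage_f.subset_samples(sub["sample_id"]))
            group = (sub["tissue"] == t1).to_numpy(float)
            props = cohort.truth.proportions.loc[sub["sample_id"]]
            out[key] = fit_ridge_de(norm, sub, group, proportions=props,
                                    coef_names=["group"])
    return reversion_statistic(out["hf"], out["ipsc"], alpha=alpha)


def reversion_monotonicity_study(seed: int = 0, rhos=(0.0, 0.25, 0.5, 0.75),
                                 n_seeds: int = 20) -> dict:
    """Mean reversion OR per planted reversion fraction rho; monotone
    increase is the expected signature."""
    means = {}
    for rho in rhos:
        ors = []
        for s in _child_seeds(seed + int(rho * 1000), n_seeds):
            cohort = simulate_cohort(SimConfig(seed=s, hf_reversion_frac=rho))
            ors.append(_reversion_or_for_cohort(cohort).odds_ratio)
        means[rho] = float(np.nanmean(ors))
    vals = [means[r] for r in rhos]
    return {"mean_or_by_rho": means,
            "monotone": bool(all(vals[i] < vals[i + 1]
                                 for i in range(len(vals) - 1)))}


def reversion_null_study(seed: int = 0, n_isoforms: int = 5000,
                         n_seeds: int = 100, p_hf: float = 0.3,
                         p_ipsc: float = 0.37) -> dict:
    """Independent DE labels and signs: the reversion OR must concentrate
    near 1."""
    rng = np.random.default_rng(seed)
    ors = []
    ids = [f"i{k:05d}" for k in range(n_isoforms)]
    for _ in range(n_seeds):
        de_hf = pd.DataFrame({
            "feature_id": ids,
            "beta": rng.normal(size=n_isoforms),
            "p_adj": np.where(rng.random(n_isoforms) < p_hf, 0.0, 1.0)})
        de_ip = pd.DataFrame({
            "feature_id": ids,
            "beta": rng.normal(size=n_isoforms),
            "p_adj": np.where(rng.random(n_isoforms) < p_ipsc, 0.0, 1.0)})
        ors.append(reversion_statistic(de_hf, de_ip).odds_ratio)
    ors = np.array(ors)
    return {"frac_in_band": float(((ors >= 0.8) & (ors <= 1.25)).mean()),
            "median_or": float(np.median(ors)), "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# GSEA calibration
# ---------------------------------------------------------------------------

def gsea_null_study(seed: int = 0, n_genes: int = 2000,
                    n_sets: int = 500) -> dict:
    """Random gene sets over symmetric-null effect sizes: the effect-size
    t-test p-values must be uniform (KS test vs U(0,1))."""
    rng = np.random.default_rng(seed)
    effects = pd.Series(rng.normal(size=n_genes),
                        index=[f"g{i:04d}" for i in range(n_genes)])
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(20, 100))
        members = set(rng.choice(effects.index.to_numpy(), size, replace=False))
        sets.append(GeneSet(f"null{k:03d}", "SIM", members))
    res = gsea_effectsize_ttest(effects, sets)
    ks = sps.kstest(res["p"].to_numpy(), "uniform")
    return {"ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "n_sets": int(len(res))}
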