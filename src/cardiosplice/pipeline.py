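"""Configuration-driven orchestration of every stage, with deterministic
outputs and JSON provenance sidecars.

Stages run in dependency order: preprocess -> pairwise DE -> deconvolution
-> ridge DE with proportions -> exon/eCLIP/motif analyses -> heart failure.
Every TSV output gains a sidecar recording the config hash and seed; rerun
with the same config gives byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import pandas as pd
import yaml

from . import __version__
from .de import (classify_specific, fisher_isoformDE_geneset, fit_linear_de,
                 fit_ridge_de, gsea_effectsize_ttest)
from .deconvolve import (build_signature, estimate_proportions, find_markers,
                         proportion_association)
from .eclip import mean_curve, threshold_sweep
from .heart_failure import (group_distances, joint_rbp_pca,
                            rbp_effectsize_location_test, reversion_statistic)
from .io import gene_body_intervals
from .preprocess import (compute_isoform_usage, filter_expressed_genes,
                         filter_expressed_isoforms, inverse_normal_transform)
from .simulate import SimConfig, simulate_cohort
from .splicing import (derive_specific_exons, domain_overlap_test,
                       first_exons, motif_window_enrichment,
                       polypyrimidine_profile, positional_tests,
                       splice_profiles)

PAIRWISE = [("iPSC-CVPC", "adult_heart"), ("iPSC-CVPC", "adult_arteria"),
            ("adult_heart", "adult_arteria")]

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "pipeline_out",
    "alpha": 0.05,
    "lr_thresh": 2.0,
    "n_pcs": 10,
    "deconvolution_method": "nusvr",
    "synthetic": {},
    "stages": ["preprocess", "de", "deconvolution", "ridge", "exons",
               "eclip", "heartfailure"],
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)

STAGE_DEPS = {
    "preprocess": [],
    "de": ["preprocess"],
    "deconvolution": ["preprocess"],
    "ridge": ["preprocess", "de", "deconvolution"],
    "exons": ["preprocess", "de"],
    "eclip": ["preprocess", "de"],
    "heartfailure": ["preprocess", "de", "deconvolution"],
}


class PipelineConfig(dict):
    @classmethod
    def load(cls, path=None, **overrides):
        cfg = dict(DEFAULT_CONFIG)
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            unknown = set(user) - _KNOWN_KEYS
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            cfg.update(user)
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        if not 0 < cfg["alpha"] < 1:
            raise ValueError("alpha must be in (0,1)")
        return cls(cfg)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: str, cfg: PipelineConfig, manifest: list,
           float_fmt="%.10g"):
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
    with open(path + ".json", "w") as fh:
        json.dump({"config_hash": cfg.hash(), "seed": cfg["seed"],
                   "version": __version__}, fh, sort_keys=True)
    manifest.append(path)


def run_pipeline(cfg: PipelineConfig, log=print) -> dict:
    """Run the enabled stages on a synthetic cohort.

    Returns a dict of in-memory results; ``results["manifest"]`` lists every
    artifact written under ``cfg["outdir"]``.
    """
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    manifest: list[str] = []
    results: dict = {}
    stages = list(cfg["stages"])
    unknown_stages = set(stages) - set(STAGE_DEPS)
    if unknown_stages:
        raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
    for st in stages:
        missing = [d for d in STAGE_DEPS[st] if d not in stages]
        if missing:
            raise ValueError(f"stage {st!r} requires upstream stage(s) {missing}")

    sim_kwargs = dict(cfg.get("synthetic") or {})
    sim_kwargs.setdefault("seed", cfg["seed"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(sim_kwargs) - known
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    cohort = simulate_cohort(SimConfig(**sim_kwargs))
    results["cohort"] = cohort
    samples = cohort.samples_frame()
    log(f"[simulate] {len(cohort.samples)} samples, "
        f"{len(cohort.gene_tpm.feature_ids)} genes, "
        f"{len(cohort.iso_tpm.feature_ids)} isoforms")

    if "preprocess" in stages:
        genes_f, grep = filter_expressed_genes(cohort.gene_tpm)
        usage, _silent = compute_isoform_usage(cohort.iso_tpm, cohort.annotation)
        usage_f, irep = filter_expressed_isoforms(usage, cohort.annotation)
        gene_norm, _ = inverse_normal_transform(genes_f)
        iso_norm, _ = inverse_normal_transform(usage_f)
        log(f"[preprocess] genes {grep.n_input} -> {grep.n_expressed}; "
            f"isoforms {irep.n_input} -> {irep.n_expressed}")
        results.update(gene_tpm_f=genes_f, usage_f=usage_f,
                       gene_norm=gene_norm, iso_norm=iso_norm)

    healthy = samples[samples["tissue"].isin(
        ["iPSC-CVPC", "adult_heart", "adult_arteria"])]
    key0 = "iPSC-CVPC_vs_adult_heart"

    if "de" in stages:
        de_gene, de_iso = {}, {}
        for t1, t2 in PAIRWISE:
            sub = healthy[healthy["tissue"].isin([t1, t2])]
            key = f"{t1}_vs_{t2}"
            g = fit_linear_de(gene_norm.subset_samples(sub["sample_id"]),
                              sub, t1, t2)
            g = classify_specific(g, genes_f, sub, t1, t2,
                                  lr_thresh=cfg["lr_thresh"], alpha=cfg["alpha"])
            i = fit_linear_de(iso_norm.subset_samples(sub["sample_id"]),
                              sub, t1, t2)
            i = classify_specific(i, usage_f, sub, t1, t2,
                                  lr_thresh=cfg["lr_thresh"], alpha=cfg["alpha"])
            de_gene[key], de_iso[key] = g, i
            _write(g, os.path.join(outdir, f"de_genes_{key}.tsv"), cfg, manifest)
            _write(i, os.path.join(outdir, f"de_isoforms_{key}.tsv"), cfg, manifest)
            log(f"[de] {key}: {int((g['p_adj'] < cfg['alpha']).sum())} DE genes, "
                f"{int((i['cls'] != 'not_DE').sum())} DE isoforms")
        results["de_gene"], results["de_iso"] = de_gene, de_iso

        effects = de_gene[key0].set_index("feature_id")["beta"]
        gsea = gsea_effectsize_ttest(effects, cohort.gene_sets)
        _write(gsea, os.path.join(outdir, "gsea_stage.tsv"), cfg, manifest)
        iso0 = de_iso[key0]
        gene_of = {f: cohort.annotation.gene_of(f) for f in iso0["feature_id"]}
        g_specific = {gene_of[f] for f, c in zip(iso0["feature_id"], iso0["cls"])
                      if c in ("tissue1_specific", "tissue2_specific")}
        g_any_de = {gene_of[f] for f, pa in zip(iso0["feature_id"], iso0["p_adj"])
                    if pa < cfg["alpha"]}
        g_none = set(gene_of.values()) - g_any_de
        fisher_sets = fisher_isoformDE_geneset(g_specific, g_none,
                                               cohort.gene_sets)
        _write(fisher_sets, os.path.join(outdir, "geneset_isoform_fisher.tsv"),
               cfg, manifest)
        results["gsea"], results["fisher_sets"] = gsea, fisher_sets

    if "deconvolution" in stages:
        markers = find_markers(cohort.sc_counts, cohort.sc_labels)
        signature = build_signature(cohort.sc_counts, cohort.sc_labels, markers)
        props = estimate_proportions(cohort.gene_tpm, signature,
                                     method=cfg["deconvolution_method"])
        _write(markers, os.path.join(outdir, "markers.tsv"), cfg, manifest)
        _write(props.reset_index(names="sample_id"),
               os.path.join(outdir, "proportions.tsv"), cfg, manifest)
        prop_assoc = proportion_association(
            gene_norm.subset_samples(healthy["sample_id"]), healthy,
            props.loc[healthy["sample_id"]])
        _write(prop_assoc, os.path.join(outdir, "proportion_association.tsv"),
               cfg, manifest)
        log(f"[deconvolution] {len(markers)} markers, "
            f"{signature.shape[0]} signature genes")
        results.update(markers=markers, signature=signature, proportions=props,
                       prop_assoc=prop_assoc)

    if "ridge" in stages:
        sub = healthy[healthy["tissue"].isin(["iPSC-CVPC", "adult_heart"])]
        group = (sub["tissue"] == "iPSC-CVPC").to_numpy(dtype=float)
        ridge = fit_ridge_de(gene_norm.subset_samples(sub["sample_id"]),
                             sub.reset_index(drop=True), group,
                             proportions=props.loc[sub["sample_id"]])
        _write(ridge, os.path.join(outdir, "ridge_stage_celltype.tsv"),
               cfg, manifest)
        n_stage = int((ridge.query("coefficient == 'group'")["p_adj"]
                       < cfg["alpha"]).sum())
        log(f"[ridge] {n_stage} stage-associated genes given cell-type "
            f"proportions")
        results["ridge"] = ridge

    if "exons" in stages:
        iso0 = results["de_iso"][key0]
        spec1 = iso0.loc[iso0["cls"] == "tissue1_specific", "feature_id"].tolist()
        spec2 = iso0.loc[iso0["cls"] == "tissue2_specific", "feature_id"].tolist()
        pair = derive_specific_exons(spec1, spec2, cohort.annotation,
                                     "iPSC-CVPC", "adult_heart")
        log(f"[exons] {len(pair.set1)} fetal-specific, {len(pair.set2)} "
            f"adult-specific exons")
        dom = domain_overlap_test(pair, cohort.annotation, cohort.domains)
        profiles = splice_profiles(pair, cohort.annotation, cohort.genome)
        pos_tests = positional_tests(profiles)
        ppt = polypyrimidine_profile(profiles)
        motifs = motif_window_enrichment(pair, cohort.annotation, cohort.genome,
                                         cohort.pwms,
                                         exclude=first_exons(cohort.annotation))
        _write(pos_tests, os.path.join(outdir, "splice_positional_tests.tsv"),
               cfg, manifest)
        _write(ppt["t_tests"], os.path.join(outdir, "polypyrimidine_tests.tsv"),
               cfg, manifest)
        _write(motifs, os.path.join(outdir, "motif_enrichment.tsv"),
               cfg, manifest)
        if not dom["skipped"]:
            _write(pd.DataFrame([{"odds_ratio": dom["odds_ratio"],
                                  "ci_low": dom["ci"][0],
                                  "ci_high": dom["ci"][1], "p": dom["p"]}]),
                   os.path.join(outdir, "domain_overlap.tsv"), cfg, manifest)
        results.update(exon_pair=pair, domain_overlap=dom,
                       splice_tests=pos_tests, ppt=ppt, motifs=motifs)

    if "eclip" in stages:
        bodies = gene_body_intervals(cohort.annotation)
        sweep = threshold_sweep(results["de_iso"][key0], cohort.annotation,
                                bodies, cohort.peaksets, alpha=cfg["alpha"])
        _write(sweep, os.path.join(outdir, "eclip_sweep.tsv"), cfg, manifest)
        _write(mean_curve(sweep), os.path.join(outdir, "eclip_mean_curve.tsv"),
               cfg, manifest)
        results["eclip_sweep"] = sweep

    if "heartfailure" in stages:
        props = results["proportions"]
        pcs, var_exp, _load = joint_rbp_pca(cohort.gene_tpm,
                                            cohort.truth.rbp_genes)
        dist = group_distances(pcs, samples,
                               K=min(cfg["n_pcs"], pcs.shape[1]))
        _write(pcs.reset_index(names="sample_id"),
               os.path.join(outdir, "rbp_pca.tsv"), cfg, manifest)
        _write(dist.paired, os.path.join(outdir, "hf_distances.tsv"),
               cfg, manifest)

        hf_sub = samples[samples["tissue"].isin(["HF_pre", "adult_heart"])]
        hf_group = (hf_sub["tissue"] == "HF_pre").to_numpy(dtype=float)
        ridge_hf_gene = fit_ridge_de(
            gene_norm.subset_samples(hf_sub["sample_id"]),
            hf_sub.reset_index(drop=True), hf_group,
            proportions=props.loc[hf_sub["sample_id"]], coef_names=["group"])
        rbp_idx = ridge_hf_gene["feature_id"].isin(set(cohort.truth.rbp_genes))
        loc_test = rbp_effectsize_location_test(
            ridge_hf_gene.loc[rbp_idx, "beta"].to_numpy())
        ridge_hf_iso = fit_ridge_de(
            iso_norm.subset_samples(hf_sub["sample_id"]),
            hf_sub.reset_index(drop=True), hf_group,
            proportions=props.loc[hf_sub["sample_id"]], coef_names=["group"])
        sub = healthy[healthy["tissue"].isin(["iPSC-CVPC", "adult_heart"])]
        group = (sub["tissue"] == "iPSC-CVPC").to_numpy(dtype=float)
        ridge_ipsc_iso = fit_ridge_de(
            iso_norm.subset_samples(sub["sample_id"]),
            sub.reset_index(drop=True), group,
            proportions=props.loc[sub["sample_id"]], coef_names=["group"])
        rev = reversion_statistic(ridge_hf_iso, ridge_ipsc_iso,
                                  alpha=cfg["alpha"])
        _write(ridge_hf_iso, os.path.join(outdir, "hf_isoform_de.tsv"),
               cfg, manifest)
        _write(pd.DataFrame([{
            "n_universe": rev.n_universe, "n_hf_de": rev.n_hf_de,
            "n_same_trend": rev.n_same_trend, "odds_ratio": rev.odds_ratio,
            "p": rev.p, "effect_correlation": rev.effect_correlation,
            "rbp_mean_effect": loc_test["mean"],
            "rbp_location_p": loc_test["p"],
        }]), os.path.join(outdir, "hf_reversion.tsv"), cfg, manifest)
        log(f"[heartfailure] reversion OR {rev.odds_ratio:.2f} "
            f"(p {rev.p:.2e}), effect r {rev.effect_correlation:.2f}")
        results.update(pcs=pcs, pca_var_exp=var_exp, distances=dist,
                       rbp_location=loc_test, reversion=rev,
                       ridge_hf_iso=ridge_hf_iso, ridge_ipsc_iso=ridge_ipsc_iso)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({"artifacts": sorted(os.path.relpath(p, outdir)
                                       for p in manifest),
                   "config_hash": cfg.hash()}, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
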