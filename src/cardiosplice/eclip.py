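"""Threshold sweep testing whether genes with tissue-specific isoforms are
enriched for overlapping eCLIP peaks.

For each of 13 log2-ratio cutoffs (0 to 6 in steps of 0.5) and each eCLIP
experiment, a Fisher 2x2 compares peak overlap between genes owning at
least one isoform passing the cutoff (per direction) and background genes
with no differentially expressed isoform at all.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PeakSet, TranscriptAnnotation
from .stats import fisher_2x2

DEFAULT_GRID = np.arange(0.0, 6.5, 0.5)     # 13 thresholds


def genes_overlapping_peaks(gene_bodies: dict[str, tuple[str, int, int]],
                            peaks: PeakSet) -> set[str]:
    """Genes whose body shares >= 1 bp with >= 1 peak (strand-blind)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in peaks.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    starts_ends = {c: (np.array([i[0] for i in sorted(iv)]),
                       np.array([i[1] for i in sorted(iv)]))
                   for c, iv in by_chrom.items()}
    out = set()
    for gid, (chrom, gs, ge) in gene_bodies.items():
        if chrom not in starts_ends:
            continue
        ps, pe = starts_ends[chrom]
        if bool(((ps < ge) & (pe > gs)).any()):
            out.add(gid)
    return out


def assign_gene_direction(de_iso: pd.DataFrame, ann: TranscriptAnnotation,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Collapse isoform DE to genes.

    Each gene with >= 1 FDR-significant isoform is assigned the direction
    and magnitude of its largest-|log2 ratio| significant isoform; genes with
    no DE isoform at all form the background.
    """
    df = de_iso.copy()
    df["gene_id"] = [ann.gene_of(f) for f in df["feature_id"]]
    sig = df[df["p_adj"] < alpha]
    rows = []
    for gid, grp in sig.groupby("gene_id"):
        best = grp.loc[grp["log2_ratio"].abs().idxmax()]
        rows.append((gid, float(best["log2_ratio"])))
    de_genes = pd.DataFrame(rows, columns=["gene_id", "log2_ratio"])
    any_de = set(de_genes["gene_id"])
    background = sorted(set(df["gene_id"]) - any_de)
    de_genes["direction"] = np.where(de_genes["log2_ratio"] > 0, "tissue1", "tissue2")
    return de_genes, background


def threshold_sweep(de_iso: pd.DataFrame, ann: TranscriptAnnotation,
                    gene_bodies, peaksets: list[PeakSet],
                    grid=DEFAULT_GRID, alpha: float = 0.05) -> pd.DataFrame:
    """Enrichment curves: per direction x experiment x cutoff, a Fisher 2x2
    (specific vs background) x (overlaps peaks).  Genes with DE isoforms
    failing a cutoff are excluded from both sides.  Returns a long frame;
    the cross-experiment mean log2 OR per (direction, cutoff) is the
    summary curve.
    """
    de_genes, background = assign_gene_direction(de_iso, ann, alpha)
    bg = set(background)
    results = []
    overlap_cache = {ps.experiment_id: genes_overlapping_peaks(gene_bodies, ps)
                     for ps in peaksets}
    for direction, sign in (("tissue1", 1.0), ("tissue2", -1.0)):
        dsub = de_genes[de_genes["direction"] == direction]
        for tau in grid:
            spec = set(dsub.loc[dsub["log2_ratio"] * sign > tau, "gene_id"])
            for ps in peaksets:
                hits = overlap_cache[ps.experiment_id]
                if not spec:
                    results.append((direction, ps.experiment_id, ps.rbp_name,
                                    float(tau), 0, len(bg), np.nan, np.nan, np.nan))
                    continue
                a = len(spec & hits); b = len(spec) - a
                c = len(bg & hits); d = len(bg) - c
                or_, p = fisher_2x2((a, b, c, d))
                results.append((direction, ps.experiment_id, ps.rbp_name,
                                float(tau), len(spec), len(bg), or_,
                                np.log2(or_) if or_ > 0 else np.nan, p))
    return pd.DataFrame(results, columns=["direction", "experiment_id",
                                          "rbp_name", "threshold",
                                          "n_specific", "n_background",
                                          "odds_ratio", "log2_or", "p"])


def mean_curve(sweep: pd.DataFrame) -> pd.DataFrame:
    """Cross-experiment mean log2 OR per direction and cutoff."""
    return (sweep.groupby(["direction", "threshold"])["log2_or"]
            .mean().reset_index(name="mean_log2_or"))
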