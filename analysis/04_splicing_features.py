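"""Stage-specific exons and their sequence features: protein-domain
overlap, splice-site positional composition, polypyrimidine tract, and
motif enrichment in acceptor-side windows.

Usage: python analysis/04_splicing_features.py [seed]
"""

import sys
import warnings

from cardiosplice.pipeline import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
cfg = PipelineConfig.load(seed=seed, outdir="results/splicing")
cfg["stages"] = ["preprocess", "de", "exons"]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_pipeline(cfg)

pair = res["exon_pair"]
print(f"specific exons: {len(pair.set1)} fetal-like, {len(pair.set2)} adult")
dom = res["domain_overlap"]
if not dom["skipped"]:
    print(f"domain overlap OR = {dom['odds_ratio']:.2f} "
          f"[{dom['ci'][0]:.2f}, {dom['ci'][1]:.2f}], p = {dom['p']:.2e}")
sig = res["splice_tests"].query("p_adj < 0.05")
print(f"{len(sig)} (position, nucleotide) composition differences at FDR 5%")
mot = res["motifs"].sort_values("q").iloc[0]
print(f"top motif: {mot['motif_id']} favored by {mot['favored']} "
      f"(log2 ratio {mot['log2_ratio']:+.2f}, q = {mot['q']:.2e})")
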