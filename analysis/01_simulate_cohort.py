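"""Generate the default synthetic cardiovascular cohort and write every
fixture (matrices, annotation, genome, peaks, motifs, gene sets, domains,
single-cell counts) in the standard formats.

Usage: python analysis/01_simulate_cohort.py [seed] [outdir]
"""

import sys

from cardiosplice.simulate import SimConfig, simulate_cohort, write_cohort

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
outdir = sys.argv[2] if len(sys.argv) > 2 else "results/cohort"

cohort = simulate_cohort(SimConfig(seed=seed))
manifest = write_cohort(cohort, outdir)

t = cohort.truth
print(f"cohort: {len(cohort.samples)} samples "
      f"({sum(s.tissue == 'iPSC-CVPC' for s in cohort.samples)} fetal-like, "
      f"{sum(s.tissue == 'adult_heart' for s in cohort.samples)} adult heart, "
      f"{sum(s.tissue == 'adult_arteria' for s in cohort.samples)} adult arteria, "
      f"{sum(s.tissue.startswith('HF') for s in cohort.samples)} heart failure)")
print(f"genes: {len(cohort.gene_tpm.feature_ids)}, "
      f"isoforms: {len(cohort.iso_tpm.feature_ids)}")
print(f"planted: {len(t.stage_de)} stage-DE genes, "
      f"{len(t.switch_table)} switch pairs "
      f"({int(t.switch_table['reverts'].sum())} reverting pre-LVAD), "
      f"{len(t.rbp_genes)} RBP-panel genes")
print(f"wrote {len(manifest)} fixtures to {outdir}")
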