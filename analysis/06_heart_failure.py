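"""Heart failure vs the fetal program: RBP-panel PCA with PC-space
distances (paired pre/post-LVAD tests), the RBP effect-size location test,
and the fetal-reversion odds ratio for isoform usage.

Usage: python analysis/06_heart_failure.py [seed]
"""

import sys
import warnings

from cardiosplice.pipeline import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
cfg = PipelineConfig.load(seed=seed, outdir="results/heart_failure")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_pipeline(cfg, log=lambda *_: None)

paired = res["distances"].paired.set_index("target")
for target in ("iPSC-CVPC", "adult_heart"):
    row = paired.loc[target]
    direction = "closer pre-LVAD" if row["mean_pre_minus_post"] < 0 \
        else "closer post-LVAD"
    print(f"distance to {target}: {direction} "
          f"(pre-post = {row['mean_pre_minus_post']:+.2f}, p = {row['p']:.2e})")

loc = res["rbp_location"]
print(f"RBP effect sizes (pre-LVAD vs adult heart): mean {loc['mean']:+.3f}, "
      f"p = {loc['p']:.2e}")

rev = res["reversion"]
A, B, C, D = rev.table
print(f"reversion: {rev.n_same_trend} of {rev.n_hf_de} HF-DE isoforms match "
      f"the fetal trend; OR = {rev.odds_ratio:.2f} (p = {rev.p:.2e}), "
      f"effect-size r = {rev.effect_correlation:.2f}")
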