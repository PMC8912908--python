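"""Cell-type deconvolution: find markers in the labeled single-cell counts,
build the signature matrix, estimate mixture proportions with nu-SVR, and
associate expression with each proportion.  Compares estimates against the
generator's true proportions.

Usage: python analysis/03_deconvolution.py [seed]
"""

import sys
import warnings

import numpy as np

from cardiosplice.pipeline import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
cfg = PipelineConfig.load(seed=seed, outdir="results/deconvolution")
cfg["stages"] = ["preprocess", "deconvolution"]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_pipeline(cfg)

truth = res["cohort"].truth.proportions
est = res["proportions"]
print(f"{len(res['markers'])} markers -> signature "
      f"{res['signature'].shape[0]} genes x {res['signature'].shape[1]} types")
for ct in est.columns:
    r = np.corrcoef(est[ct], truth.loc[est.index, ct])[0, 1]
    print(f"  {ct:<15s} Pearson r vs truth = {r:.3f}")
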