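"""Ground-truth validation sweep: oracle equivalences, null calibrations
and recovery of planted structure, summarized in one table.

This is the long-running companion to the per-stage drivers; it is the
same battery that scripts/acceptance.py reports.

Usage: python analysis/07_validation_studies.py [seed]
"""

import sys
import warnings

import pandas as pd

from cardiosplice import experiments as ex

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
warnings.filterwarnings("ignore")

rows = []

r = ex.ols_oracle_study(seed=seed, n_designs=100)
rows.append(("OLS vs normal-equations oracle (max |diff|)", r["max"]))
r = ex.null_calibration_study(seed=seed, n_seeds=100)
rows.append(("null fraction p<0.05", r["frac_p_lt_alpha"]))
rows.append(("null seeds with zero Bonferroni hits (/100)", r["n_clean_seeds"]))
r = ex.de_recovery_study(seed=seed)
rows.append(("specific-gene sensitivity", r["sensitivity"]))
rows.append(("false specific calls (/1700 nulls)", r["false_specific"]))
r = ex.ridge_limit_study(seed=seed)
rows.append(("ridge lambda=0 vs OLS (max |diff|)", r["lambda0_max_abs_diff"]))
r = ex.fisher_oracle_study()
rows.append(("exact-test OR vs enumeration (max rel diff)", r["max_or_rel_diff"]))
r = ex.deconvolution_study(seed=seed)
rows.append(("deconvolution min per-type Pearson r", r["min_pearson_r"]))
r = ex.eclip_sweep_study(seed=seed)
rows.append(("eCLIP OR at threshold 0 (target 3.5)", r["or_at_tau0"]))
r = ex.splice_positional_study(seed=seed)
rows.append(("splice planted-position flag rate", r["flag_rate"]))
rows.append(("splice null flagged fraction", r["null_flag_fraction"]))
r = ex.reversion_monotonicity_study(seed=seed)
for rho, v in r["mean_or_by_rho"].items():
    rows.append((f"reversion mean OR at rho={rho}", v))
r = ex.gsea_null_study(seed=seed)
rows.append(("GSEA null KS p", r["ks_p"]))

table = pd.DataFrame(rows, columns=["quantity", "value"])
table.to_csv("results/validation_summary.tsv", sep="\t", index=False)
print(table.to_string(index=False))
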