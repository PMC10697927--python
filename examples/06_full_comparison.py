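"""End-to-end comparison: threshold IDIF vs NMF-IDIF through kinetic modeling.

Runs the complete pipeline on the noisy phantom — both input-function
extractions, then 2TCM fits of synthetic brain regions with each input —
and prints the comparison report plus the per-region V_T table.
"""

import warnings

from nmfidif import RunConfig, run_compare, run_end_to_end

warnings.simplefilter("ignore")

config = RunConfig(seed=0, n_components=3)
report = run_compare(config)
for key in ("threshold_idif", "nmf_idif"):
    r = report[key]
    print(f"{key:>15}: r = {r['pearson_r']:.4f}, "
          f"integral {r['integral_candidate']:.1f} vs true {r['integral_reference']:.1f}, "
          f"|error| {r['abs_integral_error']:.1f} kBq/mL*min")

print()
table = run_end_to_end(config)
cols = ["region", "V_T_true", "V_T_true_plasma", "V_T_nmf_idif", "V_T_threshold_idif"]
print(table[cols].round(2).to_string(index=False))

# Reading the table: fits with the true plasma input recover V_T; the
# NMF-IDIF input gives a moderate underestimate (residual spill-in); the
# threshold IDIF's large positive activity bias depresses V_T far more -
# the same ordering the method shows on real scans.
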