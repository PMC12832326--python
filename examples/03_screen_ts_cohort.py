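"""Screen a TS cohort against the normative table.

Each subject's three ratios are converted to z-scores against their own
bone-age group, then two radiographic signs are flagged:

* metacarpal sign proxy: 4:3 (or 5:3) MC z-score strictly below -2
* brachydactyly type A3:  5:3 MP ratio strictly below 0.5
"""

from phalanx import (
    GeneratorConfig,
    build_default_reference,
    calibrated_ts_config,
    cohort_prevalence,
    generate_ts_cohort,
    screen_cohort,
)

config = GeneratorConfig(seed=20240)
table, trim, _, _ = build_default_reference(config)

# Calibrate the TS 4:3 MC mixture against this table, then simulate the
# study-sized TS cohort (n = 81).
ts_config = calibrated_ts_config(config, table)
metadata, ratios = generate_ts_cohort(ts_config, backend="ratio_level")

results = screen_cohort(ratios, metadata, table)
print(results.head().round(2).to_string(index=False))

summary = cohort_prevalence(results, metadata)
print("\nflag prevalence in the TS cohort:")
for flag in ("flag_mc43_short", "flag_mc53_short", "flag_bda3"):
    e = summary[flag]
    print(f"  {flag}: {e['count']}/{e['n']} ({100 * e['proportion']:.1f}%)")

# SHOX-related wrist signs ride along as boolean annotations.
for sign in ("shox_triangularization", "shox_lucency", "shox_pyramidalization"):
    e = summary[sign]
    print(f"  {sign}: {e['count']}/{e['n']} ({100 * e['proportion']:.1f}%)")
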