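"""Build the age-stratified normative reference table.

Reference construction has two steps: a single-pass +/-2.25 SDS trim on
each ratio (a subject is dropped if ANY of its three ratios is extreme),
then per-age-group means and SDs on the retained subjects.
"""

from phalanx import (
    GeneratorConfig,
    build_reference,
    compute_ratios,
    generate_reference_cohort,
    trim_outliers,
)

config = GeneratorConfig(seed=7)
metadata, lengths = generate_reference_cohort(config)
ratios, rejects = compute_ratios(lengths)
print(f"measured {len(ratios)} subjects ({len(rejects)} rejected rows)")

retained, trim = trim_outliers(ratios, trim_limit=2.25)
print(
    f"trim at +/-2.25 SDS: retained {trim.n_retained}/"
    f"{trim.n_input} ({100 * trim.n_retained / trim.n_input:.1f}%)"
)
print(f"per-ratio exclusions: {trim.n_excluded_per_ratio}")

table = build_reference(retained, metadata, trim_limit=2.25)

# The table is the normative product: for each ratio, six bone-age groups
# with n / mean / SD, plus pooled rows.
print()
print("4:3 MC ratio by bone-age group:")
for g in range(1, 7):
    s = table.group_stat("r43mc", g)
    print(f"  group {g}: n={s.n:4d}  mean={s.mean:.3f}  sd={s.sd:.4f}")
pooled = table.pooled["r43mc"]
print(f"  pooled : n={pooled.n:4d}  mean={pooled.mean:.3f}  sd={pooled.sd:.4f}")

# Persist for later screening runs; the JSON round-trips exactly.
table.to_json("reference.json")
print("\nwrote reference.json")
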