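"""Filter and classify somatic panel variants for actionability.

Simulates a small testing cohort, applies the dual-pool / coverage / 4%-LOD
retention filters and the therapy rule engine, and prints what was retained
and why variants were actionable.
"""

from lungdx.simulate import CohortSpec, generate_variant_cohort
from lungdx.variants import annotate_variants

samples, variants, truth = generate_variant_cohort(CohortSpec(n_samples=60, seed=4))
annotated = annotate_variants(variants)

n_ret = int(annotated["retained"].sum())
n_act = int(annotated["actionable"].sum())
print(f"{len(annotated)} called variants in {len(samples)} samples")
print(f"retained after filters: {n_ret}")
print(f"actionable: {n_act}")

print("\nactionable variants and the rule each one matched:")
act = annotated[annotated["actionable"]]
for row in act.head(12).itertuples(index=False):
    print(
        f"  {row.sample_id} {row.gene:7s} {row.protein_change:.<16s} "
        f"VAF {row.vaf:.2f}  -> {row.matched_rule} ({row.tier})"
    )
# "standard" tier = approved EGFR-inhibitor indications; "emerging" covers
# proposed targets (KRAS, BRAF V600, PIK3CA hotspots, ERBB2 insertions, ...).
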