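"""Stratify a simulated testing cohort by actionable alterations.

Joins annotated variants to sample metadata and prints, per histology
group, the proportion with >=1 actionable alteration and the therapy
eligibility pie (EGFR+ / other emerging targets / KRAS-only / none).
"""

from lungdx.simulate import CohortSpec, generate_variant_cohort
from lungdx.stratify import build_sample_records, cooccurrence_matrix, stratify
from lungdx.variants import annotate_variants

samples, variants, _ = generate_variant_cohort(CohortSpec(n_samples=533, seed=2))
records = build_sample_records(samples, annotate_variants(variants))
report = stratify(records)

for group in ("overall", "adenocarcinoma", "SqCC", "NSCLC-NOS"):
    g = report[group]
    print(
        f"{group:15s} n={g['n_samples']:3d}  "
        f">=1 actionable: {g['percent_ge1_actionable']:5.1f}% "
        f"(excl. KRAS: {g['percent_ge1_actionable_excl_kras']:5.1f}%)"
    )

print(f"\ntriple-negative (no EGFR/KRAS/BRAF mutation): {report['n_triple_negative']}")
print("\nadenocarcinoma eligibility pie:")
for cat, n in report["adenocarcinoma"]["eligibility_pie"].items():
    pct = report["adenocarcinoma"]["eligibility_pie_percent"][cat]
    print(f"  {cat:10s} {n:3d} ({pct}%)")

mat = cooccurrence_matrix(records)
print("\nco-occurrence (samples altered in both genes), top-left corner:")
print(mat.iloc[:5, :5].to_string())
# KRAS_only means the only actionable alteration is KRAS - relevant because
# KRAS-directed therapy remains an emerging option; the EGFR+ slice is
# eligible for standard EGFR inhibitors irrespective of co-alterations.
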