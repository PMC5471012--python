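"""Evaluate panel-vs-single-gene assay concordance on the validation fixture.

The fixture reproduces the validation comparison: 92 paired calls across
EGFR/KRAS/NRAS/BRAF in lung, melanoma and colon tumors, with one genuinely
discordant KRAS call and three discordances caused by the panel detecting
variants outside the single-gene assays' scope.
"""

from lungdx import fixtures
from lungdx.concordance import evaluate_concordance, tabulate_by_gene
from lungdx.simulate import generate_paired_calls

calls = generate_paired_calls(fixtures.validation_paired_call_spec(seed=1))

rep = evaluate_concordance(calls)
print(f"paired calls: {rep.n_total}")
print(f"concordant: {rep.n_concordant} ({rep.percent_int}%)")

rep_x = evaluate_concordance(calls, exclude_out_of_scope=True)
print(
    f"excluding {rep_x.n_out_of_scope} out-of-scope calls: "
    f"{rep_x.n_concordant_in_scope}/{rep_x.n_total_in_scope} "
    f"({rep_x.headline_percent_int}%)"
)

print("\nreference calls by gene (mutation / no mutation):")
print(tabulate_by_gene(calls).to_string(index=False))
# Out-of-scope rows are variants the panel found at loci the corresponding
# single-gene assay never interrogates - a method-scope difference, not a
# disagreement, hence the second (higher) concordance rendering.
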