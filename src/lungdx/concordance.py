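"""Paired-call concordance between a panel assay and prior single-gene assays.

Each row pairs one reference-method call with one test-method call at one
gene/locus in one sample. A call is either a specific mutation or
"no_mutation". Rows can be flagged out-of-scope when the test assay detected
a variant at a locus the reference single-gene assay never interrogates;
such rows can be excluded from both numerator and denominator, mirroring how
validation studies report concordance with and without method-scope
discordances.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

NO_MUTATION = "no_mutation"

PAIRED_CALL_COLUMNS = [
    "sample_id",
    "cohort",
    "gene",
    "reference_call",
    "reference_variant",
    "test_call",
    "test_variant",
    "in_scope",
]


@dataclass
class ConcordanceReport:
    """Concordance accounting, before and after out-of-scope exclusion."""

    n_total: int
    n_concordant: int
    percent: float          # one decimal, all calls
    percent_int: int        # nearest integer, all calls
    n_out_of_scope: int
    n_total_in_scope: int
    n_concordant_in_scope: int
    percent_in_scope: float
    percent_in_scope_int: int
    excluded: bool = False

    @property
    def headline_percent_int(self) -> int:
        return self.percent_in_scope_int if self.excluded else self.percent_int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_concordant(row) -> bool:
    ref_mut = row.reference_call != NO_MUTATION
    test_mut = row.test_call != NO_MUTATION
    if ref_mut != test_mut:
        return False
    if not ref_mut:
        return True
    # both mutation calls: compare variant identity when both report one
    ref_v = None if pd.isna(row.reference_variant) else str(row.reference_variant)
    test_v = None if pd.isna(row.test_variant) else str(row.test_variant)
    if ref_v is None or test_v is None:
        return True
    return ref_v == test_v


def evaluate_concordance(
    calls: pd.DataFrame, exclude_out_of_scope: bool = False
) -> ConcordanceReport:
    """Count agreeing reference/test call pairs.

    Concordant iff both methods agree on mutation-vs-no-mutation, and, when
    both report a mutation, on the variant itself (protein change if both
    carry one, else coding change — callers store whichever identity they
    compare in the *_variant columns).
    """
    if calls is None or len(calls) == 0:
        raise ValueError("empty paired-call table")
    conc = calls.apply(_is_concordant, axis=1)
    in_scope = calls["in_scope"].astype(bool)

    n_total = len(calls)
    n_concordant = int(conc.sum())
    n_oos = int((~in_scope).sum())
    n_total_is = int(in_scope.sum())
    n_concordant_is = int((conc & in_scope).sum())

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else 0.0

    return ConcordanceReport(
        n_total=n_total,
        n_concordant=n_concordant,
        percent=pct(n_concordant, n_total),
        percent_int=round(100.0 * n_concordant / n_total),
        n_out_of_scope=n_oos,
        n_total_in_scope=n_total_is,
        n_concordant_in_scope=n_concordant_is,
        percent_in_scope=pct(n_concordant_is, n_total_is),
        percent_in_scope_int=(
            round(100.0 * n_concordant_is / n_total_is) if n_total_is else 0
        ),
        excluded=exclude_out_of_scope,
    )


def tabulate_by_gene(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (mutation, no-mutation) reference-call counts plus totals.

    Classification follows the reference method's call, matching how
    validation tables count "hot spot mutation calls (mut/no mutation)".
    """
    if calls is None or len(calls) == 0:
        raise ValueError("empty paired-call table")
    rows = []
    for gene, grp in calls.groupby("gene", sort=True):
        is_mut = grp["reference_call"] != NO_MUTATION
        rows.append(
            {
                "gene": gene,
                "n_mutation": int(is_mut.sum()),
                "n_no_mutation": int((~is_mut).sum()),
            }
        )
    out = pd.DataFrame(rows)
    total = pd.DataFrame(
        [
            {
                "gene": "TOTAL",
                "n_mutation": int(out["n_mutation"].sum()),
                "n_no_mutation": int(out["n_no_mutation"].sum()),
            }
        ]
    )
    return pd.concat([out, total], ignore_index=True)
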