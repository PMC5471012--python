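"""Cohort stratification by actionable alterations.

Joins per-sample variant annotations, fusion calls and histology metadata,
then computes the cohort-level summaries a molecular tumor board reads:
triple-negative status (no EGFR/KRAS/BRAF mutation), the proportion of each
histology group with at least one actionable alteration, therapy-eligibility
categories (EGFR+ / ALK+ / other emerging targets / KRAS-only / none),
variant-burden histograms and a gene-by-gene co-occurrence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import FusionCall, STATUS_KNOWN, STATUS_NOVEL, STATUS_QC_FAIL
from .variants import SYNONYMOUS

HISTOLOGIES = ("adenocarcinoma", "SqCC", "NSCLC-NOS", "other")

TRIPLE_NEGATIVE_GENES = ("EGFR", "KRAS", "BRAF")

#: genes whose actionable alterations define "emerging therapy" eligibility
#: beyond EGFR inhibitors and ALK inhibitors; order sets category precedence
EMERGING_GENES = ("RET", "ROS1", "BRAF", "PIK3CA", "ERBB2", "NRAS", "MAP2K1", "AKT1")

CATEGORY_NONE = "none"
CATEGORY_KRAS_ONLY = "KRAS_only"

POSITIVE_STATUSES = (STATUS_KNOWN, STATUS_NOVEL)


@dataclass
class SampleRecord:
    """One sample with its annotated variants and fusion calls joined in."""

    sample_id: str
    histology: str
    specimen_type: str = "FFPE"
    tumor_cell_content: float = 50.0
    variants: pd.DataFrame | None = None          # annotated variant rows
    fusion_calls: list[FusionCall] = field(default_factory=list)
    alk_ihc: str = "NA"
    alk_ros1_fish: str = "NA"

    @property
    def retained_variants(self) -> pd.DataFrame:
        if self.variants is None or len(self.variants) == 0:
            return pd.DataFrame(columns=["gene", "actionable", "variant_class"])
        return self.variants[self.variants["retained"]]

    def actionable_genes(self, include_kras: bool = True) -> set[str]:
        """Genes with >=1 retained actionable mutation, plus fusion genes."""
        rv = self.retained_variants
        genes = set(rv.loc[rv["actionable"], "gene"]) if len(rv) else set()
        if not include_kras:
            genes.discard("KRAS")
        genes |= self.fusion_positive_genes
        return genes

    @property
    def fusion_positive_genes(self) -> set[str]:
        return {
            c.gene for c in self.fusion_calls if c.status in POSITIVE_STATUSES
        }

    @property
    def fusion_tested(self) -> bool:
        """Assayed and QC-passing for at least one gene."""
        return any(c.status != STATUS_QC_FAIL for c in self.fusion_calls)


def is_triple_negative(record: SampleRecord) -> bool:
    """No retained EGFR, KRAS or BRAF mutation (fusion results play no part)."""
    rv = record.retained_variants
    if len(rv) == 0:
        return True
    return not rv["gene"].isin(TRIPLE_NEGATIVE_GENES).any()


def eligibility_category(
    record: SampleRecord,
    precedence: tuple[str, ...] = ("EGFR", "ALK"),
    t790m_counts: bool = True,
) -> str:
    """Therapy-eligibility category of one sample.

    EGFR+ means an actionable EGFR mutation irrespective of other
    alterations; ALK+ an ALK fusion irrespective of other alterations;
    then one category per other emerging-target gene; KRAS_only when the
    only actionable alteration(s) are KRAS; else none. The EGFR/ALK order
    for the rare double-positive is configurable via `precedence`.
    """
    rv = record.retained_variants
    act = rv[rv["actionable"]] if len(rv) else rv
    mut_genes = set(act["gene"]) if len(act) else set()
    if not t790m_counts and len(act):
        only_t790m = act[act["gene"] == "EGFR"]["matched_rule"].eq("EGFR_T790M").all()
        if "EGFR" in mut_genes and only_t790m:
            mut_genes.discard("EGFR")
    fus_genes = record.fusion_positive_genes

    for first in precedence:
        if first == "EGFR" and "EGFR" in mut_genes:
            return "EGFR+"
        if first == "ALK" and "ALK" in fus_genes:
            return "ALK+"
    for gene in EMERGING_GENES:
        if gene in mut_genes or gene in fus_genes:
            return f"{gene}+"
    if "KRAS" in mut_genes:
        return CATEGORY_KRAS_ONLY
    return CATEGORY_NONE


def _variant_burden_bin(n: int) -> str:
    if n == 0:
        return "0"
    if n <= 2:
        return "1-2"
    return ">2"


def _group_report(records: list[SampleRecord]) -> dict:
    n = len(records)
    cats = [eligibility_category(r) for r in records]
    genes_incl = [r.actionable_genes(include_kras=True) for r in records]
    genes_excl = [r.actionable_genes(include_kras=False) for r in records]
    n_ge1 = sum(1 for g in genes_incl if g)
    n_ge1_no_kras = sum(1 for g in genes_excl if g)

    hist: dict[str, int] = {"0": 0, "1-2": 0, ">2": 0}
    per_gene: dict[str, int] = {}
    for r in records:
        rv = r.retained_variants
        nonsyn = rv[rv["variant_class"] != SYNONYMOUS] if len(rv) else rv
        hist[_variant_burden_bin(len(nonsyn))] += 1
        for g in set(rv.loc[rv["actionable"], "gene"]) if len(rv) else set():
            per_gene[g] = per_gene.get(g, 0) + 1
        for g in r.fusion_positive_genes:
            per_gene[g] = per_gene.get(g, 0) + 1

    pie = {c: cats.count(c) for c in sorted(set(cats))}
    n_tested = sum(1 for r in records if r.fusion_tested)
    n_fus_pos = sum(1 for r in records if r.fusion_positive_genes)

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else 0.0

    return {
        "n_samples": n,
        "n_ge1_actionable": n_ge1,
        "percent_ge1_actionable": pct(n_ge1, n),
        "n_ge1_actionable_excl_kras": n_ge1_no_kras,
        "percent_ge1_actionable_excl_kras": pct(n_ge1_no_kras, n),
        "variant_count_histogram": hist,
        "eligibility_pie": pie,
        "eligibility_pie_percent": {c: pct(k, n) for c, k in pie.items()},
        "per_gene_actionable": dict(sorted(per_gene.items())),
        "n_fusion_tested": n_tested,
        "n_fusion_positive": n_fus_pos,
        "percent_fusion_positive_of_tested": pct(n_fus_pos, n_tested),
        "percent_fusion_positive_of_all": pct(n_fus_pos, n),
    }


def stratify(records: list[SampleRecord]) -> dict:
    """Full stratification report: overall and per histology group.

    Fusion-untested samples stay in every denominator except the
    "of_tested" fusion-positivity rendering, which divides by successfully
    assayed samples only (both denominators are reported). Pure function of
    its inputs.
    """
    if not records:
        raise ValueError("empty cohort")
    report = {"overall": _group_report(records)}
    for hist in HISTOLOGIES:
        group = [r for r in records if r.histology == hist]
        if group:
            report[hist] = _group_report(group)
    report["n_triple_negative"] = sum(1 for r in records if is_triple_negative(r))
    return report


def cooccurrence_matrix(records: list[SampleRecord]) -> pd.DataFrame:
    """Symmetric gene x gene matrix of samples altered in both genes.

    An alteration is any retained variant or fusion-positive call; the
    diagonal holds per-gene sample totals.
    """
    gene_sets = []
    for r in records:
        rv = r.retained_variants
        genes = set(rv["gene"]) if len(rv) else set()
        genes |= r.fusion_positive_genes
        gene_sets.append(genes)
    all_genes = sorted(set().union(*gene_sets)) if gene_sets else []
    mat = pd.DataFrame(
        np.zeros((len(all_genes), len(all_genes)), dtype=int),
        index=all_genes,
        columns=all_genes,
    )
    for genes in gene_sets:
        for g1 in genes:
            for g2 in genes:
                mat.loc[g1, g2] += 1
    return mat


def build_sample_records(
    samples: pd.DataFrame,
    annotated_variants: pd.DataFrame | None = None,
    fusion_calls: pd.DataFrame | None = None,
) -> list[SampleRecord]:
    """Assemble SampleRecords from the three keyed tables.

    `samples` needs sample_id + histology (specimen_type, tumor_cell_content,
    alk_ihc, alk_ros1_fish optional); variants/fusions join on sample_id.
    """
    records = []
    var_by_sample = (
        dict(tuple(annotated_variants.groupby("sample_id")))
        if annotated_variants is not None and len(annotated_variants)
        else {}
    )
    fus_by_sample: dict[str, list[FusionCall]] = {}
    if fusion_calls is not None and len(fusion_calls):
        for row in fusion_calls.itertuples(index=False):
            fus_by_sample.setdefault(str(row.sample_id), []).append(
                FusionCall(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    status=str(row.status),
                    best_fusion_id=(
                        None if pd.isna(row.best_fusion_id) else str(row.best_fusion_id)
                    ),
                    ratio_3p5p=float(row.ratio_3p5p),
                    max_specific_signal=float(row.max_specific_signal),
                    qc_ratio=float(row.qc_ratio),
                )
            )
    for row in samples.itertuples(index=False):
        sid = str(row.sample_id)
        records.append(
            SampleRecord(
                sample_id=sid,
                histology=str(row.histology),
                specimen_type=str(getattr(row, "specimen_type", "FFPE")),
                tumor_cell_content=float(getattr(row, "tumor_cell_content", 50.0)),
                variants=var_by_sample.get(sid),
                fusion_calls=fus_by_sample.get(sid, []),
                alk_ihc=str(getattr(row, "alk_ihc", "NA")),
                alk_ros1_fish=str(getattr(row, "alk_ros1_fish", "NA")),
            )
        )
    return records
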