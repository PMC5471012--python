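"""Unit tests for cohort stratification."""

import pandas as pd
import pytest

from lungdx.fusion import FusionCall
from lungdx.simulate import CohortSpec, generate_variant_cohort
from lungdx.stratify import (
    SampleRecord,
    build_sample_records,
    cooccurrence_matrix,
    eligibility_category,
    is_triple_negative,
    stratify,
)
from lungdx.variants import annotate_variants


def _record(sid="S1", histology="adenocarcinoma", variants=None, fusions=()):
    df = None
    if variants:
        df = annotate_variants(
            pd.DataFrame(
                [
                    {
                        "sample_id": sid,
                        "gene": gene,
                        "coding_change": None,
                        "protein_change": change,
                        "exon": exon,
                        "vaf": 0.3,
                        "detected_in_pool_a": True,
                        "detected_in_pool_b": True,
                        "coverage": 2000,
                    }
                    for gene, change, exon in variants
                ]
            )
        )
    calls = [
        FusionCall(sid, gene, status, fid, 10.0, 500.0, 1.0)
        for gene, status, fid in fusions
    ]
    return SampleRecord(
        sample_id=sid, histology=histology, variants=df, fusion_calls=calls
    )


class TestTripleNegative:
    def test_tp53_only_is_triple_negative(self):
        assert is_triple_negative(_record(variants=[("TP53", "p.R175H", 5)]))

    def test_kras_mutation_is_not(self):
        assert not is_triple_negative(_record(variants=[("KRAS", "p.G12V", 2)]))

    def test_no_variants_is_triple_negative(self):
        assert is_triple_negative(_record())

    def test_fusion_results_never_alter_status(self):
        rec = _record(
            variants=[("TP53", "p.R175H", 5)],
            fusions=[("ALK", "KNOWN_FUSION", "EML4-ALK_E13:A20")],
        )
        assert is_triple_negative(rec)


class TestEligibilityCategory:
    def test_egfr_wins_over_concurrent_kras(self):
        rec = _record(
            variants=[("EGFR", "p.L858R", 21), ("KRAS", "p.G12C", 2)]
        )
        assert eligibility_category(rec) == "EGFR+"

    def test_alk_fusion_wins_over_braf(self):
        rec = _record(
            variants=[("BRAF", "p.V600E", 15)],
            fusions=[("ALK", "KNOWN_FUSION", "EML4-ALK_E13:A20")],
        )
        assert eligibility_category(rec) == "ALK+"

    def test_kras_only(self):
        assert (
            eligibility_category(_record(variants=[("KRAS", "p.G12C", 2)]))
            == "KRAS_only"
        )

    def test_braf_with_kras_is_braf_category(self):
        rec = _record(
            variants=[("BRAF", "p.V600E", 15), ("KRAS", "p.G12C", 2)]
        )
        assert eligibility_category(rec) == "BRAF+"

    def test_no_actionable_is_none(self):
        assert eligibility_category(_record(variants=[("TP53", "p.R175H", 5)])) == "none"

    def test_novel_fusion_counts_as_positive(self):
        rec = _record(fusions=[("RET", "NOVEL_FUSION", None)])
        assert eligibility_category(rec) == "RET+"

    def test_precedence_is_configurable(self):
        rec = _record(
            variants=[("EGFR", "p.L858R", 21)],
            fusions=[("ALK", "KNOWN_FUSION", "EML4-ALK_E13:A20")],
        )
        assert eligibility_category(rec) == "EGFR+"
        assert eligibility_category(rec, precedence=("ALK", "EGFR")) == "ALK+"


class TestStratify:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stratify([])

    def test_all_kras_cohort(self):
        records = [
            _record(sid=f"S{i}", variants=[("KRAS", "p.G12C", 2)])
            for i in range(5)
        ]
        rep = stratify(records)
        assert rep["overall"]["percent_ge1_actionable"] == 100.0
        assert rep["overall"]["eligibility_pie"] == {"KRAS_only": 5}
        assert rep["overall"]["percent_ge1_actionable_excl_kras"] == 0.0

    def test_two_sample_histology_split(self):
        records = [
            _record(sid="A", histology="adenocarcinoma",
                    variants=[("EGFR", "p.L858R", 21)]),
            _record(sid="B", histology="SqCC"),
        ]
        rep = stratify(records)
        assert rep["adenocarcinoma"]["percent_ge1_actionable"] == 100.0
        assert rep["SqCC"]["percent_ge1_actionable"] == 0.0

    def test_pie_partitions_every_group(self):
        spec = CohortSpec(n_samples=300, seed=17)
        samples, variants, _ = generate_variant_cohort(spec)
        records = build_sample_records(samples, annotate_variants(variants))
        rep = stratify(records)
        for group, g in rep.items():
            if not isinstance(g, dict):
                continue
            assert sum(g["eligibility_pie"].values()) == g["n_samples"]
            assert sum(g["variant_count_histogram"].values()) == g["n_samples"]
            # percent >=1 actionable complements percent(none)
            none = g["eligibility_pie"].get("none", 0)
            assert g["n_ge1_actionable"] == g["n_samples"] - none

    def test_report_matches_truth_sidecar_exactly(self):
        spec = CohortSpec(n_samples=400, seed=23)
        samples, variants, truth = generate_variant_cohort(spec)
        records = build_sample_records(samples, annotate_variants(variants))
        rep = stratify(records)
        assert rep["overall"]["n_ge1_actionable"] == int(truth["actionable"].sum())

    def test_determinism(self):
        spec = CohortSpec(n_samples=100, seed=31)
        samples, variants, _ = generate_variant_cohort(spec)
        records = build_sample_records(samples, annotate_variants(variants))
        assert stratify(records) == stratify(records)


class TestCooccurrence:
    def test_single_double_mutant_sample(self):
        records = [
            _record(variants=[("KRAS", "p.G12C", 2), ("PIK3CA", "p.E545K", 9)])
        ]
        mat = cooccurrence_matrix(records)
        assert mat.loc["KRAS", "PIK3CA"] == 1
        assert mat.loc["KRAS", "KRAS"] == 1

    def test_mutually_exclusive_drivers_have_zero_offdiagonals(self):
        records = [
            _record(sid="A", variants=[("KRAS", "p.G12C", 2)]),
            _record(sid="B", variants=[("EGFR", "p.L858R", 21)]),
        ]
        mat = cooccurrence_matrix(records)
        assert mat.loc["KRAS", "EGFR"] == 0
        assert mat.loc["KRAS", "KRAS"] == 1

    def test_matches_pairwise_brute_force(self):
        spec = CohortSpec(n_samples=50, seed=41)
        samples, variants, _ = generate_variant_cohort(spec)
        records = build_sample_records(samples, annotate_variants(variants))
        mat = cooccurrence_matrix(records)
        # O(n * g^2) recount straight from the records
        for g1 in mat.index:
            for g2 in mat.columns:
                n = 0
                for r in records:
                    genes = set(r.retained_variants["gene"]) | r.fusion_positive_genes
                    if g1 in genes and g2 in genes:
                        n += 1
                assert mat.loc[g1, g2] == n

    def test_symmetry(self):
        spec = CohortSpec(n_samples=80, seed=43)
        samples, variants, _ = generate_variant_cohort(spec)
        records = build_sample_records(samples, annotate_variants(variants))
        mat = cooccurrence_matrix(records)
        assert (mat.values == mat.values.T).all()
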