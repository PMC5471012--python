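"""Unit tests for variant parsing, filtering and the actionability engine."""

import pandas as pd
import pytest

from lungdx.variants import (
    ActionabilityRule,
    RuleLoadError,
    check_panel_membership,
    classify_actionable,
    filter_variants,
    load_rules,
    parse_protein_change,
)


class TestProteinChangeParser:
    @pytest.mark.parametrize(
        "notation,codon,ref,alt,kind",
        [
            ("p.L858R", 858, "L", "R", "missense"),
            ("L858R", 858, "L", "R", "missense"),
            ("p.Leu858Arg", 858, "L", "R", "missense"),
            ("p.G12C", 12, "G", "C", "missense"),
            ("p.R196*", 196, "R", "*", "nonsense"),
            ("p.Arg196Ter", 196, "R", "*", "nonsense"),
            ("p.L858=", 858, "L", "L", "synonymous"),
            ("p.E746_A750del", 746, "E", None, "inframe_del"),
            ("p.A767_V769dup", 767, "A", None, "inframe_ins"),
            ("p.D770_N771insSVD", 770, "D", None, "inframe_ins"),
            ("p.P152fs", 152, "P", None, "frameshift"),
            ("p.P152Lfs*18", 152, "P", None, "frameshift"),
        ],
    )
    def test_dialect(self, notation, codon, ref, alt, kind):
        parsed = parse_protein_change(notation)
        assert parsed.codon == codon
        assert parsed.ref_aa == ref
        assert parsed.alt_aa == alt
        assert parsed.variant_class == kind

    @pytest.mark.parametrize("junk", ["", None, "???", "c.2573T>G", "12345"])
    def test_unparseable_is_other_never_raises(self, junk):
        parsed = parse_protein_change(junk)
        assert parsed.variant_class == "other"
        assert parsed.codon is None

    def test_exon_event_alias(self):
        parsed = parse_protein_change("exon19del")
        assert parsed.variant_class == "inframe_del"
        assert parsed.codon is None


def _variant_row(**kw):
    row = {
        "sample_id": "S1",
        "gene": "EGFR",
        "coding_change": "c.2573T>G",
        "protein_change": "p.L858R",
        "exon": 21,
        "vaf": 0.30,
        "detected_in_pool_a": True,
        "detected_in_pool_b": True,
        "coverage": 2000,
    }
    row.update(kw)
    return row


class TestRetentionFilters:
    def test_clean_variant_retained(self):
        df = filter_variants(pd.DataFrame([_variant_row(vaf=0.08)]))
        assert df.loc[0, "retained"]

    def test_single_pool_rejected_with_pool_reason(self):
        df = filter_variants(
            pd.DataFrame([_variant_row(detected_in_pool_b=False)])
        )
        assert not df.loc[0, "retained"]
        assert df.loc[0, "rejection_reason"] == "pool_discordance"

    def test_vaf_lod_is_inclusive_and_coverage_strict(self):
        rows = [
            _variant_row(vaf=0.04, coverage=1001),   # retained: VAF at LOD
            _variant_row(vaf=0.0399, coverage=1001), # below LOD
            _variant_row(vaf=0.04, coverage=1000),   # coverage not > 1000
        ]
        df = filter_variants(pd.DataFrame(rows))
        assert list(df["retained"]) == [True, False, False]
        assert df.loc[1, "rejection_reason"] == "below_lod"
        assert df.loc[2, "rejection_reason"] == "low_coverage"

    def test_rejection_reason_order_pool_first(self):
        # fails every rule; the pool rule is reported
        df = filter_variants(
            pd.DataFrame(
                [_variant_row(detected_in_pool_a=False, vaf=0.01, coverage=10)]
            )
        )
        assert df.loc[0, "rejection_reason"] == "pool_discordance"

    def test_retained_set_independent_of_input_order(self):
        rows = [
            _variant_row(sample_id=f"S{i}", vaf=v)
            for i, v in enumerate([0.5, 0.03, 0.04, 0.2])
        ]
        fwd = filter_variants(pd.DataFrame(rows))
        rev = filter_variants(pd.DataFrame(rows[::-1]))
        kept_fwd = set(fwd.loc[fwd["retained"], "sample_id"])
        kept_rev = set(rev.loc[rev["retained"], "sample_id"])
        assert kept_fwd == kept_rev


class TestActionabilityEngine:
    @pytest.mark.parametrize(
        "gene,change,exon,expect_rule",
        [
            ("KRAS", "p.G12C", 2, "KRAS_codons_12_13_61"),
            ("KRAS", "p.Q61H", 3, "KRAS_codons_12_13_61"),
            ("EGFR", "p.T790M", 20, "EGFR_T790M"),
            ("EGFR", "p.L858R", 21, "EGFR_codon_858"),
            ("EGFR", "p.E746_A750del", 19, "EGFR_exon19_deletion"),
            ("EGFR", "p.A767_V769dup", 20, "EGFR_exon20_insertion"),
            ("ERBB2", "p.Y772_A775dup", 20, "ERBB2_exon20_insertion"),
            ("BRAF", "p.V600E", 15, "BRAF_codon_600"),
            ("AKT1", "p.L52R", 2, "AKT1_L52R"),
        ],
    )
    def test_actionable_matches(self, rules, gene, change, exon, expect_rule):
        actionable, rule_id, tier = classify_actionable(gene, change, exon, rules)
        assert actionable
        assert rule_id == expect_rule
        assert tier in ("standard", "emerging")

    @pytest.mark.parametrize(
        "gene,change,exon",
        [
            ("BRAF", "p.D594N", 15),   # codon 594 outside the 600 rule
            ("BRAF", "p.G469A", 11),
            ("TP53", "p.R175H", 5),    # no TP53 rule exists
            ("EGFR", "p.S768I", 20),   # missense, not an exon-20 insertion
            ("KRAS", "p.A146T", 4),
            ("AKT1", "p.E17K", 2),     # rule names L52R only
        ],
    )
    def test_not_actionable(self, rules, gene, change, exon):
        actionable, rule_id, _ = classify_actionable(gene, change, exon, rules)
        assert not actionable and rule_id is None

    def test_t790m_flag_downgrades_resistance_call(self, rules):
        actionable, _, _ = classify_actionable(
            "EGFR", "p.T790M", 20, rules, t790m_actionable=False
        )
        assert not actionable

    def test_unknown_gene_in_rule_file_rejected(self, panel, tmp_path):
        bad = tmp_path / "rules.yaml"
        bad.write_text(
            "rules:\n"
            "  - {id: MYC_rule, gene: MYC, kind: codon_set, codons: [1]}\n"
        )
        with pytest.raises(RuleLoadError, match="MYC"):
            load_rules(bad, panel=panel)

    def test_overlapping_codon_sets_rejected(self, panel, tmp_path):
        bad = tmp_path / "rules.yaml"
        bad.write_text(
            "rules:\n"
            "  - {id: a, gene: KRAS, kind: codon_set, codons: [12, 13]}\n"
            "  - {id: b, gene: KRAS, kind: codon_set, codons: [13, 61]}\n"
        )
        with pytest.raises(RuleLoadError, match="overlap"):
            load_rules(bad, panel=panel)


class TestPanelMembership:
    @pytest.mark.parametrize(
        "gene,exon,expected",
        [
            ("EGFR", 19, True),
            ("EGFR", 25, False),
            ("MYC", 1, False),
            ("TP53", 7, True),
            ("AKT1", None, True),  # exon unknown, gene on panel
        ],
    )
    def test_membership(self, panel, gene, exon, expected):
        assert check_panel_membership(gene, exon, panel) is expected

    def test_panel_has_26_genes(self, panel):
        assert len(panel.genes) == 26
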