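"""Panel variant filtering and actionability classification.

Covers the DNA side of the diagnostic chain: parsing the mixed protein-level
variant notations seen in clinical reports, the amplicon-panel region model
(26 genes, selected complete exons), the variant-retention filters of a
dual-pool amplicon assay (variant seen in both library pools, coverage
>1000X, VAF at or above the 4% clinical limit of detection), and a rule
engine mapping retained variants to actionable therapy categories
(e.g. KRAS codons 12/13/61, EGFR exon 19 deletions, BRAF V600).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

# variant classes
MISSENSE = "missense"
NONSENSE = "nonsense"
INFRAME_DEL = "inframe_del"
INFRAME_INS = "inframe_ins"
FRAMESHIFT = "frameshift"
SPLICE = "splice"
SYNONYMOUS = "synonymous"
OTHER = "other"

DEFAULT_MIN_VAF = 0.04
DEFAULT_MIN_COVERAGE = 1000

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}


class RuleLoadError(ValueError):
    """Raised for malformed or inconsistent actionability rule files."""


@dataclass(frozen=True)
class ParsedProteinChange:
    """Outcome of parsing one protein-level notation.

    codon is the first affected codon (span start for indels); unparseable
    input yields (None, None, None, "other") rather than an exception.
    """

    codon: int | None
    ref_aa: str | None
    alt_aa: str | None
    variant_class: str


def _normalize_aa(token: str) -> str:
    """Collapse three-letter amino-acid codes to one-letter; pass through."""
    out = []
    i = 0
    while i < len(token):
        chunk = token[i : i + 3]
        if chunk in _AA3TO1:
            out.append(_AA3TO1[chunk])
            i += 3
        else:
            out.append(token[i])
            i += 1
    return "".join(out)


_RX_SUBST = re.compile(r"^([A-Z\*])(\d+)(=|[A-Z\*])$")
_RX_FS = re.compile(r"^([A-Z])(\d+)[A-Z]?fs(\*?\d*)$", re.IGNORECASE)
_RX_SPAN = re.compile(
    r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?(del|dup|ins|delins)([A-Z\*]*)$"
)
_RX_EXON_EVENT = re.compile(
    r"^exon\s*(\d+)\s*(del(?:etion)?|ins(?:ertion)?)$", re.IGNORECASE
)


def normalize_protein_change(notation: str) -> str:
    """Canonical form: no 'p.' prefix, one-letter codes, no whitespace."""
    text = notation.strip().strip("()")
    if text.lower().startswith("p."):
        text = text[2:]
    return _normalize_aa(text.replace(" ", ""))


def parse_protein_change(notation: str | None) -> ParsedProteinChange:
    """Parse an HGVS-like protein notation (total function; never raises).

    Accepted dialect: optional "p." prefix; one- or three-letter amino-acid
    codes; substitutions (L858R, Leu858Arg, R196*, L858=), frameshifts
    (P152fs, P152Lfs*18), spans (E746_A750del, A767_V769dup,
    D770_N771insSVD), and the bare exon-event alias (exon19del). Anything
    else classifies as "other" with codon None.
    """
    if notation is None or not str(notation).strip():
        return ParsedProteinChange(None, None, None, OTHER)
    text = str(notation).strip()
    m = _RX_EXON_EVENT.match(text)
    if m:
        kind = INFRAME_DEL if m.group(2).lower().startswith("del") else INFRAME_INS
        return ParsedProteinChange(None, None, None, kind)
    text = normalize_protein_change(text)

    m = _RX_SUBST.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "=" or alt == ref:
            return ParsedProteinChange(pos, ref, ref, SYNONYMOUS)
        if alt == "*":
            return ParsedProteinChange(pos, ref, alt, NONSENSE)
        return ParsedProteinChange(pos, ref, alt, MISSENSE)

    m = _RX_FS.match(text)
    if m:
        return ParsedProteinChange(int(m.group(2)), m.group(1), None, FRAMESHIFT)

    m = _RX_SPAN.match(text)
    if m:
        ref, pos, op = m.group(1), int(m.group(2)), m.group(5)
        if op == "del":
            return ParsedProteinChange(pos, ref, None, INFRAME_DEL)
        if op in ("dup", "ins"):
            return ParsedProteinChange(pos, ref, None, INFRAME_INS)
        # delins: composite event, reported at its span start
        return ParsedProteinChange(pos, ref, None, INFRAME_DEL)

    return ParsedProteinChange(None, None, None, OTHER)


# ---------------------------------------------------------------------------
# panel model
# ---------------------------------------------------------------------------


class PanelDefinition:
    """Gene -> interrogated exon numbers for the 26-gene amplicon panel."""

    def __init__(self, exons_by_gene: dict[str, set[int]]):
        bad = [g for g, ex in exons_by_gene.items() if not ex]
        if bad:
            raise ValueError(f"panel genes with empty exon sets: {bad}")
        self.exons_by_gene = {g: set(ex) for g, ex in exons_by_gene.items()}

    @property
    def genes(self) -> list[str]:
        return sorted(self.exons_by_gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self.exons_by_gene

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PanelDefinition":
        return cls(
            {
                str(row.gene): {int(e) for e in str(row.exons).split(",")}
                for row in df.itertuples(index=False)
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene": g, "exons": ",".join(str(e) for e in sorted(ex))}
                for g, ex in sorted(self.exons_by_gene.items())
            ]
        )


def default_panel() -> PanelDefinition:
    from .io import read_panel, _packaged_path

    return read_panel(_packaged_path("panel.tsv"))


def check_panel_membership(
    gene: str, exon: int | None, panel: PanelDefinition
) -> bool:
    """True iff the gene is on the panel and the exon (if given) is covered."""
    if gene not in panel:
        return False
    return exon is None or int(exon) in panel.exons_by_gene[gene]


# ---------------------------------------------------------------------------
# actionability rules
# ---------------------------------------------------------------------------

KIND_CODON_SET = "codon_set"
KIND_NAMED_CHANGE = "named_protein_change"
KIND_EXON_EVENT = "exon_event"

_EVENT_CLASS = {"deletion": INFRAME_DEL, "insertion": INFRAME_INS}


@dataclass(frozen=True)
class ActionabilityRule:
    rule_id: str
    gene: str
    kind: str
    tier: str
    codons: frozenset[int] = frozenset()
    change: str | None = None
    exon: int | None = None
    event: str | None = None

    def __post_init__(self) -> None:
        if self.kind == KIND_CODON_SET and not self.codons:
            raise RuleLoadError(f"rule {self.rule_id}: codon_set without codons")
        if self.kind == KIND_NAMED_CHANGE and not self.change:
            raise RuleLoadError(f"rule {self.rule_id}: named change missing")
        if self.kind == KIND_EXON_EVENT and (
            self.exon is None or self.event not in _EVENT_CLASS
        ):
            raise RuleLoadError(
                f"rule {self.rule_id}: exon_event needs exon and "
                f"event in {sorted(_EVENT_CLASS)}"
            )

    def matches(
        self,
        gene: str,
        protein_change: str | None,
        parsed: ParsedProteinChange,
        exon: int | None,
    ) -> bool:
        if gene != self.gene:
            return False
        if self.kind == KIND_CODON_SET:
            return (
                parsed.codon in self.codons
                and parsed.variant_class != SYNONYMOUS
            )
        if self.kind == KIND_NAMED_CHANGE:
            if protein_change is None:
                return False
            return normalize_protein_change(protein_change) == self.change
        # exon_event
        return (
            exon is not None
            and int(exon) == self.exon
            and parsed.variant_class == _EVENT_CLASS[self.event]
        )


def load_rules(
    path: str | Path | None = None, panel: PanelDefinition | None = None
) -> list[ActionabilityRule]:
    """Load rules from YAML (packaged default when path is None).

    Validates that rule genes exist on the panel and that codon sets within
    a gene are pairwise disjoint, so no variant can match two codon rules.
    """
    from .io import _packaged_path

    if path is None:
        path = _packaged_path("actionable_rules.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        rules.append(
            ActionabilityRule(
                rule_id=str(entry["id"]),
                gene=str(entry["gene"]),
                kind=str(entry["kind"]),
                tier=str(entry.get("tier", "emerging")),
                codons=frozenset(int(c) for c in entry.get("codons", [])),
                change=(
                    normalize_protein_change(str(entry["change"]))
                    if "change" in entry
                    else None
                ),
                exon=int(entry["exon"]) if "exon" in entry else None,
                event=str(entry["event"]) if "event" in entry else None,
            )
        )
    panel = panel or default_panel()
    unknown = sorted({r.gene for r in rules} - set(panel.genes))
    if unknown:
        raise RuleLoadError(f"rule file names genes absent from panel: {unknown}")
    by_gene: dict[str, set[int]] = {}
    for r in rules:
        if r.kind != KIND_CODON_SET:
            continue
        seen = by_gene.setdefault(r.gene, set())
        overlap = seen & r.codons
        if overlap:
            raise RuleLoadError(
                f"codon sets overlap within {r.gene}: {sorted(overlap)}"
            )
        seen |= r.codons
    return rules


def classify_actionable(
    gene: str,
    protein_change: str | None,
    exon: int | None,
    rules: list[ActionabilityRule],
    parsed: ParsedProteinChange | None = None,
    t790m_actionable: bool = True,
) -> tuple[bool, str | None, str | None]:
    """First-matching-rule classification: (actionable, rule id, tier).

    t790m_actionable=False drops the EGFR T790M resistance annotation from
    the actionable set (it is then reported but not counted).
    """
    parsed = parsed or parse_protein_change(protein_change)
    for rule in rules:
        if not t790m_actionable and rule.kind == KIND_NAMED_CHANGE and rule.change == "T790M":
            continue
        if rule.matches(gene, protein_change, parsed, exon):
            return True, rule.rule_id, rule.tier
    return False, None, None


# ---------------------------------------------------------------------------
# filtering + annotation
# ---------------------------------------------------------------------------

REJECT_POOL = "pool_discordance"
REJECT_COVERAGE = "low_coverage"
REJECT_VAF = "below_lod"

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "coding_change",
    "protein_change",
    "exon",
    "vaf",
    "detected_in_pool_a",
    "detected_in_pool_b",
    "coverage",
]


def filter_variants(
    variants: pd.DataFrame,
    min_vaf: float = DEFAULT_MIN_VAF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Apply the dual-pool / coverage / LOD retention filters.

    Retained iff detected in both library pools AND coverage strictly above
    min_coverage AND VAF >= min_vaf (the LOD is inclusive, the coverage rule
    strict). The first failing rule, in the order pool -> coverage -> VAF,
    is recorded as the rejection reason. Input order does not affect the
    outcome (row-wise, pure).
    """
    out = variants.copy()
    retained = []
    reasons = []
    for row in out.itertuples(index=False):
        if not (bool(row.detected_in_pool_a) and bool(row.detected_in_pool_b)):
            retained.append(False)
            reasons.append(REJECT_POOL)
        elif not int(row.coverage) > min_coverage:
            retained.append(False)
            reasons.append(REJECT_COVERAGE)
        elif not float(row.vaf) >= min_vaf:
            retained.append(False)
            reasons.append(REJECT_VAF)
        else:
            retained.append(True)
            reasons.append(None)
    out["retained"] = retained
    out["rejection_reason"] = reasons
    return out


def annotate_variants(
    variants: pd.DataFrame,
    rules: list[ActionabilityRule] | None = None,
    panel: PanelDefinition | None = None,
    min_vaf: float = DEFAULT_MIN_VAF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    t790m_actionable: bool = True,
) -> pd.DataFrame:
    """Full per-variant annotation: filters, parsing, panel check, rules.

    Returns the variant table with added columns: retained, rejection_reason,
    codon, variant_class, in_panel, actionable, matched_rule, tier.
    Actionability is only ever assigned to retained variants.
    """
    rules = rules if rules is not None else load_rules(panel=panel)
    panel = panel or default_panel()
    out = filter_variants(variants, min_vaf=min_vaf, min_coverage=min_coverage)
    codons, classes, in_panel, actionable, rule_ids, tiers = (
        [], [], [], [], [], [],
    )
    for row in out.itertuples(index=False):
        exon = None if pd.isna(row.exon) else int(row.exon)
        pc = None if pd.isna(row.protein_change) else str(row.protein_change)
        parsed = parse_protein_change(pc)
        codons.append(parsed.codon)
        classes.append(parsed.variant_class)
        in_panel.append(check_panel_membership(str(row.gene), exon, panel))
        if row.retained:
            act, rid, tier = classify_actionable(
                str(row.gene), pc, exon, rules,
                parsed=parsed, t790m_actionable=t790m_actionable,
            )
        else:
            act, rid, tier = False, None, None
        actionable.append(act)
        rule_ids.append(rid)
        tiers.append(tier)
    out["codon"] = pd.array(codons, dtype="Int64")
    out["variant_class"] = classes
    out["in_panel"] = in_panel
    out["actionable"] = actionable
    out["matched_rule"] = rule_ids
    out["tier"] = tiers
    return out
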