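"""Seeded synthetic-data generators for the diagnostic pipeline.

Three generators emulate the three input families the pipeline consumes:

* ``generate_variant_cohort`` — a prospective NSCLC testing cohort: sample
  metadata (histology, specimen type, tumor cell content) and a somatic
  variant table drawn from a curated per-gene catalogue of recurrent
  alterations (KRAS codon 12/13, EGFR exon 19 deletions / L858R / T790M,
  BRAF V600 and non-V600, TP53 missense, ...).
* ``generate_nanostring_batch`` — probe-count profiles for the RNA fusion
  assay, including fusion-positive, novel-fusion, jointly-overexpressed and
  degraded-RNA (QC-fail) profiles.
* ``generate_paired_calls`` — paired reference-vs-test method calls for
  assay validation, with out-of-scope discordance flags.

Every generator takes an explicit seed, is byte-reproducible for a fixed
seed + spec, and writes ground truth to a sidecar table kept separate from
the primary outputs so downstream recovery can be checked exactly.

Counts are drawn from a negative-binomial noise model around probe-role
specific means (a stand-in: the real count-noise law of the assay is not
modeled from data). Fusion-positive means sit well clear (>=5x) of the
default caller thresholds so that classification on synthetic batches is
a test of logic, not of borderline calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import NO_MUTATION, PAIRED_CALL_COLUMNS
from .fusion import (
    ASSAY_ROLES,
    CountProfile,
    ProbeSet,
    ROLE_FIVE_PRIME,
    ROLE_FUSION_SPECIFIC,
    ROLE_HOUSEKEEPING,
    ROLE_NEG_CONTROL,
    ROLE_POS_CONTROL,
    ROLE_THREE_PRIME,
    STATUS_KNOWN,
    STATUS_NEGATIVE,
    STATUS_NOVEL,
    STATUS_QC_FAIL,
    default_probe_set,
)
from .variants import VARIANT_COLUMNS


class SpecError(ValueError):
    """Raised for invalid generator specifications."""


# ---------------------------------------------------------------------------
# variant catalogue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogueVariant:
    gene: str
    protein_change: str
    coding_change: str
    exon: int
    actionable: bool  # hand-curated truth, independent of the rule engine


#: Recurrent alterations per gene; the ``actionable`` flag is curated by hand
#: from the same therapy-rule definitions the annotation engine encodes, and
#: serves as the generator-side ground truth.
VARIANT_CATALOGUE: dict[str, list[CatalogueVariant]] = {
    "KRAS": [
        CatalogueVariant("KRAS", "p.G12C", "c.34G>T", 2, True),
        CatalogueVariant("KRAS", "p.G12V", "c.35G>T", 2, True),
        CatalogueVariant("KRAS", "p.G12D", "c.35G>A", 2, True),
        CatalogueVariant("KRAS", "p.G13C", "c.37G>T", 2, True),
        CatalogueVariant("KRAS", "p.Q61H", "c.183A>C", 3, True),
        CatalogueVariant("KRAS", "p.A146T", "c.436G>A", 4, False),
    ],
    "EGFR": [
        CatalogueVariant("EGFR", "p.E746_A750del", "c.2235_2249del", 19, True),
        CatalogueVariant("EGFR", "p.L858R", "c.2573T>G", 21, True),
        CatalogueVariant("EGFR", "p.T790M", "c.2369C>T", 20, True),
        CatalogueVariant("EGFR", "p.G719A", "c.2156G>C", 18, True),
        CatalogueVariant("EGFR", "p.L861Q", "c.2582T>A", 21, True),
        CatalogueVariant("EGFR", "p.A767_V769dup", "c.2300_2308dup", 20, True),
        CatalogueVariant("EGFR", "p.S768I", "c.2303G>T", 20, False),
    ],
    "BRAF": [
        CatalogueVariant("BRAF", "p.V600E", "c.1799T>A", 15, True),
        CatalogueVariant("BRAF", "p.G466V", "c.1397G>T", 11, False),
        CatalogueVariant("BRAF", "p.G469A", "c.1406G>C", 11, False),
        CatalogueVariant("BRAF", "p.D594N", "c.1780G>A", 15, False),
        CatalogueVariant("BRAF", "p.K601E", "c.1801A>G", 15, False),
    ],
    "TP53": [
        CatalogueVariant("TP53", "p.R175H", "c.524G>A", 5, False),
        CatalogueVariant("TP53", "p.R248Q", "c.743G>A", 7, False),
        CatalogueVariant("TP53", "p.R273H", "c.818G>A", 8, False),
        CatalogueVariant("TP53", "p.G245S", "c.733G>A", 7, False),
        CatalogueVariant("TP53", "p.R196*", "c.586C>T", 6, False),
        CatalogueVariant("TP53", "p.P152fs", "c.454delC", 5, False),
    ],
    "PIK3CA": [
        CatalogueVariant("PIK3CA", "p.E542K", "c.1624G>A", 9, True),
        CatalogueVariant("PIK3CA", "p.E545K", "c.1633G>A", 9, True),
        CatalogueVariant("PIK3CA", "p.H1047R", "c.3140A>G", 20, True),
        CatalogueVariant("PIK3CA", "p.C420R", "c.1258T>C", 7, False),
        CatalogueVariant("PIK3CA", "p.R88Q", "c.263G>A", 1, False),
    ],
    "NRAS": [
        CatalogueVariant("NRAS", "p.Q61K", "c.181C>A", 3, True),
        CatalogueVariant("NRAS", "p.G12D", "c.35G>A", 2, True),
    ],
    "ERBB2": [
        CatalogueVariant("ERBB2", "p.Y772_A775dup", "c.2313_2324dup", 20, True),
    ],
    "MAP2K1": [
        CatalogueVariant("MAP2K1", "p.K57N", "c.171G>T", 2, True),
        CatalogueVariant("MAP2K1", "p.Q56P", "c.167A>C", 2, True),
    ],
    "AKT1": [
        CatalogueVariant("AKT1", "p.L52R", "c.155T>G", 2, True),
        CatalogueVariant("AKT1", "p.E17K", "c.49G>A", 2, False),
    ],
    "STK11": [
        CatalogueVariant("STK11", "p.F354L", "c.1062C>G", 8, False),
        CatalogueVariant("STK11", "p.D194N", "c.580G>A", 4, False),
        CatalogueVariant("STK11", "p.Q37*", "c.109C>T", 1, False),
    ],
    "PTEN": [
        CatalogueVariant("PTEN", "p.R130G", "c.388C>G", 5, False),
        CatalogueVariant("PTEN", "p.R233*", "c.697C>T", 7, False),
    ],
    "MET": [
        CatalogueVariant("MET", "p.T1010I", "c.3029C>T", 13, False),
    ],
    "CTNNB1": [
        CatalogueVariant("CTNNB1", "p.S45F", "c.134C>T", 2, False),
    ],
}

DEFAULT_HISTOLOGY_MIX = {
    "adenocarcinoma": 348 / 533,
    "SqCC": 90 / 533,
    "NSCLC-NOS": 80 / 533,
    "other": 15 / 533,
}

DEFAULT_MUTATION_RATES = {
    "TP53": 0.45,
    "KRAS": 0.30,
    "EGFR": 0.14,
    "BRAF": 0.07,
    "STK11": 0.08,
    "PIK3CA": 0.05,
    "MET": 0.03,
    "PTEN": 0.03,
    "CTNNB1": 0.02,
    "NRAS": 0.02,
    "ERBB2": 0.02,
    "MAP2K1": 0.01,
    "AKT1": 0.005,
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic prospective testing cohort."""

    n_samples: int
    histology_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGY_MIX)
    )
    per_gene_mutation_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    vaf_range: tuple[float, float] = (0.05, 0.85)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise SpecError("n_samples must be a positive integer")
        total = sum(self.histology_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"histology proportions sum to {total}, not 1")
        for gene, rate in self.per_gene_mutation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"mutation rate for {gene} outside [0,1]: {rate}")
            if gene not in VARIANT_CATALOGUE:
                raise SpecError(f"no catalogue entries for gene {gene}")
        lo, hi = self.vaf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise SpecError(f"vaf_range must lie in (0,1]: {self.vaf_range}")


def generate_variant_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (samples, variants, truth) tables for one cohort.

    Each sample gets a histology label; per gene, a Bernoulli draw at the
    spec's rate decides mutation presence and a catalogue entry supplies the
    notation. The truth sidecar records which samples carry >=1 actionable
    mutation according to the catalogue's hand-curated flags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    histologies = list(spec.histology_mix)
    probs = np.array([spec.histology_mix[h] for h in histologies])
    probs = probs / probs.sum()

    sample_rows, variant_rows, truth_rows = [], [], []
    width = max(4, len(str(spec.n_samples)))
    genes = sorted(spec.per_gene_mutation_rates)
    for i in range(spec.n_samples):
        sid = f"S{i + 1:0{width}d}"
        hist = str(rng.choice(histologies, p=probs))
        specimen = "FFPE" if rng.random() < 0.745 else "cytology"
        tcc = int(rng.integers(10, 96))
        sample_rows.append(
            {
                "sample_id": sid,
                "histology": hist,
                "specimen_type": specimen,
                "tumor_cell_content": tcc,
            }
        )
        actionable_genes = []
        for gene in genes:
            if rng.random() >= spec.per_gene_mutation_rates[gene]:
                continue
            entry = VARIANT_CATALOGUE[gene][
                int(rng.integers(len(VARIANT_CATALOGUE[gene])))
            ]
            vaf = float(rng.uniform(*spec.vaf_range))
            variant_rows.append(
                {
                    "sample_id": sid,
                    "gene": gene,
                    "coding_change": entry.coding_change,
                    "protein_change": entry.protein_change,
                    "exon": entry.exon,
                    "vaf": round(vaf, 4),
                    "detected_in_pool_a": True,
                    "detected_in_pool_b": True,
                    "coverage": int(rng.integers(1200, 4001)),
                }
            )
            if entry.actionable:
                actionable_genes.append(gene)
        truth_rows.append(
            {
                "sample_id": sid,
                "actionable": bool(actionable_genes),
                "actionable_genes": ";".join(actionable_genes),
            }
        )
    samples = pd.DataFrame(sample_rows)
    variants = pd.DataFrame(variant_rows, columns=VARIANT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return samples, variants, truth


# ---------------------------------------------------------------------------
# NanoString-style count batches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionEvent:
    """One planted fusion: fusion_id None means a novel (unprobed) fusion."""

    gene: str
    fusion_id: str | None
    index: int


@dataclass
class NanoStringBatchSpec:
    """Parameters of a synthetic hybridization batch.

    ``baseline_count_scale`` multiplies the endogenous-probe means (RNA
    input); ``noise_dispersion`` is the negative-binomial overdispersion
    alpha in Var = mu + alpha*mu^2. ``n_adenocarcinoma``, when set, fixes
    the number of adenocarcinomas among QC-passing profiles (fusion events
    are always placed in adenocarcinomas, as in lung practice).
    ``overexpressed`` plants joint 3'+5' elevation without rearrangement.
    """

    n_profiles: int
    events: list[FusionEvent] = field(default_factory=list)
    n_degraded: int = 0
    baseline_count_scale: float = 1.0
    noise_dispersion: float = 0.02
    seed: int = 0
    n_adenocarcinoma: int | None = None
    overexpressed: list[tuple[str, int]] = field(default_factory=list)
    sample_ids: list[str] | None = None
    batch_id: str = "batch0"

    def validate(self, probe_set: ProbeSet) -> None:
        if self.n_profiles <= 0:
            raise SpecError("n_profiles must be positive")
        if not 0 <= self.n_degraded <= self.n_profiles:
            raise SpecError("n_degraded must be in [0, n_profiles]")
        if self.baseline_count_scale <= 0 or self.noise_dispersion <= 0:
            raise SpecError("scale and dispersion must be positive")
        idx = [e.index for e in self.events]
        if len(set(idx)) != len(idx):
            raise SpecError("event profile indices must be distinct")
        if any(i < 0 or i >= self.n_profiles for i in idx):
            raise SpecError("event index out of range")
        for e in self.events:
            probe_set.require_gene(e.gene)
            if e.fusion_id is not None:
                known = {p.fusion_id for p in probe_set.fusion_probes(e.gene)}
                if e.fusion_id not in known:
                    raise SpecError(
                        f"fusion id {e.fusion_id!r} not in probe set for {e.gene}"
                    )
        for gene, i in self.overexpressed:
            probe_set.require_gene(gene)
            if not 0 <= i < self.n_profiles:
                raise SpecError("overexpressed index out of range")
        if self.sample_ids is not None and len(self.sample_ids) != self.n_profiles:
            raise SpecError("sample_ids length must equal n_profiles")
        if (
            self.n_adenocarcinoma is not None
            and self.n_adenocarcinoma > self.n_profiles - self.n_degraded
        ):
            raise SpecError("n_adenocarcinoma exceeds QC-passing profile count")


# probe-role mean raw counts for a sound hybridization
MEAN_NEG = 12.0
MEAN_HK = 2500.0
MEAN_FLANK = 150.0
MEAN_FUSION_BASELINE = 5.0
MEAN_FUSION_POSITIVE = 1200.0
POS_COUNTS_PER_FM = 200.0
FUSION_FOLD = 12.0          # 3' elevation of a rearranged allele
OVEREXPRESSION_FOLD = 12.0  # joint 3'+5' elevation without rearrangement
DEGRADATION_FACTOR = 0.01   # endogenous signal left in a failed hybridization


@dataclass
class NanoStringBatch:
    """Generated batch: profiles plus metadata and the truth sidecar."""

    profiles: list[CountProfile]
    probe_set: ProbeSet
    samples: pd.DataFrame   # sample_id, histology
    truth: pd.DataFrame     # sample_id, gene, status, fusion_id, raw_ratio_3p5p
    sound_hk_level: float   # expected housekeeping level of a sound profile
    spec: NanoStringBatchSpec

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float) -> int:
    """Negative-binomial count with mean mu and Var = mu + alpha*mu^2."""
    if mu <= 0:
        return 0
    n = 1.0 / alpha
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


def generate_nanostring_batch(
    spec: NanoStringBatchSpec, probe_set: ProbeSet | None = None
) -> NanoStringBatch:
    """Generate one hybridization batch per the spec.

    Fusion-positive profiles get ~12x elevated 3'-flank counts (plus an
    elevated junction probe unless the event is novel); degraded profiles
    have all endogenous signal suppressed 100x so the housekeeping QC ratio
    clears the failure threshold; overexpressed profiles elevate 3' and 5'
    jointly, leaving the ratio balanced. Spike-in controls are unaffected by
    degradation.
    """
    probe_set = probe_set or default_probe_set()
    spec.validate(probe_set)
    rng = np.random.default_rng(spec.seed)
    alpha = spec.noise_dispersion

    event_by_index = {e.index: e for e in spec.events}
    over_by_index: dict[int, set[str]] = {}
    for gene, i in spec.overexpressed:
        over_by_index.setdefault(i, set()).add(gene)

    # degraded profiles drawn among indices hosting no planted signal
    reserved = set(event_by_index) | set(over_by_index)
    eligible = [i for i in range(spec.n_profiles) if i not in reserved]
    if spec.n_degraded > len(eligible):
        raise SpecError("not enough event-free profiles to degrade")
    degraded = set(
        rng.choice(eligible, size=spec.n_degraded, replace=False).tolist()
        if spec.n_degraded
        else []
    )

    # histology: events sit in adenocarcinomas; optionally fix the AC count
    # among QC-passing profiles
    histology = {}
    passing = [i for i in range(spec.n_profiles) if i not in degraded]
    ac = set(event_by_index)
    if spec.n_adenocarcinoma is not None:
        extra_needed = spec.n_adenocarcinoma - len(ac)
        if extra_needed < 0:
            raise SpecError("n_adenocarcinoma smaller than event count")
        pool = [i for i in passing if i not in ac]
        ac |= set(rng.choice(pool, size=extra_needed, replace=False).tolist())
    others = ["SqCC", "NSCLC-NOS", "other"]
    for i in range(spec.n_profiles):
        if i in ac:
            histology[i] = "adenocarcinoma"
        elif spec.n_adenocarcinoma is None and rng.random() < 0.5:
            histology[i] = "adenocarcinoma"
        else:
            histology[i] = others[int(rng.integers(3))]

    width = max(3, len(str(spec.n_profiles)))
    ids = spec.sample_ids or [
        f"NS{i + 1:0{width}d}" for i in range(spec.n_profiles)
    ]

    profiles: list[CountProfile] = []
    truth_rows = []
    sample_rows = []
    scale = spec.baseline_count_scale
    for i in range(spec.n_profiles):
        event = event_by_index.get(i)
        over = over_by_index.get(i, set())
        endo = DEGRADATION_FACTOR if i in degraded else 1.0
        counts: dict[str, float] = {}
        for probe in probe_set.probes.values():
            if probe.role == ROLE_NEG_CONTROL:
                mu = MEAN_NEG
            elif probe.role == ROLE_POS_CONTROL:
                mu = probe.nominal_amount * POS_COUNTS_PER_FM
            elif probe.role == ROLE_HOUSEKEEPING:
                mu = MEAN_HK * scale * endo
            elif probe.role == ROLE_FIVE_PRIME:
                fold = OVEREXPRESSION_FOLD if probe.gene in over else 1.0
                mu = MEAN_FLANK * fold * scale * endo
            elif probe.role == ROLE_THREE_PRIME:
                fold = 1.0
                if event is not None and probe.gene == event.gene:
                    fold = FUSION_FOLD
                elif probe.gene in over:
                    fold = OVEREXPRESSION_FOLD
                mu = MEAN_FLANK * fold * scale * endo
            else:  # fusion_specific
                mu = MEAN_FUSION_BASELINE
                if (
                    event is not None
                    and event.fusion_id is not None
                    and probe.fusion_id == event.fusion_id
                ):
                    mu = MEAN_FUSION_POSITIVE
                mu *= scale * endo
            counts[probe.probe_id] = _nb_draw(rng, mu, alpha)
        profile = CountProfile(
            sample_id=ids[i], counts=counts, batch_id=spec.batch_id
        )
        profiles.append(profile)
        sample_rows.append({"sample_id": ids[i], "histology": histology[i]})
        for gene in probe_set.genes:
            if i in degraded:
                status, fid = STATUS_QC_FAIL, None
            elif event is not None and event.gene == gene:
                status = STATUS_KNOWN if event.fusion_id else STATUS_NOVEL
                fid = event.fusion_id
            else:
                status, fid = STATUS_NEGATIVE, None
            three = profile.values(probe_set.probe_ids(ROLE_THREE_PRIME, gene))
            five = profile.values(probe_set.probe_ids(ROLE_FIVE_PRIME, gene))
            raw_ratio = three.mean() / five.mean() if five.mean() > 0 else np.nan
            truth_rows.append(
                {
                    "sample_id": ids[i],
                    "gene": gene,
                    "status": status,
                    "fusion_id": fid,
                    "raw_ratio_3p5p": raw_ratio,
                }
            )

    return NanoStringBatch(
        profiles=profiles,
        probe_set=probe_set,
        samples=pd.DataFrame(sample_rows),
        truth=pd.DataFrame(truth_rows),
        sound_hk_level=MEAN_HK * scale,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# paired validation calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedGroup:
    """Call counts for one (cohort, gene) cell of a validation table."""

    cohort: str
    gene: str
    mut_concordant: int = 0
    mut_discordant: int = 0
    nomut_concordant: int = 0
    nomut_discordant: int = 0
    n_out_of_scope: int = 0  # taken from the nomut_discordant rows

    def validate(self) -> None:
        for name in (
            "mut_concordant",
            "mut_discordant",
            "nomut_concordant",
            "nomut_discordant",
            "n_out_of_scope",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.n_out_of_scope > self.nomut_discordant:
            raise SpecError(
                "out-of-scope rows must be test-positive discordants "
                "(n_out_of_scope <= nomut_discordant)"
            )


@dataclass
class PairedCallSpec:
    groups: list[PairedGroup]
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            return
        for g in self.groups:
            g.validate()


def _catalogue_coding(rng: np.random.Generator, gene: str) -> str:
    entries = VARIANT_CATALOGUE.get(gene)
    if not entries:
        return "c.1A>G"
    return entries[int(rng.integers(len(entries)))].coding_change


def generate_paired_calls(spec: PairedCallSpec) -> pd.DataFrame:
    """Expand a PairedCallSpec into one row per paired call.

    Row counts match the spec exactly; discordant mutation rows pair a
    reference variant with a test no-mutation call, discordant no-mutation
    rows pair a reference no-mutation with a test variant (flagged
    out-of-scope for the first ``n_out_of_scope`` of them).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"V{counter:04d}"

    for g in spec.groups:
        for _ in range(g.mut_concordant):
            v = _catalogue_coding(rng, g.gene)
            rows.append((next_id(), g.cohort, g.gene, v, v, v, v, True))
        for _ in range(g.mut_discordant):
            v = _catalogue_coding(rng, g.gene)
            rows.append(
                (next_id(), g.cohort, g.gene, v, v, NO_MUTATION, None, True)
            )
        for _ in range(g.nomut_concordant):
            rows.append(
                (
                    next_id(), g.cohort, g.gene,
                    NO_MUTATION, None, NO_MUTATION, None, True,
                )
            )
        for k in range(g.nomut_discordant):
            v = _catalogue_coding(rng, g.gene)
            in_scope = k >= g.n_out_of_scope
            rows.append(
                (next_id(), g.cohort, g.gene, NO_MUTATION, None, v, v, in_scope)
            )
    df = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "cohort": cohort,
                "gene": gene,
                "reference_call": rc if rc == NO_MUTATION else "mutation",
                "reference_variant": rv,
                "test_call": tc if tc == NO_MUTATION else "mutation",
                "test_variant": tv,
                "in_scope": in_scope,
            }
            for sid, cohort, gene, rc, rv, tc, tv, in_scope in rows
        ],
        columns=PAIRED_CALL_COLUMNS[:1] + PAIRED_CALL_COLUMNS[1:],
    )
    return df
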