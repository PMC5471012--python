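"""RNA count-based ALK/RET/ROS1 gene-fusion calling.

Implements the expression-imbalance fusion caller used with multiplexed
hybridization count assays (NanoString nCounter Elements style): background
correction against negative-control probes, scaling on the positive-control
titration series, a housekeeping-collapse QC rule, the 3'/5' imbalance ratio
around the tyrosine-kinase exons, junction-specific ("toehold") probe signal,
and the quadrant classification that separates known fusions, novel fusions
and negative samples.

The biological rationale: a rearrangement that places the kinase domain of
ALK, RET or ROS1 under a foreign promoter elevates transcription of exons 3'
of the breakpoint relative to the 5' exons, so the 3'/5' ratio flags any
fusion; a junction-spanning probe additionally identifies *which* fusion when
the breakpoint is in the probe set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FUSION_GENES = ("ALK", "RET", "ROS1")

ROLE_FIVE_PRIME = "five_prime"
ROLE_THREE_PRIME = "three_prime"
ROLE_FUSION_SPECIFIC = "fusion_specific"
ROLE_HOUSEKEEPING = "housekeeping"
ROLE_POS_CONTROL = "pos_control"
ROLE_NEG_CONTROL = "neg_control"

PROBE_ROLES = (
    ROLE_FIVE_PRIME,
    ROLE_THREE_PRIME,
    ROLE_FUSION_SPECIFIC,
    ROLE_HOUSEKEEPING,
    ROLE_POS_CONTROL,
    ROLE_NEG_CONTROL,
)

#: roles whose counts pass through background correction and scaling
ASSAY_ROLES = (ROLE_FIVE_PRIME, ROLE_THREE_PRIME, ROLE_FUSION_SPECIFIC)

STATUS_KNOWN = "KNOWN_FUSION"
STATUS_NOVEL = "NOVEL_FUSION"
STATUS_NEGATIVE = "NEGATIVE"
STATUS_QC_FAIL = "QC_FAIL"


class FusionCallerError(ValueError):
    """Raised on malformed probe sets, profiles or degenerate controls."""


@dataclass(frozen=True)
class Probe:
    probe_id: str
    role: str
    gene: str | None = None
    fusion_id: str | None = None
    nominal_amount: float | None = None

    def __post_init__(self) -> None:
        if self.role not in PROBE_ROLES:
            raise FusionCallerError(
                f"unknown probe role {self.role!r} for probe {self.probe_id!r}"
            )
        if self.role == ROLE_FUSION_SPECIFIC and not self.fusion_id:
            raise FusionCallerError(
                f"fusion-specific probe {self.probe_id!r} lacks a fusion id"
            )


class ProbeSet:
    """Annotated probe collection governing one assay design.

    Validates the structural requirements of the dual 3'/5' + junction-probe
    design: each fusion gene needs at least one probe flanking each side of
    the kinase exons, probe ids are unique across roles, and every
    fusion-specific probe belongs to exactly one gene.
    """

    def __init__(self, probes: Iterable[Probe]):
        probes = list(probes)
        ids = [p.probe_id for p in probes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FusionCallerError(f"duplicate probe ids: {dupes}")
        self.probes: dict[str, Probe] = {p.probe_id: p for p in probes}
        self._by_role: dict[str, list[Probe]] = {r: [] for r in PROBE_ROLES}
        for p in probes:
            self._by_role[p.role].append(p)
        for gene in self.genes:
            if not self.probe_ids(ROLE_FIVE_PRIME, gene) or not self.probe_ids(
                ROLE_THREE_PRIME, gene
            ):
                raise FusionCallerError(
                    f"gene {gene} needs >=1 probe on each side of the kinase exons"
                )

    @property
    def genes(self) -> list[str]:
        seen = sorted(
            {p.gene for p in self.probes.values() if p.gene is not None}
        )
        return seen

    def probe_ids(self, role: str, gene: str | None = None) -> list[str]:
        return [
            p.probe_id
            for p in self._by_role[role]
            if gene is None or p.gene == gene
        ]

    def fusion_probes(self, gene: str) -> list[Probe]:
        return [p for p in self._by_role[ROLE_FUSION_SPECIFIC] if p.gene == gene]

    @property
    def all_probe_ids(self) -> list[str]:
        return list(self.probes)

    def require_gene(self, gene: str) -> None:
        if gene not in self.genes:
            raise FusionCallerError(
                f"gene {gene!r} absent from probe set (have {self.genes})"
            )

    # -- IO ---------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeSet":
        probes = []
        for row in df.itertuples(index=False):
            gene = None if pd.isna(row.gene) else str(row.gene)
            fusion_id = (
                None if pd.isna(row.fusion_id) else str(row.fusion_id)
            )
            nominal = (
                None
                if pd.isna(row.nominal_amount)
                else float(row.nominal_amount)
            )
            probes.append(
                Probe(
                    probe_id=str(row.probe_id),
                    role=str(row.role),
                    gene=gene,
                    fusion_id=fusion_id,
                    nominal_amount=nominal,
                )
            )
        return cls(probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "probe_id": p.probe_id,
                    "gene": p.gene,
                    "role": p.role,
                    "fusion_id": p.fusion_id,
                    "nominal_amount": p.nominal_amount,
                }
                for p in self.probes.values()
            ]
        )


def default_probe_set() -> ProbeSet:
    """The probe design shipped with the package (ALK, RET, ROS1)."""
    from .io import read_probes, _packaged_path

    return read_probes(_packaged_path("probes.tsv"))


@dataclass
class CountProfile:
    """One sample x one hybridization: probe id -> count.

    Raw counts are non-negative integers; background-corrected or scaled
    profiles hold floats.
    """

    sample_id: str
    counts: dict[str, float]
    batch_id: str = "batch0"

    def validate_against(self, probe_set: ProbeSet) -> None:
        missing = [p for p in probe_set.all_probe_ids if p not in self.counts]
        if missing:
            raise FusionCallerError(
                f"profile {self.sample_id}: missing counts for probes {missing}"
            )
        bad = {p: c for p, c in self.counts.items() if c < 0}
        if bad:
            raise FusionCallerError(
                f"profile {self.sample_id}: negative counts {bad}"
            )

    def values(self, probe_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.counts[p] for p in probe_ids], dtype=float)


@dataclass
class CallerThresholds:
    """Tunable cut-offs of the caller.

    ratio_threshold and specific_signal_threshold position the dotted lines
    of the quadrant plot; they are lab-calibration parameters, not constants
    of the method. qc_ratio_threshold is the housekeeping-collapse rule
    (fail iff H/Hi strictly exceeds it; default 8). hk_reference_level, when
    set, fixes the reference housekeeping level H; otherwise batch-level
    calling derives H from the batch. Per-gene overrides for the two calling
    thresholds are allowed via the *_by_gene maps.
    """

    ratio_threshold: float = 2.0
    specific_signal_threshold: float = 50.0
    qc_ratio_threshold: float = 8.0
    background_sd_multiplier: float = 2.0
    pseudocount: float = 1.0
    reference_factor: float = 800.0
    hk_reference_level: float | None = None
    ratio_threshold_by_gene: dict[str, float] = field(default_factory=dict)
    specific_signal_threshold_by_gene: dict[str, float] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name in (
            "ratio_threshold",
            "specific_signal_threshold",
            "qc_ratio_threshold",
            "pseudocount",
            "reference_factor",
        ):
            if getattr(self, name) <= 0:
                raise FusionCallerError(f"{name} must be strictly positive")
        if self.background_sd_multiplier < 0:
            raise FusionCallerError("background_sd_multiplier must be >= 0")

    def ratio_cut(self, gene: str) -> float:
        return self.ratio_threshold_by_gene.get(gene, self.ratio_threshold)

    def signal_cut(self, gene: str) -> float:
        return self.specific_signal_threshold_by_gene.get(
            gene, self.specific_signal_threshold
        )


@dataclass
class FusionCall:
    """Per-sample, per-gene classification with its evidence statistics."""

    sample_id: str
    gene: str
    status: str
    best_fusion_id: str | None
    ratio_3p5p: float
    max_specific_signal: float
    qc_ratio: float
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.status == STATUS_KNOWN and self.best_fusion_id is None:
            raise FusionCallerError("KNOWN_FUSION requires a best_fusion_id")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def background_correct(
    profile: CountProfile,
    probe_set: ProbeSet,
    thresholds: CallerThresholds,
) -> CountProfile:
    """Subtract the negative-control background from assay probes.

    Background = mean(negative controls) + multiplier * SD(negative controls),
    floored at zero. Control and housekeeping counts are preserved so that QC
    and scaling can still see them.
    """
    profile.validate_against(probe_set)
    neg_ids = probe_set.probe_ids(ROLE_NEG_CONTROL)
    if not neg_ids:
        raise FusionCallerError(
            "no negative-control probes in probe set; cannot estimate background"
        )
    neg = profile.values(neg_ids)
    background = neg.mean() + thresholds.background_sd_multiplier * neg.std(
        ddof=1 if len(neg) > 1 else 0
    )
    assay_ids = {
        pid for role in ASSAY_ROLES for pid in probe_set.probe_ids(role)
    }
    corrected = {
        pid: max(0.0, c - background) if pid in assay_ids else float(c)
        for pid, c in profile.counts.items()
    }
    return replace(profile, counts=corrected)


def scale_by_positive_controls(
    profile: CountProfile,
    probe_set: ProbeSet,
    reference_factor: float | None = None,
    thresholds: CallerThresholds | None = None,
) -> CountProfile:
    """Scale assay-probe counts onto a common positive-control scale.

    Multiplies by reference_factor / geometric-mean(positive controls), which
    makes downstream statistics invariant to global multiplicative factors on
    the raw counts (lane-to-lane hybridization efficiency).
    """
    if reference_factor is None:
        reference_factor = (
            thresholds.reference_factor if thresholds else 800.0
        )
    if reference_factor <= 0:
        raise FusionCallerError("reference_factor must be strictly positive")
    pos_ids = probe_set.probe_ids(ROLE_POS_CONTROL)
    if not pos_ids:
        raise FusionCallerError("no positive-control probes in probe set")
    pos = profile.values(pos_ids)
    if np.any(pos <= 0):
        zeroed = [p for p, c in zip(pos_ids, pos) if c <= 0]
        raise FusionCallerError(
            f"profile {profile.sample_id}: degenerate hybridization, "
            f"positive controls at zero: {zeroed}"
        )
    geo = float(np.exp(np.mean(np.log(pos))))
    factor = reference_factor / geo
    assay_ids = {
        pid for role in ASSAY_ROLES for pid in probe_set.probe_ids(role)
    }
    scaled = {
        pid: c * factor if pid in assay_ids else float(c)
        for pid, c in profile.counts.items()
    }
    return replace(profile, counts=scaled)


def normalize_profile(
    profile: CountProfile, probe_set: ProbeSet, thresholds: CallerThresholds
) -> CountProfile:
    """background_correct then scale_by_positive_controls."""
    corrected = background_correct(profile, probe_set, thresholds)
    return scale_by_positive_controls(
        corrected, probe_set, thresholds.reference_factor
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def housekeeping_level(profile: CountProfile, probe_set: ProbeSet) -> float:
    """Geometric mean of the housekeeping probe counts (+1 to tolerate zeros)."""
    hk_ids = probe_set.probe_ids(ROLE_HOUSEKEEPING)
    if not hk_ids:
        raise FusionCallerError("no housekeeping probes in probe set")
    hk = profile.values(hk_ids)
    return float(np.exp(np.mean(np.log(hk + 1.0))))


def qc_check(
    profile: CountProfile,
    probe_set: ProbeSet,
    thresholds: CallerThresholds,
    reference_level: float | None = None,
) -> tuple[bool, float]:
    """Housekeeping-collapse QC on the *raw* profile.

    Computes H/Hi = reference housekeeping level over this profile's
    housekeeping level (geometric means); a degraded-RNA hybridization has
    collapsed housekeeping signal, hence a large ratio. Returns
    (passed, qc_ratio); fail iff qc_ratio strictly exceeds the threshold
    (default 8, i.e. a ratio of exactly 8 still passes).

    The reference H resolves: explicit argument > thresholds.hk_reference_level.
    Batch-level calling (`call_batch`) derives it from the batch when neither
    is set.
    """
    hi = housekeeping_level(profile, probe_set)
    if reference_level is None:
        reference_level = thresholds.hk_reference_level
    if reference_level is None:
        raise FusionCallerError(
            "no housekeeping reference level: pass reference_level or set "
            "thresholds.hk_reference_level (call_batch derives one per batch)"
        )
    qc_ratio = reference_level / hi
    return qc_ratio <= thresholds.qc_ratio_threshold, qc_ratio


def batch_housekeeping_reference(
    profiles: Sequence[CountProfile], probe_set: ProbeSet
) -> float:
    """Batch reference H: geometric mean over profiles of per-profile levels."""
    if not profiles:
        raise FusionCallerError("empty batch")
    levels = [housekeeping_level(p, probe_set) for p in profiles]
    return float(np.exp(np.mean(np.log(levels))))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def compute_ratio_3p5p(
    profile: CountProfile,
    probe_set: ProbeSet,
    gene: str,
    pseudocount: float = 1.0,
) -> float:
    """3'/5' imbalance ratio for one gene on a corrected+scaled profile.

    (mean 3' counts + pseudocount) / (mean 5' counts + pseudocount); the
    pseudocount keeps the ratio finite when the 5' signal is fully
    background-subtracted.
    """
    probe_set.require_gene(gene)
    three = profile.values(probe_set.probe_ids(ROLE_THREE_PRIME, gene))
    five = profile.values(probe_set.probe_ids(ROLE_FIVE_PRIME, gene))
    return (three.mean() + pseudocount) / (five.mean() + pseudocount)


def compute_fusion_signal(
    profile: CountProfile, probe_set: ProbeSet, gene: str
) -> tuple[float, str | None]:
    """Maximum junction-probe signal for a gene and the fusion id attaining it.

    Ties break to the lexicographically smaller fusion id. A gene with no
    fusion-specific probes yields (0.0, None).
    """
    probe_set.require_gene(gene)
    probes = probe_set.fusion_probes(gene)
    if not probes:
        return 0.0, None
    best = min(
        probes,
        key=lambda p: (-profile.counts[p.probe_id], p.fusion_id),
    )
    return float(profile.counts[best.probe_id]), best.fusion_id


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_quadrant(
    ratio: float, signal: float, ratio_cut: float, signal_cut: float
) -> tuple[str, str | None]:
    """Map the (signal, ratio) point to a status per the quadrant semantics.

    upper right (both high) -> KNOWN_FUSION; lower right (ratio high only)
    -> NOVEL_FUSION; lower left -> NEGATIVE. The upper-left quadrant
    (specific signal without imbalance) is not an interpretable fusion
    pattern and maps to NEGATIVE with a warning.
    """
    high_ratio = ratio >= ratio_cut
    high_signal = signal >= signal_cut
    if high_ratio and high_signal:
        return STATUS_KNOWN, None
    if high_ratio:
        return STATUS_NOVEL, None
    if high_signal:
        return (
            STATUS_NEGATIVE,
            "specific signal above threshold without 3'/5' imbalance",
        )
    return STATUS_NEGATIVE, None


def call_fusion(
    profile: CountProfile,
    probe_set: ProbeSet,
    thresholds: CallerThresholds,
    gene: str,
    qc_ratio: float = 0.0,
    _normalized: CountProfile | None = None,
) -> FusionCall:
    """Classify one gene in one QC-passing profile.

    `profile` is the raw profile; normalization runs internally (pass
    `_normalized` to reuse a precomputed one across genes).
    """
    probe_set.require_gene(gene)
    norm = _normalized or normalize_profile(profile, probe_set, thresholds)
    ratio = compute_ratio_3p5p(norm, probe_set, gene, thresholds.pseudocount)
    signal, best_id = compute_fusion_signal(norm, probe_set, gene)
    status, warning = classify_quadrant(
        ratio, signal, thresholds.ratio_cut(gene), thresholds.signal_cut(gene)
    )
    return FusionCall(
        sample_id=profile.sample_id,
        gene=gene,
        status=status,
        best_fusion_id=best_id if status == STATUS_KNOWN else None,
        ratio_3p5p=ratio,
        max_specific_signal=signal,
        qc_ratio=qc_ratio,
        warning=warning,
    )


def call_batch(
    profiles: Sequence[CountProfile],
    probe_set: ProbeSet,
    thresholds: CallerThresholds | None = None,
    hk_reference_level: float | None = None,
) -> tuple[list[FusionCall], dict]:
    """Run QC + fusion calling over a batch and summarize positivity.

    QC-failing profiles receive QC_FAIL for every gene and are excluded from
    the positivity denominator. The summary reports, per gene and overall:
    n analyzed, n failed, n positive, percent positive (one decimal). A
    sample is "positive overall" if any gene is KNOWN_FUSION or NOVEL_FUSION.
    """
    if not profiles:
        raise FusionCallerError("empty batch")
    thresholds = thresholds or CallerThresholds()
    reference = (
        hk_reference_level
        if hk_reference_level is not None
        else thresholds.hk_reference_level
    )
    if reference is None:
        reference = batch_housekeeping_reference(profiles, probe_set)

    calls: list[FusionCall] = []
    genes = probe_set.genes
    n_failed = 0
    positive_samples: set[str] = set()
    per_gene_pos = {g: 0 for g in genes}
    for profile in profiles:
        passed, qc_ratio = qc_check(
            profile, probe_set, thresholds, reference_level=reference
        )
        if not passed:
            n_failed += 1
            for gene in genes:
                calls.append(
                    FusionCall(
                        sample_id=profile.sample_id,
                        gene=gene,
                        status=STATUS_QC_FAIL,
                        best_fusion_id=None,
                        ratio_3p5p=float("nan"),
                        max_specific_signal=float("nan"),
                        qc_ratio=qc_ratio,
                    )
                )
            continue
        norm = normalize_profile(profile, probe_set, thresholds)
        for gene in genes:
            call = call_fusion(
                profile,
                probe_set,
                thresholds,
                gene,
                qc_ratio=qc_ratio,
                _normalized=norm,
            )
            calls.append(call)
            if call.status in (STATUS_KNOWN, STATUS_NOVEL):
                per_gene_pos[gene] += 1
                positive_samples.add(profile.sample_id)

    n_total = len(profiles)
    n_analyzed = n_total - n_failed

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else 0.0

    summary = {
        "n_profiles": n_total,
        "n_failed": n_failed,
        "n_analyzed": n_analyzed,
        "failure_percent": pct(n_failed, n_total),
        "failure_percent_rounded": round(100.0 * n_failed / n_total)
        if n_total
        else 0,
        "n_positive": len(positive_samples),
        "positive_percent": pct(len(positive_samples), n_analyzed),
        "hk_reference_level": reference,
        "per_gene": {
            g: {
                "n_positive": per_gene_pos[g],
                "positive_percent": pct(per_gene_pos[g], n_analyzed),
            }
            for g in genes
        },
    }
    return calls, summary


def calls_to_frame(calls: Iterable[FusionCall]) -> pd.DataFrame:
    """Flatten FusionCalls into the fusion-call table (one row/sample x gene)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "status": c.status,
                "best_fusion_id": c.best_fusion_id,
                "ratio_3p5p": c.ratio_3p5p,
                "max_specific_signal": c.max_specific_signal,
                "qc_ratio": c.qc_ratio,
                "warning": c.warning,
            }
            for c in calls
        ]
    )
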