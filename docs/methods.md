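# Methods

## Fusion calling from hybridization counts

The caller operates on per-sample probe-count vectors from a dual-design
probe set: for each of ALK, RET and ROS1, capture/reporter probes flank the
tyrosine-kinase exons on the 5′ and 3′ sides, and junction-spanning
("toehold") probes target known fusion transcripts. Shared housekeeping,
positive-control (a six-point titration: 128, 32, 8, 2, 0.5, 0.125 fM) and
negative-control probes support normalization and QC.

Processing order and defaults:

1. **QC (raw counts).** A hybridization fails if H/Hᵢ > 8, where Hᵢ is the
   profile's housekeeping geometric mean (a +1 pseudocount tolerates zero
   counts) and H is a reference housekeeping level. The reference resolves
   from: an explicit argument, then `CallerThresholds.hk_reference_level`,
   then — in batch calling — the geometric mean of per-profile levels
   across the batch. The batch-derived reference is the default because a
   minority of degraded profiles barely moves a geometric mean; it is
   undefined as a failure detector when *every* profile has collapsed, so
   saturation scenarios should pass an explicit reference. The inequality
   is strict: a ratio of exactly 8 passes.
2. **Background correction.** Assay probes (5′/3′ flank + junction) are
   reduced by mean(negative controls) + 2·SD and floored at zero. Control
   and housekeeping counts pass through unchanged.
3. **Positive-control scaling.** Assay counts are multiplied by
   `reference_factor / geomean(positive controls)`. Default
   `reference_factor = 800`, the expected control geometric mean of the
   synthetic batches, making the scale factor ≈ 1 on sound profiles. Any
   zero positive control is a degenerate hybridization and an error. The
   construction makes every downstream statistic invariant to global
   multiplicative factors on the raw counts.
4. **Statistics.** Per gene: the 3′/5′ ratio of probe-count means with a
   +1 pseudocount on both numerator and denominator (keeps the ratio finite
   when a 5′ signal is fully background-subtracted), and the maximum
   junction-probe count with ties broken toward the lexicographically
   smaller fusion id.
5. **Classification.** With ratio threshold *r* = 2.0 and signal threshold
   *s* = 50 (both inclusive, per-gene overrides supported): ratio ≥ *r* and
   signal ≥ *s* → KNOWN_FUSION; ratio ≥ *r* alone → NOVEL_FUSION; anything
   else → NEGATIVE. The fourth quadrant — junction signal without imbalance
   — is not an interpretable fusion pattern and maps to NEGATIVE with a
   warning annotation. The thresholds are lab-calibration parameters, not
   constants of the method; the defaults are chosen once to separate the
   synthetic classes cleanly (planted fusions sit at a ratio of ~12 and
   signals of ~1000 on the scaled axis).

Batch summaries report QC failures and positivity per gene and overall;
QC-failed profiles are excluded from positivity denominators.

## Variant filtering and actionability

A variant is retained iff it was detected in **both** library pools of the
bidirectional amplicon design, its coverage strictly exceeds 1000×, and its
VAF is at least the 4% clinical limit of detection (the LOD is inclusive,
the coverage rule strict — matching the conventions the thresholds come
from). The first failing rule in the order pool → coverage → VAF is
recorded as the rejection reason, so filtering is order-independent and
fully auditable.

The protein-notation parser accepts a constrained HGVS-like dialect
(optional `p.` prefix, one- or three-letter codes, substitutions,
frameshifts, del/dup/ins spans, and the `exon19del` alias) and is total:
unparseable input classifies as `other` with no codon, never an exception.

Actionability rules live in a YAML file (`lungdx/data/actionable_rules.yaml`)
with three match kinds: codon sets (e.g. KRAS {12, 13, 61}), named protein
changes (EGFR T790M, AKT1 L52R) and exon events (EGFR exon 19 deletion,
EGFR/ERBB2 exon 20 insertion). The first matching rule in file order wins;
at load time rule genes are checked against the panel and per-gene codon
sets are verified disjoint. The PIK3CA set is {542, 545, 1047}: the source
listing repeats 1047, which is treated as a typographical duplication (the
file carries a comment; overrides are a rule-file edit away). EGFR T790M is
a resistance marker rather than a sensitizing mutation; it counts as
actionable by default with a `t790m_actionable=False` escape hatch.
Codon numbering is 1-based on the canonical protein; exon numbering follows
the panel file; no genomic coordinates are modeled.

## Concordance

Two paired calls are concordant when both methods agree on
mutation-vs-no-mutation and, when both report a mutation, on the variant
identity (the comparison uses whichever notation both sides carry — the
motivating discordant case was two methods reporting *different* KRAS
variants at the same codon). Rows flagged out-of-scope (the panel found a
variant at a locus the single-gene assay never interrogates) can be removed
from numerator and denominator; both renderings, at one decimal and at the
nearest integer, are always reported.

## Stratification

Triple-negative status (no retained EGFR/KRAS/BRAF mutation) is computed
from variants only — fusion results never feed into it, keeping the two
analyses orthogonal. Eligibility categories apply the precedence
EGFR+ → ALK+ → per-gene emerging targets (RET, ROS1, BRAF, PIK3CA, ERBB2,
NRAS, MAP2K1, AKT1) → KRAS_only → none; EGFR-before-ALK for the rare
double-positive is a configurable default (the order in which the two
standard-therapy categories are conventionally listed). Categories
partition every cohort, and the ≥1-actionable percentage equals
100 − percent(none) by construction; percentages are reported with and
without KRAS. The variant-burden histogram {0, 1–2, >2} counts all
retained non-synonymous variants, not just actionable ones. Fusion-untested
samples stay in denominators, with fusion positivity additionally rendered
against the successfully-tested denominator.

## Synthetic data

The generators exist to exercise the pipeline's logic at realistic scale,
not to model assay physics:

* **Counts** are negative-binomial around probe-role means (negative
  controls 12, flank probes 150, housekeeping 2500, junction probes 5 at
  baseline; positive controls 200 counts/fM) with dispersion
  α = 0.02 (Var = μ + αμ²). No distributional information is available for
  the real assay's counts; overdispersed counts are the standard assumption
  for hybridization data and this noise model is a documented stand-in.
  At α = 0.02 the probability that a null 3′/5′ ratio reaches the calling
  threshold is < 5·10⁻⁶ per gene-test (measured by direct simulation), so
  classification on synthetic batches is unambiguous — passing tests
  demonstrate the caller's logic, not its borderline calibration on real
  degraded FFPE material.
* **Fusion events** raise 3′-flank means 12-fold and, unless the event is
  novel, the matching junction-probe mean to 1200. **Degradation**
  suppresses all endogenous probes 100-fold (spike-in controls are
  unaffected). **Overexpression** raises 5′ and 3′ jointly 12-fold.
* **Cohorts** draw per-gene mutation presence as independent Bernoulli
  variables (defaults approximating an advanced-NSCLC testing population:
  TP53 0.45, KRAS 0.30, EGFR 0.14, BRAF 0.07, …) with notations from a
  curated catalogue of recurrent variants. Rates are user-set parameters,
  not fitted quantities; histology proportions default to 348/90/80/15
  over adenocarcinoma/SqCC/NSCLC-NOS/other per 533.
* **Ground truth** (actionable samples, fusion statuses, QC failures) is
  written to sidecar tables, never into the primary inputs; the cohort
  truth derives from hand-curated catalogue flags and the fusion truth from
  the planted event list, both independent of the engines they validate.

What the synthetic data does **not** emulate: probe-sequence effects,
batch/cartridge effects, partial RNA degradation (degradation is a single
scalar), subclonal VAF structure, histology-dependent mutation rates, and
co-mutation correlations. Results on synthetic batches therefore validate
the decision logic and accounting, not real-world sensitivity.

## Fixture compositions

`lungdx.fixtures` encodes two study-scale compositions used by the examples
and acceptance checks: a 169-hybridization batch (34 degraded, ten fusion
events — 4× EML4-ALK_E13:A20, 1× EML4-ALK_E6ab:A20, 2× CCDC6-RET_C1:R12,
one novel RET, SLC34A2-ROS1_S4:R32, SDC4-ROS1_S2:R32 — all placed in the 67
adenocarcinomas among the 135 analyzable profiles) and a 92-row validation
comparison (29 mutation / 63 no-mutation reference calls across four genes
and three tumor types, with one genuine KRAS discordance and three
out-of-scope discordances). Problem sizes throughout the test suite (cohorts
of 50–5000, batches of 4–169) are chosen to keep the full suite in the
tens-of-seconds range while leaving binomial checks adequately powered.

## Numerical conventions

Geometric means use log-space arithmetic; housekeeping levels add +1 before
the log. Percentages are computed at one decimal with nearest-integer
renderings alongside. Ties in junction-probe maxima break
lexicographically. All generators take explicit integer seeds
(`numpy.random.default_rng`); writers emit deterministic provenance headers
(tool version, seed, config hash — no timestamps), so equal seeds yield
byte-identical artifacts.
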