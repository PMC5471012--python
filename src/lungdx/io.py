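"""Tabular IO, configuration and the end-to-end pipeline runner.

All tables are UTF-8 delimited text with a header row and '.' for missing
values; comment lines start with '#'. Writers emit a deterministic
provenance header (tool version, seed, config hash) so that re-running with
the same seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import PAIRED_CALL_COLUMNS, evaluate_concordance, tabulate_by_gene
from .fusion import CallerThresholds, CountProfile, ProbeSet, call_batch, calls_to_frame
from .variants import VARIANT_COLUMNS, PanelDefinition, annotate_variants, load_rules

NA_REP = "."


class TableFormatError(ValueError):
    """Raised for malformed input tables (missing columns, bad rows)."""


def _packaged_path(name: str):
    return importlib.resources.files("lungdx.data") / name


def provenance_header(seed: int | None = None, extra: dict | None = None) -> str:
    fields = {"tool": f"lungdx {__version__}"}
    if seed is not None:
        fields["seed"] = seed
    if extra:
        fields.update(extra)
    return "# " + " ".join(f"{k}={v}" for k, v in fields.items())


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    seed: int | None = None,
    extra: dict | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(provenance_header(seed, extra) + "\n")
        df.to_csv(fh, sep=sep, index=index, na_rep=NA_REP)


def read_table(
    path: str | Path,
    sep: str = "\t",
    required: list[str] | None = None,
    index_col=None,
) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=sep, comment="#", na_values=[NA_REP], keep_default_na=True,
        index_col=index_col,
    )
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableFormatError(
                f"{path}: missing required column(s) {missing}"
            )
    return df


# -- format-specific wrappers ----------------------------------------------


def read_variants(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=VARIANT_COLUMNS)
    df["detected_in_pool_a"] = df["detected_in_pool_a"].astype(bool)
    df["detected_in_pool_b"] = df["detected_in_pool_b"].astype(bool)
    return df


def write_variants(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    write_table(df, path, seed=seed)


def read_samples(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=["sample_id", "histology"])


def read_paired_calls(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=PAIRED_CALL_COLUMNS)
    df["in_scope"] = df["in_scope"].astype(bool)
    return df


def read_probes(path: str | Path) -> ProbeSet:
    df = read_table(
        path, required=["probe_id", "gene", "role", "fusion_id", "nominal_amount"]
    )
    return ProbeSet.from_frame(df)


def read_panel(path: str | Path) -> PanelDefinition:
    df = read_table(path, required=["gene", "exons"])
    return PanelDefinition.from_frame(df)


def write_counts(
    profiles: list[CountProfile], path: str | Path, seed: int | None = None
) -> None:
    """Count matrix CSV: probes as rows, samples as columns."""
    mat = pd.DataFrame({p.sample_id: p.counts for p in profiles})
    mat.index.name = "probe_id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(provenance_header(seed) + "\n")
        # %.10g renders whole numbers without a trailing .0, so raw integer
        # counts round-trip byte-identically through the float reader
        mat.to_csv(fh, na_rep=NA_REP, float_format="%.10g")


def read_counts(path: str | Path, batch_id: str = "batch0") -> list[CountProfile]:
    mat = read_table(path, sep=",", index_col="probe_id")
    return [
        CountProfile(
            sample_id=str(col),
            counts={str(p): float(c) for p, c in mat[col].items()},
            batch_id=batch_id,
        )
        for col in mat.columns
    ]


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- VCF-lite ---------------------------------------------------------------

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
    '##INFO=<ID=EXON,Number=1,Type=Integer,Description="Exon number">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
]


def export_vcf_lite(variants: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF rendering of a gene/protein-level variant table.

    The assay reports variants at gene/protein granularity, so CHROM/POS/
    REF/ALT carry placeholders and the substance travels in INFO. Intended
    for interoperability, not for genomic round-trips.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = list(_VCF_HEADER)
    for row in variants.itertuples(index=False):
        info = [
            f"GENE={row.gene}",
            f"SAMPLE={row.sample_id}",
            f"VAF={float(row.vaf):.4f}",
        ]
        if not pd.isna(row.protein_change):
            info.append(f"PCHANGE={row.protein_change}")
        if not pd.isna(row.exon):
            info.append(f"EXON={int(row.exon)}")
        vid = row.coding_change if not pd.isna(row.coding_change) else "."
        lines.append(f".\t0\t{vid}\t.\t.\t.\tPASS\t{';'.join(info)}")
    path.write_text("\n".join(lines) + "\n")


def import_vcf_lite(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
        rows.append(
            {
                "sample_id": info.get("SAMPLE"),
                "gene": info.get("GENE"),
                "coding_change": None if f[2] == "." else f[2],
                "protein_change": info.get("PCHANGE"),
                "exon": int(info["EXON"]) if "EXON" in info else None,
                "vaf": float(info["VAF"]),
                "detected_in_pool_a": True,
                "detected_in_pool_b": True,
                "coverage": 0,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# -- pipeline ---------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration; None paths fall back to packaged files."""

    out_dir: str = "lungdx_out"
    seed: int = 0
    rules_file: str | None = None
    panel_file: str | None = None
    probes_file: str | None = None
    thresholds: dict = field(default_factory=dict)
    exclude_out_of_scope: bool = False
    t790m_actionable: bool = True
    simulate_cohort_n: int = 533
    simulate: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("rules_file", "panel_file", "probes_file"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> annotate -> call fusions -> concordance -> stratify.

    Returns the provenance manifest; every artifact lands under
    config.out_dir. Stage failures abort with the stage name attached.
    """
    from . import fixtures, simulate as sim
    from .stratify import build_sample_records, cooccurrence_matrix, stratify

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stage = "setup"
    try:
        probe_set = (
            read_probes(config.probes_file)
            if config.probes_file
            else read_probes(_packaged_path("probes.tsv"))
        )
        panel = (
            read_panel(config.panel_file)
            if config.panel_file
            else read_panel(_packaged_path("panel.tsv"))
        )
        rules = load_rules(config.rules_file, panel=panel)
        thresholds = CallerThresholds(**config.thresholds)

        stage = "simulate"
        cohort_spec = sim.CohortSpec(n_samples=config.simulate_cohort_n, seed=seed)
        samples, variants, truth = sim.generate_variant_cohort(cohort_spec)
        write_table(samples, out / "samples.tsv", seed=seed)
        write_variants(variants, out / "variants.tsv", seed=seed)
        write_table(truth, out / "truth_cohort.tsv", seed=seed)
        batch = sim.generate_nanostring_batch(
            fixtures.prospective_batch_spec(seed=seed), probe_set
        )
        write_counts(batch.profiles, out / "counts.csv", seed=seed)
        write_table(batch.truth, out / "truth_fusions.tsv", seed=seed)
        paired = sim.generate_paired_calls(
            fixtures.validation_paired_call_spec(seed=seed)
        )
        write_table(paired, out / "paired_calls.tsv", seed=seed)

        stage = "annotate"
        annotated = annotate_variants(
            variants, rules=rules, panel=panel,
            t790m_actionable=config.t790m_actionable,
        )
        write_table(annotated, out / "annotated_variants.tsv", seed=seed)

        stage = "call-fusions"
        calls, batch_summary = call_batch(batch.profiles, probe_set, thresholds)
        fusion_frame = calls_to_frame(calls)
        write_table(fusion_frame, out / "fusion_calls.tsv", seed=seed)
        write_json(batch_summary, out / "fusion_batch_summary.json")

        stage = "concordance"
        report = evaluate_concordance(
            paired, exclude_out_of_scope=config.exclude_out_of_scope
        )
        write_json(report.to_dict(), out / "concordance.json")
        write_table(tabulate_by_gene(paired), out / "calls_by_gene.tsv", seed=seed)

        stage = "stratify"
        records = build_sample_records(samples, annotated)
        strat = stratify(records)
        write_json(strat, out / "stratification.json")
        write_table(
            cooccurrence_matrix(records),
            out / "cooccurrence.tsv",
            seed=seed,
            index=True,
        )
        # fusion batch stratified on its own histology metadata
        fusion_records = build_sample_records(batch.samples, None, fusion_frame)
        write_json(stratify(fusion_records), out / "fusion_stratification.json")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "tool": f"lungdx {__version__}",
        "seed": seed,
        "config_hash": config.config_hash(),
        "stages": [
            "simulate", "annotate", "call-fusions", "concordance", "stratify",
        ],
        "artifacts": sorted(
            p.name
            for p in out.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
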