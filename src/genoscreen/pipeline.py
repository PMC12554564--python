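"""End-to-end orchestration: panel -> filter -> triage -> PGx -> reports.

A run is driven by a :class:`RunConfig` (usually loaded from JSON).  All
referenced files are validated up front, before any stage executes.  The
primary outputs are JSON (one report per sample plus a cohort summary);
TSV summaries are derived from the JSON content, never the reverse.
Reports are byte-stable for identical inputs; no timestamps are embedded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from genoscreen import pgx as pgx_mod
from genoscreen.panel import PanelConfig, load_panel_config
from genoscreen.triage import (
    ClassifiedVariant,
    apply_curation_decisions,
    load_annotations,
    load_decisions,
    select_reportable,
    tabulate_transitions,
)
from genoscreen.variants import (
    VariantCall,
    filter_qual,
    filter_vaf,
    read_vcf,
    restrict_to_regions,
    write_filter_audit,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "load_run_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf_paths: list[Path]
    out_dir: Path
    panel_config: Path | None = None
    allele_definitions: Path | None = None
    function_table: Path | None = None
    annotations: Path | None = None
    decisions: Path | None = None
    vaf_threshold: float = 0.10
    min_qual: float = 20.0
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [
            p
            for p in [
                *self.vcf_paths,
                self.panel_config,
                self.allele_definitions,
                self.function_table,
                self.annotations,
                self.decisions,
            ]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"missing input files: {[str(p) for p in missing]}"
            )
        if not self.vcf_paths:
            raise ValueError("no input VCFs configured")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    base = Path(path).parent

    def _p(key: str) -> Path | None:
        v = raw.get(key)
        return (base / v) if v is not None else None

    return RunConfig(
        vcf_paths=[base / v for v in raw["vcf_paths"]],
        out_dir=base / raw.get("out_dir", "reports"),
        panel_config=_p("panel_config"),
        allele_definitions=_p("allele_definitions"),
        function_table=_p("function_table"),
        annotations=_p("annotations"),
        decisions=_p("decisions"),
        vaf_threshold=raw.get("vaf_threshold", 0.10),
        min_qual=raw.get("min_qual", 20.0),
        log_level=raw.get("log_level", "INFO"),
    )


@dataclass
class RunResult:
    reports: dict[str, dict]
    summary: "object"  # pandas.DataFrame of PGx categories
    out_dir: Path


def _screen_variants(
    vcf: Path, panel: PanelConfig | None, config: RunConfig
) -> list[VariantCall]:
    calls = []
    regions = panel.regions() if panel is not None else []
    for v in read_vcf(vcf, panel):
        v = filter_vaf(v, config.vaf_threshold)
        if not v.filtered:
            v = filter_qual(v, config.min_qual)
        if not v.filtered and regions:
            v = restrict_to_regions(v, regions)
        calls.append(v)
    return calls


def run_pipeline(config: RunConfig) -> RunResult:
    """Run all stages over the configured VCFs and write the report bundle."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    panel = (
        load_panel_config(config.panel_config)
        if config.panel_config is not None
        else None
    )
    definitions = (
        pgx_mod.load_allele_definitions(config.allele_definitions)
        if config.allele_definitions is not None
        else pgx_mod.load_default_definitions()
    )
    functions = (
        pgx_mod.load_function_table(config.function_table)
        if config.function_table is not None
        else pgx_mod.load_default_functions()
    )
    annotations = (
        load_annotations(config.annotations)
        if config.annotations is not None
        else None
    )
    decisions = (
        load_decisions(config.decisions) if config.decisions is not None else {}
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, dict] = {}
    audit_calls: list[VariantCall] = []
    all_pheno: list[pgx_mod.PhenotypeCall] = []
    all_classified: list[ClassifiedVariant] = []

    ann_index = {}
    if annotations is not None:
        for r in annotations.itertuples(index=False):
            ann_index[(r.chrom, int(r.pos), r.ref, r.alt)] = (
                r.auto_tier,
                r.clinvar_tier,
                bool(getattr(r, "risk_allele", False)),
            )

    for vcf in config.vcf_paths:
        sample_id = Path(vcf).stem
        screened = _screen_variants(vcf, panel, config)
        audit_calls.extend(v for v in screened if v.filtered)
        kept = [v for v in screened if not v.filtered]

        classified: list[ClassifiedVariant] = []
        for v in kept:
            ann = ann_index.get(v.key)
            if ann is None:
                continue
            auto, clinvar, risk = ann
            classified.append(
                ClassifiedVariant(
                    v, auto_tier=auto, clinvar_tier=clinvar, risk_allele=risk
                )
            )
        classified = apply_curation_decisions(classified, decisions)
        all_classified.extend(classified)
        pending = [c for c in classified if c.final_tier == "pending"]
        reportable = (
            []
            if pending
            else select_reportable(classified, panel)
        )

        pgx_report = {}
        for gene in sorted(definitions):
            defs = definitions[gene]
            genotypes = pgx_mod.read_pgx_sites(vcf, defs)
            dip = pgx_mod.call_diplotype(genotypes, defs)
            dip.sample_id = sample_id
            pheno = pgx_mod.map_phenotype(dip, functions)
            pheno.sample_id = sample_id
            all_pheno.append(pheno)
            pgx_report[gene] = {
                "diplotype": dip.label,
                "phenotype": pheno.phenotype,
                "ambiguous": dip.ambiguous,
                "alternatives": ["/".join(p) for p in dip.alternatives],
            }

        report = {
            "schema_version": "1.0",
            "sample_id": sample_id,
            "n_variants_screened": len(screened),
            "n_variants_filtered": sum(1 for v in screened if v.filtered),
            "pending_curation": [list(c.variant.key) for c in pending],
            "reportable": [
                {
                    "gene": c.variant.gene,
                    "chrom": c.variant.chrom,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": c.variant.alt,
                    "final_tier": c.final_tier,
                }
                for c in reportable
            ],
            "pgx": pgx_report,
        }
        reports[sample_id] = report
        with open(out_dir / f"{sample_id}.report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")

    write_filter_audit(audit_calls, out_dir / "filter_audit.tsv")
    summary = pgx_mod.summarize_cohort(all_pheno)
    summary.to_csv(out_dir / "pgx_summary.tsv", sep="\t", index=False)
    if all_classified and not any(
        c.final_tier == "pending" for c in all_classified
    ):
        tabulate_transitions(all_classified).to_tsv(
            out_dir / "transition_matrix.tsv"
        )
    return RunResult(reports=reports, summary=summary, out_dir=out_dir)
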