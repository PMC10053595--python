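"""End-to-end orchestration: filter -> ASE -> editing, plus result tables.

``run_all`` consumes a validated :class:`RunConfig`, writes one TSV per
stage artifact and a JSON run report that freezes every threshold used, so
results are interpretable without the config file.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from asedit.ase import AseResult, GroupDesign, analyze_sites
from asedit.editing import EditingCandidate, KnownEditingTable, detect_editing, intersect_known
from asedit.io_formats import (
    GenomeAnnotation,
    read_bed,
    read_fasta,
    read_gtf,
    read_variants,
    write_table,
)
from asedit.snv_filter import FilterReport, FilterThresholds, run_cascade
from asedit.ssr import ssr_mask


@dataclass
class RunConfig:
    variants: str
    gtf: str
    fasta: str
    design: str
    paralog_bed: str
    sine_bed: str
    outdir: str
    ssr_bed: Optional[str] = None  # scanned from fasta when absent
    known_editing: Optional[str] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    ase_delta_min: float = 0.1
    ase_fdr_max: float = 0.001
    balance_alpha: float = 0.05
    editing_aaf_ceiling: float = 0.7
    editing_delta_min: float = 0.1
    editing_fdr_max: float = 0.05
    flank: int = 1000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = FilterThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)

    def validate(self) -> None:
        for name in ("variants", "gtf", "fasta", "design", "paralog_bed", "sine_bed"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} input missing: {path}")
        for name in ("ssr_bed", "known_editing"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name} input missing: {path}")
        for name in (
            "ase_delta_min", "editing_delta_min", "editing_aaf_ceiling",
        ):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("ase_fdr_max", "editing_fdr_max", "balance_alpha"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} outside (0, 1]")


def read_design(path: str) -> GroupDesign:
    df = pd.read_csv(path, sep="\t")
    return GroupDesign(dict(zip(df["sample_id"].astype(str), df["group"].astype(str))))


def ase_table(results: Sequence[AseResult], group_names: Tuple[str, str]) -> pd.DataFrame:
    g1, g2 = group_names
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.ref,
                "alt": r.site.alt,
                "id": r.site.id,
                f"aaf_{g1}": r.group_aaf.get(g1),
                f"aaf_{g2}": r.group_aaf.get(g2),
                "delta_aaf": r.delta_aaf,
                "p": r.p_value,
                "q": r.q_value,
                "balance_p": r.balance_p,
                "category": r.category,
                "consequence": r.consequence,
                "ase_flag": int(r.ase_flag),
            }
        )
    return pd.DataFrame(rows)


def editing_table(candidates: Sequence[EditingCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "ref": c.site.ref,
                "alt": c.site.alt,
                "editing_type": c.editing_type,
                "strand": c.resolved_strand,
                "delta_aaf": c.delta_aaf,
                "q": c.q_value,
                "sine_start": c.sine_interval.start if c.sine_interval else None,
                "sine_end": c.sine_interval.end if c.sine_interval else None,
                "known_match": c.known_site_match,
                "localization": c.localization,
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "editing_type", "strand", "delta_aaf",
        "q", "sine_start", "sine_end", "known_match", "localization",
    ]
    return pd.DataFrame(rows, columns=cols)


def filter_report_table(report: FilterReport) -> pd.DataFrame:
    return pd.DataFrame(report.as_dicts())


def run_all(config: RunConfig) -> Dict[str, object]:
    """Execute the variant branch of the pipeline and write all artifacts."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    design = read_design(config.design)
    annotation = read_gtf(config.gtf)
    genome = read_fasta(config.fasta)
    paralogs = read_bed(config.paralog_bed)
    sines = read_bed(config.sine_bed)
    if config.ssr_bed is not None:
        ssrs = read_bed(config.ssr_bed)
    else:
        ssrs = ssr_mask(genome)
    sites = read_variants(config.variants, design.samples)

    survivors, report = run_cascade(
        sites, annotation, paralogs, ssrs, design.n_samples, config.thresholds
    )
    results = analyze_sites(
        survivors,
        design,
        annotation,
        genome,
        delta_min=config.ase_delta_min,
        fdr_max=config.ase_fdr_max,
        balance_alpha=config.balance_alpha,
        flank=config.flank,
    )
    editing, audit = detect_editing(
        results,
        annotation,
        sines,
        aaf_ceiling=config.editing_aaf_ceiling,
        delta_min=config.editing_delta_min,
        fdr_max=config.editing_fdr_max,
    )
    if config.known_editing is not None:
        known = KnownEditingTable.from_tsv(config.known_editing)
        editing = intersect_known(editing, known)

    write_table(filter_report_table(report), os.path.join(config.outdir, "filter_report.tsv"))
    ase_df = ase_table(results, design.group_names)
    write_table(ase_df, os.path.join(config.outdir, "ase.tsv"))
    write_table(editing_table(editing), os.path.join(config.outdir, "editing.tsv"))
    audit_df = pd.DataFrame(
        [
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "violated": ",".join(reasons),
            }
            for c, reasons in audit
        ],
        columns=["chrom", "pos", "violated"],
    )
    write_table(audit_df, os.path.join(config.outdir, "editing_audit.tsv"))

    run_report = {
        "n_input_sites": len(sites),
        "filter_report": report.as_dicts(),
        "n_tested": int(sum(1 for r in results if r.p_value is not None)),
        "n_ase": int(sum(1 for r in results if r.ase_flag)),
        "n_editing_candidates": len(editing) + len(audit),
        "n_editing": len(editing),
        "n_known_editing_matches": int(
            sum(1 for c in editing if c.known_site_match is not None)
        ),
        "thresholds": dataclasses.asdict(config.thresholds),
        "ase_thresholds": {
            "delta_min": config.ase_delta_min,
            "fdr_max": config.ase_fdr_max,
            "balance_alpha": config.balance_alpha,
        },
        "editing_thresholds": {
            "aaf_ceiling": config.editing_aaf_ceiling,
            "delta_min": config.editing_delta_min,
            "fdr_max": config.editing_fdr_max,
        },
    }
    with open(os.path.join(config.outdir, "run_report.json"), "w") as fh:
        json.dump(run_report, fh, indent=2, sort_keys=True)
    return {
        "report": report,
        "results": results,
        "editing": editing,
        "audit": audit,
        "run_report": run_report,
    }
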