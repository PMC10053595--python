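"""RNA-editing candidate discovery.

Canonical editing reads as A>G on the edited strand (A-to-I) or C>T
(C-to-U). Strand is resolved from the overlapping gene; intergenic sites
are accepted when exactly one strand reading is canonical. Candidates must
lack a known SNP identifier, stay at or below the editing-efficiency
ceiling (AAF 0.7) in every sample, overlap a PRE-1 SINE interval, and pass
the differential significance premises (FDR < 0.05, |dAAF| > 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from asedit.ase import AseResult
from asedit.intervals import GenomicInterval, IntervalIndex
from asedit.io_formats import GenomeAnnotation, VariantSite

#: (ref, alt, strand) -> editing type, for canonical substitutions only
_CANONICAL = {
    ("A", "G", "+"): "A_to_I",
    ("T", "C", "-"): "A_to_I",
    ("C", "T", "+"): "C_to_U",
    ("G", "A", "-"): "C_to_U",
}

EDITING_RULES = ("aaf_ceiling", "known_snp", "sine_overlap", "significance")


@dataclass
class EditingCandidate:
    site: VariantSite
    editing_type: str
    resolved_strand: str
    delta_aaf: Optional[float] = None
    q_value: Optional[float] = None
    sine_interval: Optional[GenomicInterval] = None
    known_site_match: Optional[str] = None
    localization: Optional[str] = None


@dataclass
class KnownEditingTable:
    """Known editing sites keyed by (chrom, 1-based pos, editing type)."""

    rows: Dict[Tuple[str, int, str], str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str) -> "KnownEditingTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.add(str(row.chrom), int(row.pos), str(row.type), str(row.tissue))
        return table

    def add(self, chrom: str, pos: int, editing_type: str, tissue: str) -> None:
        key = (chrom, pos, editing_type)
        if key in self.rows:
            raise ValueError(f"duplicate known-site row {key}")
        self.rows[key] = tissue

    def lookup(self, chrom: str, pos: int, editing_type: str) -> Optional[str]:
        return self.rows.get((chrom, pos, editing_type))

    def __len__(self) -> int:
        return len(self.rows)


def canonical_reading(ref: str, alt: str, strand: str) -> Optional[str]:
    return _CANONICAL.get((ref, alt, strand))


def resolve_canonical(
    site: VariantSite, annotation: GenomeAnnotation
) -> Optional[Tuple[str, str]]:
    """(editing_type, resolved_strand) or None for non-canonical changes.

    Gene strand wins when a gene overlaps; intergenic sites accept the
    single canonical strand reading if one exists. Sites with conflicting
    canonical readings on opposite gene strands are excluded as ambiguous.
    """
    genes = annotation.genes_at(site.chrom, site.pos0)
    strands = sorted({g.strand for g in genes})
    if strands:
        readings = [
            (canonical_reading(site.ref, site.alt, strand), strand)
            for strand in strands
        ]
        hits = [(etype, strand) for etype, strand in readings if etype is not None]
        if not hits:
            return None
        if len({etype for etype, _ in hits}) > 1:
            return None  # ambiguous: conflicting canonical readings
        return hits[0]
    for strand in ("+", "-"):
        etype = canonical_reading(site.ref, site.alt, strand)
        if etype is not None:
            return etype, strand
    return None


def editing_filter(
    candidates: Sequence[EditingCandidate],
    sine_intervals: Sequence[GenomicInterval],
    aaf_ceiling: float = 0.7,
    delta_min: float = 0.1,
    fdr_max: float = 0.05,
) -> Tuple[List[EditingCandidate], List[Tuple[EditingCandidate, List[str]]]]:
    """Apply the four editing rules; return survivors and a per-candidate
    audit naming every violated rule."""
    sine_idx = IntervalIndex.build(sine_intervals)
    kept: List[EditingCandidate] = []
    audit: List[Tuple[EditingCandidate, List[str]]] = []
    for cand in candidates:
        violated: List[str] = []
        aafs = [cand.site.aaf(s) for s in cand.site.counts]
        if any(a is not None and a > aaf_ceiling for a in aafs):
            violated.append("aaf_ceiling")
        if cand.site.id is not None:
            violated.append("known_snp")
        hits = sine_idx.at(cand.site.chrom, cand.site.pos0)
        if hits:
            cand.sine_interval = sorted(hits, key=lambda iv: (iv.start, iv.end))[0]
        else:
            violated.append("sine_overlap")
        if not (
            cand.q_value is not None
            and cand.q_value < fdr_max
            and cand.delta_aaf is not None
            and abs(cand.delta_aaf) > delta_min
        ):
            violated.append("significance")
        if violated:
            audit.append((cand, violated))
        else:
            kept.append(cand)
    return kept, audit


def detect_editing(
    ase_results: Sequence[AseResult],
    annotation: GenomeAnnotation,
    sine_intervals: Sequence[GenomicInterval],
    aaf_ceiling: float = 0.7,
    delta_min: float = 0.1,
    fdr_max: float = 0.05,
) -> Tuple[List[EditingCandidate], List[Tuple[EditingCandidate, List[str]]]]:
    """Editing branch over analyzed sites: canonical resolution then the
    four-rule filter. Returns (survivors, audit of removed candidates)."""
    candidates = []
    for res in ase_results:
        resolved = resolve_canonical(res.site, annotation)
        if resolved is None:
            continue
        etype, strand = resolved
        candidates.append(
            EditingCandidate(
                site=res.site,
                editing_type=etype,
                resolved_strand=strand,
                delta_aaf=res.delta_aaf,
                q_value=res.q_value,
                localization=res.consequence,
            )
        )
    return editing_filter(candidates, sine_intervals, aaf_ceiling, delta_min, fdr_max)


def intersect_known(
    candidates: Sequence[EditingCandidate], known: KnownEditingTable
) -> List[EditingCandidate]:
    """Annotate candidates matching known sites on (chrom, pos, type)."""
    for cand in candidates:
        tissue = known.lookup(cand.site.chrom, cand.site.pos, cand.editing_type)
        cand.known_site_match = tissue
    return list(candidates)
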