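"""Readers and writers for the external formats the pipeline consumes.

Internal convention is 0-based half-open everywhere. GTF (1-based closed)
and VCF (1-based positions) are converted on ingest; ``VariantSite.pos``
keeps the familiar 1-based VCF position and exposes ``pos0`` for interval
arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from asedit.intervals import (
    GenomicInterval,
    IntervalIndex,
    intersect_stranded,
    merge_intervals,
)

QUALITY_KEYS = ("MQ", "DP", "QD", "ReadPosRankSum", "MQRankSum")
NUCLEOTIDES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    transcript_id: str
    biotype: str
    strand: str
    exons: List[GenomicInterval]
    cds: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length_nt(self) -> int:
        return sum(len(e) for e in self.exons)

    def junctions(self) -> List[int]:
        """Internal exon boundaries (donor exon ends, acceptor exon starts)."""
        out: List[int] = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.extend((a.end, b.start))
        return out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: List[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class GenomeAnnotation:
    """Gene models plus the interval indexes the context filters query."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: List[GeneModel] = list(genes)
        self.gene_index = IntervalIndex()
        self._gene_by_span: Dict[Tuple[str, int, int, str], GeneModel] = {}
        junctions: Dict[str, set] = {}
        for gene in self.genes:
            span = gene.span
            self.gene_index.add(span)
            self._gene_by_span[(span.chrom, span.start, span.end, span.strand)] = gene
            for tx in gene.transcripts:
                for j in tx.junctions():
                    junctions.setdefault(gene.chrom, set()).add(j)
        self.junctions: Dict[str, np.ndarray] = {
            c: np.array(sorted(js), dtype=np.int64) for c, js in junctions.items()
        }
        plus = merge_intervals(
            g.span for g in self.genes if g.strand == "+"
        ) if any(g.strand == "+" for g in self.genes) else []
        minus = merge_intervals(
            g.span for g in self.genes if g.strand == "-"
        ) if any(g.strand == "-" for g in self.genes) else []
        self.bidirectional_regions = intersect_stranded(plus, minus)
        self._bidir_index = IntervalIndex.build(self.bidirectional_regions)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_at(self, chrom: str, pos: int) -> List[GeneModel]:
        return [
            self._gene_by_span[(iv.chrom, iv.start, iv.end, iv.strand)]
            for iv in self.gene_index.at(chrom, pos)
        ]

    def genes_near(self, chrom: str, pos: int, flank: int) -> List[GeneModel]:
        return [
            self._gene_by_span[(iv.chrom, iv.start, iv.end, iv.strand)]
            for iv in self.gene_index.overlapping(chrom, pos - flank, pos + flank + 1)
        ]

    def min_junction_distance(self, chrom: str, pos: int) -> Optional[int]:
        js = self.junctions.get(chrom)
        if js is None or len(js) == 0:
            return None
        i = int(np.searchsorted(js, pos))
        best = None
        for k in (i - 1, i):
            if 0 <= k < len(js):
                d = abs(int(js[k]) - pos)
                best = d if best is None else min(best, d)
        return best

    def in_bidirectional(self, chrom: str, pos: int) -> bool:
        return self._bidir_index.covers(chrom, pos)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass
class VariantSite:
    """One biallelic SNV with per-sample allele depths.

    ``pos`` is 1-based (as printed in VCF); ``pos0`` is the internal 0-based
    coordinate used against intervals.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None
    quality: Dict[str, float] = field(default_factory=dict)
    counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    missing_ad: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"non-ACGT allele {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def ref_total(self) -> int:
        return sum(r for r, _ in self.counts.values())

    def alt_total(self) -> int:
        return sum(a for _, a in self.counts.values())

    def aaf(self, sample: str) -> Optional[float]:
        r, a = self.counts[sample]
        return a / (r + a) if (r + a) > 0 else None


def _sorted_sites(sites: List[VariantSite]) -> List[VariantSite]:
    return sorted(sites, key=lambda s: (s.chrom, s.pos, s.ref, s.alt))


def read_variants(
    path: str,
    sample_ids: Sequence[str],
    multiallelic: str = "split",
) -> List[VariantSite]:
    """Load biallelic SNVs with per-sample ref/alt depths.

    Accepts VCF (``FORMAT/AD``) or the TSV dialect written by the simulator
    (columns chrom,pos,ref,alt,id,MQ,DP,QD,ReadPosRankSum,MQRankSum then
    ref_<sample>/alt_<sample> pairs). ``multiallelic`` is 'split' or 'drop'.
    """
    if multiallelic not in ("split", "drop"):
        raise ValueError("multiallelic must be 'split' or 'drop'")
    if path.endswith((".tsv", ".txt")):
        sites = _read_variants_tsv(path, sample_ids)
    else:
        sites = _read_variants_vcf(path, sample_ids, multiallelic)
    return _sorted_sites(sites)


def _read_variants_vcf(
    path: str, sample_ids: Sequence[str], multiallelic: str
) -> List[VariantSite]:
    sites: List[VariantSite] = []
    n_skipped_indel = 0
    with pysam.VariantFile(path) as vcf:
        present = set(vcf.header.samples)
        missing = [s for s in sample_ids if s not in present]
        if missing:
            raise ValueError(f"samples absent from VCF: {missing}")
        for rec in vcf:
            alts = rec.alts or ()
            if multiallelic == "drop" and len(alts) > 1:
                continue
            for ai, alt in enumerate(alts):
                if len(rec.ref) != 1 or alt is None or len(alt) != 1:
                    n_skipped_indel += 1
                    continue
                if rec.ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                    n_skipped_indel += 1
                    continue
                quality = {}
                for key in QUALITY_KEYS:
                    if key in rec.info:
                        val = rec.info[key]
                        if isinstance(val, tuple):
                            val = val[0]
                        if val is not None:
                            quality[key] = float(val)
                counts: Dict[str, Tuple[int, int]] = {}
                flagged = set()
                for sid in sample_ids:
                    ad = rec.samples[sid].get("AD")
                    if ad is None or ad[0] is None:
                        counts[sid] = (0, 0)
                        flagged.add(sid)
                    else:
                        alt_depth = ad[ai + 1] if len(ad) > ai + 1 else None
                        if alt_depth is None:
                            counts[sid] = (int(ad[0]), 0)
                            flagged.add(sid)
                        else:
                            counts[sid] = (int(ad[0]), int(alt_depth))
                vid = rec.id if rec.id not in (None, ".") else None
                sites.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        id=vid,
                        quality=quality,
                        counts=counts,
                        missing_ad=frozenset(flagged),
                    )
                )
    if n_skipped_indel:
        warnings.warn(f"skipped {n_skipped_indel} non-SNV allele records")
    return sites


def _read_variants_tsv(path: str, sample_ids: Sequence[str]) -> List[VariantSite]:
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    for sid in sample_ids:
        if f"ref_{sid}" not in df.columns or f"alt_{sid}" not in df.columns:
            raise ValueError(f"sample {sid!r} absent from variant TSV")
    sites = []
    for row in df.itertuples(index=False):
        quality = {
            k: float(getattr(row, k))
            for k in QUALITY_KEYS
            if k in df.columns and pd.notna(getattr(row, k))
        }
        counts = {
            sid: (int(getattr(row, f"ref_{sid}")), int(getattr(row, f"alt_{sid}")))
            for sid in sample_ids
        }
        vid = None if pd.isna(row.id) else str(row.id)
        sites.append(
            VariantSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                id=vid,
                quality=quality,
                counts=counts,
            )
        )
    return sites


def write_variants_tsv(
    sites: Sequence[VariantSite], sample_ids: Sequence[str], path: str
) -> None:
    rows = []
    for s in sites:
        row: Dict[str, object] = {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "id": s.id if s.id is not None else ".",
        }
        for k in QUALITY_KEYS:
            row[k] = s.quality.get(k, ".")
        for sid in sample_ids:
            r, a = s.counts[sid]
            row[f"ref_{sid}"] = r
            row[f"alt_{sid}"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variants_vcf(
    sites: Sequence[VariantSite],
    sample_ids: Sequence[str],
    contig_lengths: Dict[str, int],
    path: str,
) -> None:
    """Emit a minimal VCF 4.2 with INFO quality keys and FORMAT/AD."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    for key, desc in (
        ("MQ", "RMS mapping quality"),
        ("DP", "Total depth"),
        ("QD", "Quality by depth"),
        ("ReadPosRankSum", "Read position rank sum"),
        ("MQRankSum", "Mapping quality rank sum"),
    ):
        typ = "Integer" if key == "DP" else "Float"
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">'
        )
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(sample_ids)
    lines.append("\t".join(header))
    for s in _sorted_sites(list(sites)):
        info_parts = []
        for k in QUALITY_KEYS:
            if k in s.quality:
                v = s.quality[k]
                info_parts.append(f"{k}={int(v)}" if k == "DP" else f"{k}={v:.4g}")
        info = ";".join(info_parts) if info_parts else "."
        fields = [
            s.chrom,
            str(s.pos),
            s.id or ".",
            s.ref,
            s.alt,
            ".",
            ".",
            info,
            "AD",
        ]
        for sid in sample_ids:
            r, a = s.counts[sid]
            fields.append(f"{r},{a}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise ValueError(f"malformed GTF attribute at line {lineno}: {part!r}")
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path: str) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into gene models.

    1-based closed exon/CDS coordinates become 0-based half-open. Transcripts
    are grouped under genes; gene strand is taken from its features.
    """
    tx_exons: Dict[str, List[GenomicInterval]] = {}
    tx_cds: Dict[str, List[GenomicInterval]] = {}
    tx_meta: Dict[str, Tuple[str, str, str, str]] = {}  # gene, chrom, strand, biotype
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from exc
            attrs = _parse_gtf_attributes(attr, lineno)
            if "transcript_id" not in attrs:
                raise ValueError(
                    f"{feature} without transcript_id at GTF line {lineno}"
                )
            if "gene_id" not in attrs:
                raise ValueError(f"{feature} without gene_id at GTF line {lineno}")
            tid = attrs["transcript_id"]
            tx_meta.setdefault(
                tid,
                (
                    attrs["gene_id"],
                    chrom,
                    strand,
                    attrs.get("transcript_biotype", attrs.get("gene_biotype", "")),
                ),
            )
            if feature == "exon":
                tx_exons.setdefault(tid, []).append(iv)
            else:
                tx_cds.setdefault(tid, []).append(iv)
    genes: Dict[str, GeneModel] = {}
    for tid, (gene_id, chrom, strand, biotype) in tx_meta.items():
        tx = TranscriptModel(
            transcript_id=tid,
            biotype=biotype,
            strand=strand,
            exons=tx_exons.get(tid, []),
            cds=tx_cds.get(tid, []),
        )
        gene = genes.setdefault(gene_id, GeneModel(gene_id, chrom, strand, []))
        gene.transcripts.append(tx)
    for gene in genes.values():
        gene.transcripts.sort(key=lambda t: t.transcript_id)
    return GenomeAnnotation([genes[g] for g in sorted(genes)])


def write_gtf(annotation_genes: Sequence[GeneModel], path: str) -> None:
    lines = []
    for gene in annotation_genes:
        for tx in gene.transcripts:
            attr = (
                f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            for iv in tx.exons:
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            "asedit",
                            "exon",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            tx.strand,
                            ".",
                            attr,
                        ]
                    )
                )
            for iv in tx.cds:
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            "asedit",
                            "CDS",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            tx.strand,
                            "0",
                            attr,
                        ]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# BED / FASTA
# ---------------------------------------------------------------------------

def read_bed(path: str) -> List[GenomicInterval]:
    """BED3+ reader; native 0-based half-open; strand from column 6."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"BED line {lineno}: start >= end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str,
    names: Optional[Sequence[str]] = None,
) -> None:
    """BED3 writer (BED6 when names are given; score column 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n"
                )


def read_fasta(path: str) -> Dict[str, str]:
    """FASTA to {chrom: uppercase sequence}; duplicate headers are an error."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path: str) -> None:
    """Canonical TSV result writer: header line, tab-separated, '.' for NA."""
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")
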