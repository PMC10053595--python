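"""Allele-specific-expression statistics.

The differential test is a binomial likelihood-ratio test: each sample's
alternative-allele count is Binomial(depth, AAF) with the AAF shared at the
group level. Under H0 both groups share one AAF, under H1 each group has its
own; 2(l1 - l0) is referred to chi-square with 1 df. With group-level
parameters the per-sample likelihoods pool, so the statistic depends only on
pooled per-group ref/alt totals.

Allelic-balance categories come from a chi-square goodness-of-fit of pooled
ref/alt coverage against 1:1 (no continuity correction): 'true heterozygote'
when 1:1 is not rejected, else HeteroRef/HeteroAlt by the dominant allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq
from scipy.special import xlogy
from scipy.stats import chi2

from asedit.io_formats import GenomeAnnotation, GeneModel, TranscriptModel, VariantSite

CONSEQUENCE_CLASSES = (
    "cds_missense",
    "cds_synonymous",
    "five_prime_utr",
    "three_prime_utr",
    "noncoding_exon",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

#: precedence ranks: CDS > UTR > noncoding_exon > intron > up/downstream > intergenic
_SEVERITY = {
    "cds_missense": 0,
    "cds_synonymous": 0,
    "five_prime_utr": 1,
    "three_prime_utr": 1,
    "noncoding_exon": 2,
    "intron": 3,
    "upstream": 4,
    "downstream": 4,
    "intergenic": 5,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class GroupDesign:
    """Two-group sample design (e.g. implantation vs mid-luteal phase)."""

    assignment: Dict[str, str]

    def __post_init__(self) -> None:
        groups = sorted(set(self.assignment.values()))
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {groups}")
        self.group_names: Tuple[str, str] = (groups[0], groups[1])
        self.groups: Dict[str, List[str]] = {g: [] for g in groups}
        for sample, g in self.assignment.items():
            self.groups[g].append(sample)
        for g, members in self.groups.items():
            if not members:
                raise ValueError(f"group {g} is empty")
            members.sort()

    @property
    def samples(self) -> List[str]:
        return sorted(self.assignment)

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def swapped(self) -> "GroupDesign":
        g1, g2 = self.group_names
        flip = {g1: g2, g2: g1}
        return GroupDesign({s: flip[g] for s, g in self.assignment.items()})


@dataclass
class AseResult:
    site: VariantSite
    aaf_per_sample: Dict[str, Optional[float]] = field(default_factory=dict)
    group_aaf: Dict[str, Optional[float]] = field(default_factory=dict)
    delta_aaf: Optional[float] = None
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    balance_p: Optional[float] = None
    category: Optional[str] = None
    consequence: Optional[str] = None
    ase_flag: bool = False
    testable: bool = True


def _group_totals(site: VariantSite, design: GroupDesign) -> Dict[str, Tuple[int, int]]:
    totals = {}
    for g, members in design.groups.items():
        r = sum(site.counts[s][0] for s in members)
        a = sum(site.counts[s][1] for s in members)
        totals[g] = (r, a)
    return totals


def compute_aaf(
    site: VariantSite, design: GroupDesign
) -> Tuple[Dict[str, Optional[float]], Dict[str, Optional[float]], Optional[float]]:
    """Per-sample AAF, pooled per-group AAF, and group1 - group2 difference.

    A group with zero total depth makes the site untestable (delta None).
    """
    per_sample = {s: site.aaf(s) for s in design.samples}
    totals = _group_totals(site, design)
    group_aaf: Dict[str, Optional[float]] = {}
    for g, (r, a) in totals.items():
        group_aaf[g] = a / (r + a) if (r + a) > 0 else None
    g1, g2 = design.group_names
    if group_aaf[g1] is None or group_aaf[g2] is None:
        return per_sample, group_aaf, None
    return per_sample, group_aaf, group_aaf[g1] - group_aaf[g2]


def test_delta_aaf(site: VariantSite, design: GroupDesign) -> Optional[float]:
    """Binomial LRT p-value for a group-level AAF difference; None if a
    whole group has zero depth."""
    totals = _group_totals(site, design)
    g1, g2 = design.group_names
    r1, a1 = totals[g1]
    r2, a2 = totals[g2]
    n1, n2 = r1 + a1, r2 + a2
    if n1 == 0 or n2 == 0:
        return None

    def _ll(alt: int, n: int) -> float:
        p = alt / n
        return float(xlogy(alt, p) + xlogy(n - alt, 1 - p))

    l1 = _ll(a1, n1) + _ll(a2, n2)
    l0 = _ll(a1 + a2, n1 + n2)
    stat = max(0.0, 2.0 * (l1 - l0))
    return float(chi2.sf(stat, df=1))


test_delta_aaf.__test__ = False  # library function, not a pytest item


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def balance_category(site: VariantSite) -> Tuple[Optional[float], Optional[str]]:
    """Chi-square 1:1 goodness-of-fit on pooled ref/alt totals."""
    r, a = site.ref_total(), site.alt_total()
    total = r + a
    if total == 0:
        return None, None
    expected = total / 2.0
    stat = (r - expected) ** 2 / expected + (a - expected) ** 2 / expected
    p = float(chi2.sf(stat, df=1))
    if p >= 0.05 or r == a:
        return p, "true_heterozygote"
    return p, ("HeteroRef" if r > a else "HeteroAlt")


def classify_ase(
    results: Sequence[AseResult],
    delta_min: float = 0.1,
    fdr_max: float = 0.001,
    balance_alpha: float = 0.05,
) -> List[AseResult]:
    """BH-adjust the tested family in place and set the ASE flag.

    Flag iff |delta AAF| > delta_min AND q < fdr_max AND the 1:1 balance
    test rejects at balance_alpha (the chi-square confirmation).
    """
    tested = [r for r in results if r.p_value is not None]
    if tested:
        qs = bh_adjust([r.p_value for r in tested])
        for r, q in zip(tested, qs):
            r.q_value = float(q)
    for r in results:
        r.balance_p, r.category = balance_category(r.site)
        r.ase_flag = bool(
            r.delta_aaf is not None
            and abs(r.delta_aaf) > delta_min
            and r.q_value is not None
            and r.q_value < fdr_max
            and r.balance_p is not None
            and r.balance_p < balance_alpha
        )
    return list(results)


def analyze_sites(
    sites: Sequence[VariantSite],
    design: GroupDesign,
    annotation: Optional[GenomeAnnotation] = None,
    genome: Optional[Dict[str, str]] = None,
    delta_min: float = 0.1,
    fdr_max: float = 0.001,
    balance_alpha: float = 0.05,
    flank: int = 1000,
) -> List[AseResult]:
    """Full ASE analysis of a filtered site list."""
    results = []
    for site in sites:
        per_sample, group_aaf, delta = compute_aaf(site, design)
        res = AseResult(
            site=site,
            aaf_per_sample=per_sample,
            group_aaf=group_aaf,
            delta_aaf=delta,
            p_value=test_delta_aaf(site, design),
            testable=delta is not None,
        )
        if annotation is not None and genome is not None:
            res.consequence = annotate_consequence(site, annotation, genome, flank)
        results.append(res)
    return classify_ase(results, delta_min, fdr_max, balance_alpha)


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _cds_consequence(
    tx: TranscriptModel, site: VariantSite, genome: Dict[str, str]
) -> str:
    """Read the codon containing the site on the coding strand and compare
    translations of the ref and alt codons."""
    seq = genome[site.chrom]
    cds_seq_parts = []
    offset = None
    acc = 0
    for iv in tx.cds:  # sorted by start (genomic order)
        cds_seq_parts.append(seq[iv.start : iv.end])
        if iv.start <= site.pos0 < iv.end:
            offset = acc + (site.pos0 - iv.start)
        acc += len(iv)
    if offset is None:
        raise ValueError("site not within the transcript's CDS")
    cds_plus = "".join(cds_seq_parts)
    if tx.strand == "+":
        coding = cds_plus
        idx = offset
        ref_base, alt_base = site.ref, site.alt
    else:
        coding = _revcomp(cds_plus)
        idx = len(cds_plus) - 1 - offset
        ref_base, alt_base = _COMPLEMENT[site.ref], _COMPLEMENT[site.alt]
    if coding[idx] != ref_base:
        raise ValueError(
            f"reference allele {site.ref} disagrees with genome at "
            f"{site.chrom}:{site.pos}"
        )
    codon_start = (idx // 3) * 3
    ref_codon = coding[codon_start : codon_start + 3]
    if len(ref_codon) < 3:  # trailing partial codon: treat as synonymous-safe
        return "cds_synonymous"
    alt_codon = (
        ref_codon[: idx - codon_start]
        + alt_base
        + ref_codon[idx - codon_start + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "cds_synonymous" if ref_aa == alt_aa else "cds_missense"


def _transcript_consequence(
    tx: TranscriptModel, site: VariantSite, genome: Dict[str, str]
) -> Optional[str]:
    pos0 = site.pos0
    in_exon = any(iv.start <= pos0 < iv.end for iv in tx.exons)
    if tx.cds and any(iv.start <= pos0 < iv.end for iv in tx.cds):
        return _cds_consequence(tx, site, genome)
    if in_exon:
        if not tx.cds:
            return "noncoding_exon"
        cds_start = tx.cds[0].start
        cds_end = tx.cds[-1].end
        if pos0 < cds_start:
            return "five_prime_utr" if tx.strand == "+" else "three_prime_utr"
        if pos0 >= cds_end:
            return "three_prime_utr" if tx.strand == "+" else "five_prime_utr"
        return None  # exonic but inside the CDS span without CDS overlap
    if tx.start <= pos0 < tx.end:
        return "intron"
    return None


def annotate_consequence(
    site: VariantSite,
    annotation: GenomeAnnotation,
    genome: Dict[str, str],
    flank: int = 1000,
) -> str:
    """Assign exactly one localization class by severity precedence.

    Across overlapping transcripts the most severe class wins; ties break on
    the lowest transcript_id. Upstream/downstream are strand-aware within
    ``flank`` bp of a gene span.
    """
    if site.chrom in genome and genome[site.chrom][site.pos0] != site.ref:
        raise ValueError(
            f"reference allele {site.ref} disagrees with genome at "
            f"{site.chrom}:{site.pos}"
        )
    candidates: List[Tuple[int, str, str]] = []
    for gene in annotation.genes_at(site.chrom, site.pos0):
        for tx in gene.transcripts:
            cls = _transcript_consequence(tx, site, genome)
            if cls is not None:
                candidates.append((_SEVERITY[cls], tx.transcript_id, cls))
    if candidates:
        candidates.sort()
        return candidates[0][2]
    flank_hits: List[Tuple[int, str, str]] = []
    for gene in annotation.genes_near(site.chrom, site.pos0, flank):
        span = gene.span
        if span.start <= site.pos0 < span.end:
            continue
        before = site.pos0 < span.start
        if gene.strand == "+":
            cls = "upstream" if before else "downstream"
        else:
            cls = "downstream" if before else "upstream"
        dist = span.start - site.pos0 if before else site.pos0 - span.end + 1
        if dist <= flank:
            flank_hits.append((dist, gene.gene_id, cls))
    if flank_hits:
        flank_hits.sort()
        return flank_hits[0][2]
    return "intergenic"
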