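"""The ordered SNV filter cascade: quality -> context -> proximity -> prevalence.

Each stage returns the surviving sites plus what it removed; ``run_cascade``
chains them and produces a per-stage accounting report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from asedit.intervals import GenomicInterval, IntervalIndex
from asedit.io_formats import GenomeAnnotation, VariantSite

#: (quality key, threshold); a site survives iff every PRESENT value is
#: strictly greater than its threshold
QUALITY_RULES: Tuple[Tuple[str, float], ...] = (
    ("MQ", 40.0),
    ("DP", 10.0),
    ("QD", 2.0),
    ("ReadPosRankSum", -8.0),
    ("MQRankSum", -12.5),
)


@dataclass
class FilterThresholds:
    mq_min: float = 40.0
    dp_min: float = 10.0
    qd_min: float = 2.0
    readpos_ranksum_min: float = -8.0
    mq_ranksum_min: float = -12.5
    junction_flank: int = 5
    paralog_flank: int = 50
    pair_window: int = 45
    triplet_window: int = 35
    prevalence_fraction: float = 0.5
    strict_quality: bool = False  # absent quality annotations fail when True

    def __post_init__(self) -> None:
        for name in ("junction_flank", "paralog_flank", "pair_window", "triplet_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.prevalence_fraction <= 1):
            raise ValueError("prevalence_fraction must be in (0, 1]")

    def quality_rules(self) -> Tuple[Tuple[str, float], ...]:
        return (
            ("MQ", self.mq_min),
            ("DP", self.dp_min),
            ("QD", self.qd_min),
            ("ReadPosRankSum", self.readpos_ranksum_min),
            ("MQRankSum", self.mq_ranksum_min),
        )


@dataclass
class FilterReport:
    rows: List[Tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_removed: int) -> None:
        self.rows.append((stage, n_in, n_removed, n_in - n_removed))

    def validate(self) -> None:
        for stage, n_in, n_removed, n_out in self.rows:
            if n_out != n_in - n_removed:
                raise AssertionError(f"stage {stage} does not balance")
        for (_, _, _, out_k), (_, in_k1, _, _) in zip(self.rows, self.rows[1:]):
            if out_k != in_k1:
                raise AssertionError("stages do not chain")

    def as_dicts(self) -> List[Dict[str, object]]:
        return [
            {"stage": s, "n_in": i, "n_removed": r, "n_out": o}
            for s, i, r, o in self.rows
        ]


def quality_filter(
    sites: Sequence[VariantSite], thresholds: FilterThresholds | None = None
) -> Tuple[List[VariantSite], List[VariantSite]]:
    """GATK-style hard thresholds; absent annotations pass unless strict."""
    th = thresholds or FilterThresholds()
    kept, removed = [], []
    rules = th.quality_rules()
    for site in sites:
        ok = True
        for key, cutoff in rules:
            if key in site.quality:
                if not (site.quality[key] > cutoff):
                    ok = False
                    break
            elif th.strict_quality:
                ok = False
                break
        (kept if ok else removed).append(site)
    return kept, removed


def context_filter(
    sites: Sequence[VariantSite],
    annotation: GenomeAnnotation,
    paralog_intervals: Sequence[GenomicInterval],
    ssr_intervals: Sequence[GenomicInterval],
    thresholds: FilterThresholds | None = None,
) -> Tuple[List[VariantSite], List[Tuple[VariantSite, List[str]]]]:
    """Remove sites near splice junctions, near paralogs, in SSRs, or in
    bidirectional-gene regions. A removed site may carry several reasons."""
    th = thresholds or FilterThresholds()
    paralog_idx = IntervalIndex.build(
        iv.expanded(th.paralog_flank) for iv in paralog_intervals
    )
    ssr_idx = IntervalIndex.build(ssr_intervals)
    kept: List[VariantSite] = []
    removed: List[Tuple[VariantSite, List[str]]] = []
    for site in sites:
        reasons = []
        d = annotation.min_junction_distance(site.chrom, site.pos0)
        if d is not None and d <= th.junction_flank:
            reasons.append("junction")
        if paralog_idx.covers(site.chrom, site.pos0):
            reasons.append("paralog")
        if ssr_idx.covers(site.chrom, site.pos0):
            reasons.append("ssr")
        if annotation.in_bidirectional(site.chrom, site.pos0):
            reasons.append("bidirectional")
        if reasons:
            removed.append((site, reasons))
        else:
            kept.append(site)
    return kept, removed


def proximity_filter(
    sites: Sequence[VariantSite],
    pair_window: int = 45,
    triplet_window: int = 35,
) -> Tuple[List[VariantSite], List[VariantSite]]:
    """Drop every participant of a pair within ``pair_window`` bp or a
    triplet spanning at most ``triplet_window`` bp (same chromosome)."""
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    doomed = set()
    by_chrom: Dict[str, List[VariantSite]] = {}
    for s in ordered:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_sites in by_chrom.values():
        n = len(chrom_sites)
        for i in range(n - 1):
            if chrom_sites[i + 1].pos - chrom_sites[i].pos <= pair_window:
                doomed.add(chrom_sites[i].key)
                doomed.add(chrom_sites[i + 1].key)
        for i in range(n - 2):
            if chrom_sites[i + 2].pos - chrom_sites[i].pos <= triplet_window:
                doomed.add(chrom_sites[i].key)
                doomed.add(chrom_sites[i + 1].key)
                doomed.add(chrom_sites[i + 2].key)
    kept = [s for s in ordered if s.key not in doomed]
    removed = [s for s in ordered if s.key in doomed]
    return kept, removed


def brute_force_proximity(
    sites: Sequence[VariantSite],
    pair_window: int = 45,
    triplet_window: int = 35,
) -> List[VariantSite]:
    """O(n^2)/O(n^3) removal oracle over all pairs and triplets."""
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    doomed = set()
    n = len(ordered)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ordered[i], ordered[j]
            if a.chrom == b.chrom and abs(a.pos - b.pos) <= pair_window:
                doomed.add(a.key)
                doomed.add(b.key)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = ordered[i], ordered[j], ordered[k]
                if a.chrom == b.chrom == c.chrom:
                    span = max(a.pos, b.pos, c.pos) - min(a.pos, b.pos, c.pos)
                    if span <= triplet_window:
                        doomed.update((a.key, b.key, c.key))
    return [s for s in ordered if s.key in doomed]


def prevalence_filter(
    sites: Sequence[VariantSite],
    n_samples: int,
    fraction: float = 0.5,
) -> Tuple[List[VariantSite], List[VariantSite]]:
    """Keep sites whose alternative allele is expressed (AAF > 0) in at
    least ``ceil(fraction x n_samples)`` samples."""
    need = math.ceil(fraction * n_samples)
    kept, removed = [], []
    for site in sites:
        n_expr = sum(
            1 for r, a in site.counts.values() if a > 0 and (r + a) > 0
        )
        (kept if n_expr >= need else removed).append(site)
    return kept, removed


def run_cascade(
    sites: Sequence[VariantSite],
    annotation: GenomeAnnotation,
    paralog_intervals: Sequence[GenomicInterval],
    ssr_intervals: Sequence[GenomicInterval],
    n_samples: int,
    thresholds: FilterThresholds | None = None,
) -> Tuple[List[VariantSite], FilterReport]:
    """Apply the four stages in the fixed order and account per stage."""
    th = thresholds or FilterThresholds()
    report = FilterReport()
    current = list(sites)

    survivors, removed_q = quality_filter(current, th)
    report.add("quality", len(current), len(removed_q))
    current = survivors

    survivors, removed_c = context_filter(
        current, annotation, paralog_intervals, ssr_intervals, th
    )
    report.add("context", len(current), len(removed_c))
    current = survivors

    survivors, removed_p = proximity_filter(current, th.pair_window, th.triplet_window)
    report.add("proximity", len(current), len(removed_p))
    current = survivors

    survivors, removed_s = prevalence_filter(current, n_samples, th.prevalence_fraction)
    report.add("prevalence", len(current), len(removed_s))
    current = survivors

    report.validate()
    return current, report
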