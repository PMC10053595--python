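"""Shared fixtures: a session-scoped synthetic cohort and a hand-derived
20-variant cascade fixture whose surviving set was enumerated manually."""

from __future__ import annotations

from typing import Dict, List, Tuple

import pytest

from asedit.intervals import GenomicInterval
from asedit.io_formats import GeneModel, GenomeAnnotation, TranscriptModel, VariantSite
from asedit.simulate import SimConfig, SimData, simulate_all

SAMPLES4 = ("EP1", "EP2", "ML1", "ML2")

PASSING_QUALITY = {
    "MQ": 60.0,
    "DP": 100.0,
    "QD": 10.0,
    "ReadPosRankSum": 0.0,
    "MQRankSum": 0.0,
}


@pytest.fixture(scope="session")
def sim_small() -> SimData:
    """2,000-site cohort on a 2 x 200 kb genome; reused across modules."""
    return simulate_all(
        SimConfig(seed=11, n_sites=2000, n_chroms=2, chrom_length=200_000, n_genes=16)
    )


def make_site(
    pos0: int,
    counts: Dict[str, Tuple[int, int]] | None = None,
    quality: Dict[str, float] | None = None,
    chrom: str = "chrT",
    ref: str = "A",
    alt: str = "G",
    vid: str | None = None,
) -> VariantSite:
    if counts is None:
        counts = {s: (10, 10) for s in SAMPLES4}
    if quality is None:
        quality = dict(PASSING_QUALITY)
    return VariantSite(
        chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, id=vid,
        quality=quality, counts=counts,
    )


def hand_annotation() -> GenomeAnnotation:
    """Three genes on chrT: a two-exon plus-strand gene (junctions at
    1200/1700), plus an opposite-strand overlapping pair giving a
    bidirectional region [3400, 3500)."""
    gene_a = GeneModel(
        "geneA", "chrT", "+",
        [TranscriptModel(
            "txA", "protein_coding", "+",
            [GenomicInterval("chrT", 1000, 1200, "+"),
             GenomicInterval("chrT", 1700, 1900, "+")],
        )],
    )
    gene_b = GeneModel(
        "geneB", "chrT", "+",
        [TranscriptModel(
            "txB", "protein_coding", "+",
            [GenomicInterval("chrT", 3000, 3200, "+"),
             GenomicInterval("chrT", 3300, 3500, "+")],
        )],
    )
    gene_c = GeneModel(
        "geneC", "chrT", "-",
        [TranscriptModel(
            "txC", "protein_coding", "-",
            [GenomicInterval("chrT", 3400, 3600, "-")],
        )],
    )
    return GenomeAnnotation([gene_a, gene_b, gene_c])


def hand_cascade_fixture():
    """20 variants exercising every cascade rule exactly once each.

    Returns (sites, annotation, paralogs, ssrs, expected_surviving_pos0,
    expected_report) where expected_report is the per-stage
    (n_in, n_removed, n_out) chain derived by hand.
    """
    paralogs = [GenomicInterval("chrT", 5000, 5100)]
    ssrs = [GenomicInterval("chrT", 6000, 6020)]
    sparse_counts = {"EP1": (20, 0), "EP2": (20, 0), "ML1": (20, 0), "ML2": (10, 5)}

    def q(key: str, value: float) -> Dict[str, float]:
        quality = dict(PASSING_QUALITY)
        quality[key] = value
        return quality

    sites = [
        make_site(200, quality=q("MQ", 35.0)),           # quality: MQ not > 40
        make_site(260, quality=q("DP", 5.0)),            # quality: DP not > 10
        make_site(320, quality=q("QD", 1.0)),            # quality: QD not > 2
        make_site(380, quality=q("ReadPosRankSum", -9)),  # quality
        make_site(440, quality=q("MQRankSum", -13.0)),   # quality
        make_site(1205),   # context: 5 bp from junction 1200 -> removed
        make_site(1206),   # 6 bp from junction -> survives
        make_site(5149),   # context: paralog end 5100 + 50 flank -> removed
        make_site(5150),   # just outside the flank -> survives
        make_site(6010),   # context: inside SSR -> removed
        make_site(3450),   # context: bidirectional region -> removed
        make_site(7000),   # proximity pair (distance 40 <= 45) -> removed
        make_site(7040),   # proximity pair partner -> removed
        make_site(7200),   # distance 50 to 7250 -> both survive
        make_site(7250),
        make_site(8400, counts=sparse_counts),  # prevalence: alt in 1 of 4
        make_site(8000),
        make_site(8100),
        make_site(8200),
        make_site(8300),
    ]
    expected_surviving_pos0 = [1206, 5150, 7200, 7250, 8000, 8100, 8200, 8300]
    expected_report = [
        ("quality", 20, 5, 15),
        ("context", 15, 4, 11),
        ("proximity", 11, 2, 9),
        ("prevalence", 9, 1, 8),
    ]
    return sites, hand_annotation(), paralogs, ssrs, expected_surviving_pos0, expected_report
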