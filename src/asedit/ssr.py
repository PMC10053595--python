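"""Microsatellite (SSR) scanning: maximal perfect tandem repeats, motif 1-6 nt.

The scanner reports every maximal run of a primitive motif whose repeat
count reaches the per-period minimum. A run is found once, under its
shortest period (primitive-motif rule), anchored at its leftmost phase.
Runs touching N are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from asedit.intervals import GenomicInterval, merge_intervals

#: conservative GMATo-like per-period repeat-count minimums
DEFAULT_MIN_REPEATS: Dict[int, int] = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SsrLocus:
    interval: GenomicInterval
    motif: str  # canonical (lexicographically smallest) rotation
    repeat_count: int

    @property
    def period(self) -> int:
        return len(self.motif)


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def _validate_min_repeats(min_repeats: Dict[int, int]) -> None:
    for period, count in min_repeats.items():
        if not (1 <= period <= 6):
            raise ValueError(f"motif length {period} outside 1..6")
        if count < 2:
            raise ValueError(f"min repeat count {count} for period {period} < 2")


def find_ssrs(
    sequence: str,
    chrom: str,
    min_repeats: Dict[int, int] | None = None,
) -> List[SsrLocus]:
    """All maximal perfect tandem repeats meeting the per-period minimums.

    The reported interval spans whole motif copies only
    (length = period x repeat_count), anchored at the run start.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    _validate_min_repeats(min_repeats)
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n_mask = arr == b"N"
    loci: List[SsrLocus] = []
    for period in sorted(min_repeats):
        min_count = min_repeats[period]
        if len(seq) < period * 2:
            continue
        match = (arr[:-period] == arr[period:]) & ~n_mask[:-period] & ~n_mask[period:]
        if not match.any():
            continue
        # maximal runs of consecutive matches
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive in match index space
        for a, c in zip(starts, ends):
            run_len = int(c) - int(a) + period  # sequence span of the run
            count = run_len // period
            if count < min_count:
                continue
            motif = seq[int(a) : int(a) + period]
            if not _is_primitive(motif):
                continue
            loci.append(
                SsrLocus(
                    interval=GenomicInterval(chrom, int(a), int(a) + count * period),
                    motif=canonical_rotation(motif),
                    repeat_count=count,
                )
            )
    loci.sort(key=lambda l: (l.interval.start, l.period))
    return loci


def brute_force_ssrs(
    sequence: str,
    chrom: str,
    min_repeats: Dict[int, int] | None = None,
) -> List[SsrLocus]:
    """Exhaustive (start, period, count) enumeration; the scanner's oracle.

    Deliberately naive: O(L x period x run length) string slicing.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    _validate_min_repeats(min_repeats)
    seq = sequence.upper()
    L = len(seq)
    loci: List[SsrLocus] = []

    def _match(i: int, p: int) -> bool:
        return (
            i + p < L
            and seq[i] == seq[i + p]
            and seq[i] != "N"
            and seq[i + p] != "N"
        )

    for period in sorted(min_repeats):
        min_count = min_repeats[period]
        for start in range(L):
            if not _match(start, period):
                continue
            if start > 0 and _match(start - 1, period):
                continue  # not a run start: left-extendable
            end_match = start
            while _match(end_match + 1, period):
                end_match += 1
            run_len = end_match - start + 1 + period
            count = run_len // period
            motif = seq[start : start + period]
            if count >= min_count and _is_primitive(motif):
                loci.append(
                    SsrLocus(
                        interval=GenomicInterval(
                            chrom, start, start + count * period
                        ),
                        motif=canonical_rotation(motif),
                        repeat_count=count,
                    )
                )
    loci.sort(key=lambda l: (l.interval.start, l.period))
    return loci


def ssr_mask(
    genome: Dict[str, str],
    min_repeats: Dict[int, int] | None = None,
) -> List[GenomicInterval]:
    """Merged per-chromosome SSR intervals — the mask the context filter uses."""
    intervals: List[GenomicInterval] = []
    for chrom in sorted(genome):
        intervals.extend(l.interval for l in find_ssrs(genome[chrom], chrom, min_repeats))
    if not intervals:
        return []
    return merge_intervals(intervals)


def ssr_bed_names(loci: Sequence[SsrLocus]) -> List[str]:
    """Name column for BED6 output: motif x count."""
    return [f"{l.motif}x{l.repeat_count}" for l in loci]
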