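"""Consensus lncRNA identification.

Structural filters (length >= 200 nt, multi-exonic, not protein-coding,
expressed) feed a 3-of-5 coding-potential vote over externally produced
predictor scores (CPAT < 0.78, CPC2 < 0, FEELnc < 0.558, CNCI and PLEK
labelled noncoding), followed by Pfam/Rfam domain exclusion. Transcripts
already annotated with an lncRNA biotype are kept as known lncRNAs and
bypass the vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

CPAT_CUTOFF = 0.78
CPC2_CUTOFF = 0.0
FEELNC_CUTOFF = 0.558
PFAM_EVALUE_MAX = 1e-3
KNOWN_LNCRNA_BIOTYPES = frozenset({"lncRNA", "lincRNA"})


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    biotype: str
    length_nt: int
    exon_count: int
    mean_expression: float

    def __post_init__(self) -> None:
        if self.length_nt < 1 or self.exon_count < 1:
            raise ValueError(f"degenerate transcript record {self.transcript_id}")


@dataclass
class CodingPotentialScores:
    cpat: Optional[float] = None
    cpc2: Optional[float] = None
    feelnc: Optional[float] = None
    cnci_label: Optional[str] = None
    plek_label: Optional[str] = None

    def __post_init__(self) -> None:
        for label in (self.cnci_label, self.plek_label):
            if label is not None and label not in ("coding", "noncoding"):
                raise ValueError(f"invalid label {label!r}")


@dataclass
class DomainEvidence:
    best_pfam_evalue: Optional[float] = None
    has_rfam_hit: bool = False

    def __post_init__(self) -> None:
        if self.best_pfam_evalue is not None and self.best_pfam_evalue <= 0:
            raise ValueError("e-value must be positive")


def structural_filter(
    transcripts: Sequence[TranscriptRecord],
    min_length: int = 200,
    min_exons: int = 2,
    min_expression: float = 0.0,
) -> Tuple[List[TranscriptRecord], List[Tuple[TranscriptRecord, str]]]:
    """Drop short, mono-exonic, protein-coding or unexpressed transcripts."""
    kept, removed = [], []
    for tx in transcripts:
        if tx.length_nt < min_length:
            removed.append((tx, "short"))
        elif tx.exon_count < min_exons:
            removed.append((tx, "mono_exonic"))
        elif tx.biotype == "protein_coding":
            removed.append((tx, "protein_coding"))
        elif tx.mean_expression < min_expression:
            removed.append((tx, "low_expression"))
        else:
            kept.append(tx)
    return kept, removed


def coding_potential_vote(scores: CodingPotentialScores) -> Optional[bool]:
    """Noncoding iff >= 3 of the available per-tool verdicts are noncoding.

    Returns None ('insufficient evidence') when fewer than 3 verdicts are
    available. All numeric cutoffs are strict inequalities.
    """
    verdicts: List[bool] = []
    if scores.cpat is not None:
        verdicts.append(scores.cpat < CPAT_CUTOFF)
    if scores.cpc2 is not None:
        verdicts.append(scores.cpc2 < CPC2_CUTOFF)
    if scores.feelnc is not None:
        verdicts.append(scores.feelnc < FEELNC_CUTOFF)
    if scores.cnci_label is not None:
        verdicts.append(scores.cnci_label == "noncoding")
    if scores.plek_label is not None:
        verdicts.append(scores.plek_label == "noncoding")
    if len(verdicts) < 3:
        return None
    return sum(verdicts) >= 3


def domain_exclusion(
    candidates: Sequence[TranscriptRecord],
    evidence: Dict[str, DomainEvidence],
    pfam_evalue_max: float = PFAM_EVALUE_MAX,
) -> Tuple[List[TranscriptRecord], List[Tuple[TranscriptRecord, str]]]:
    """Keep candidates with no meaningful Pfam similarity and no Rfam hit.

    Absent evidence counts as no hit.
    """
    kept, removed = [], []
    for tx in candidates:
        ev = evidence.get(tx.transcript_id, DomainEvidence())
        if ev.best_pfam_evalue is not None and ev.best_pfam_evalue <= pfam_evalue_max:
            removed.append((tx, "pfam_hit"))
        elif ev.has_rfam_hit:
            removed.append((tx, "rfam_hit"))
        else:
            kept.append(tx)
    return kept, removed


def identify_lncrnas(
    transcripts: Sequence[TranscriptRecord],
    scores: Dict[str, CodingPotentialScores],
    evidence: Dict[str, DomainEvidence],
    min_length: int = 200,
    min_exons: int = 2,
    min_expression: float = 0.0,
    pfam_evalue_max: float = PFAM_EVALUE_MAX,
) -> Tuple[List[TranscriptRecord], pd.DataFrame]:
    """Full cascade; returns the lncRNA set and a per-transcript audit table.

    Known-lncRNA-biotype transcripts surviving the structural filter join
    the pool directly (no vote, no domain exclusion).
    """
    audit_rows: List[Dict[str, object]] = []
    surviving, removed_struct = structural_filter(
        transcripts, min_length, min_exons, min_expression
    )
    for tx, reason in removed_struct:
        audit_rows.append(
            {"transcript_id": tx.transcript_id, "fate": "removed", "reason": reason}
        )
    final: List[TranscriptRecord] = []
    vote_pool: List[TranscriptRecord] = []
    for tx in surviving:
        if tx.biotype in KNOWN_LNCRNA_BIOTYPES:
            final.append(tx)
            audit_rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "fate": "kept",
                    "reason": "known_lncrna",
                }
            )
        else:
            vote_pool.append(tx)
    voted: List[TranscriptRecord] = []
    for tx in vote_pool:
        verdict = coding_potential_vote(
            scores.get(tx.transcript_id, CodingPotentialScores())
        )
        if verdict is None:
            audit_rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "fate": "removed",
                    "reason": "insufficient_evidence",
                }
            )
        elif not verdict:
            audit_rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "fate": "removed",
                    "reason": "coding_vote",
                }
            )
        else:
            voted.append(tx)
    kept_domain, removed_domain = domain_exclusion(voted, evidence, pfam_evalue_max)
    for tx, reason in removed_domain:
        audit_rows.append(
            {"transcript_id": tx.transcript_id, "fate": "removed", "reason": reason}
        )
    for tx in kept_domain:
        audit_rows.append(
            {"transcript_id": tx.transcript_id, "fate": "kept", "reason": "novel_lncrna"}
        )
    final.extend(kept_domain)
    final.sort(key=lambda t: t.transcript_id)
    audit = pd.DataFrame(audit_rows).sort_values("transcript_id").reset_index(drop=True)
    return final, audit


# ---------------------------------------------------------------------------
# table loaders (TSV interfaces)
# ---------------------------------------------------------------------------

def read_transcript_table(path: str) -> List[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    return [
        TranscriptRecord(
            transcript_id=str(r.transcript_id),
            gene_id=str(r.gene_id),
            biotype=str(r.biotype),
            length_nt=int(r.length_nt),
            exon_count=int(r.exon_count),
            mean_expression=float(r.mean_expression),
        )
        for r in df.itertuples(index=False)
    ]


def read_scores_table(path: str) -> Dict[str, CodingPotentialScores]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    out: Dict[str, CodingPotentialScores] = {}
    for r in df.itertuples(index=False):
        out[str(r.transcript_id)] = CodingPotentialScores(
            cpat=None if pd.isna(r.cpat) else float(r.cpat),
            cpc2=None if pd.isna(r.cpc2) else float(r.cpc2),
            feelnc=None if pd.isna(r.feelnc) else float(r.feelnc),
            cnci_label=None if pd.isna(r.cnci) else str(r.cnci),
            plek_label=None if pd.isna(r.plek) else str(r.plek),
        )
    return out


def read_domain_table(path: str) -> Dict[str, DomainEvidence]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    out: Dict[str, DomainEvidence] = {}
    for r in df.itertuples(index=False):
        out[str(r.transcript_id)] = DomainEvidence(
            best_pfam_evalue=None if pd.isna(r.best_pfam_evalue) else float(r.best_pfam_evalue),
            has_rfam_hit=bool(r.has_rfam_hit),
        )
    return out
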