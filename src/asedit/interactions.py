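"""lncRNA-gene interaction triage.

cis: differentially expressed lncRNA (DEL) and gene (DEG) on the same
chromosome within 10 kb edge-to-edge. trans: cross-sample Pearson
co-expression (|r| > 0.9, p < 0.05) backed by predicted physical binding
(LncTar-style ndG < -0.1 OR lncPro-style probability > 0.9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from asedit.intervals import GenomicInterval


@dataclass
class InteractionScore:
    del_id: str
    deg_id: str
    r: Optional[float] = None
    p_corr: Optional[float] = None
    ndg: Optional[float] = None
    binding_prob: Optional[float] = None
    mode: str = "trans"
    sign: Optional[str] = None  # positive/negative correlation, set by triage


def pearson_with_p(
    x: Sequence[float], y: Sequence[float]
) -> Optional[Tuple[float, float]]:
    """Sample Pearson r with the two-sided t-transform p-value.

    Returns None (pair skipped) for constant vectors; requires n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant expression vector; correlation undefined")
        return None
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def trans_triage(
    pairs: Sequence[InteractionScore],
    r_min: float = 0.9,
    p_max: float = 0.05,
    ndg_max: float = -0.1,
    prob_min: float = 0.9,
) -> List[InteractionScore]:
    """Keep pairs with strong significant correlation AND binding evidence."""
    kept = []
    for pair in pairs:
        if pair.r is None or pair.p_corr is None:
            continue
        corr_ok = abs(pair.r) > r_min and pair.p_corr < p_max
        binding_ok = (pair.ndg is not None and pair.ndg < ndg_max) or (
            pair.binding_prob is not None and pair.binding_prob > prob_min
        )
        if corr_ok and binding_ok:
            pair.sign = "positive" if pair.r > 0 else "negative"
            pair.mode = "trans"
            kept.append(pair)
    return kept


def cis_pairs(
    del_loci: Dict[str, GenomicInterval],
    gene_loci: Dict[str, GenomicInterval],
    window: int = 10_000,
) -> List[Tuple[str, str, int]]:
    """(del_id, gene_id, gap) for same-chromosome loci within ``window`` bp.

    Gap is edge-to-edge; overlap counts as 0.
    """
    out: List[Tuple[str, str, int]] = []
    for del_id in sorted(del_loci):
        div = del_loci[del_id]
        for gene_id in sorted(gene_loci):
            gap = div.gap_to(gene_loci[gene_id])
            if gap is not None and gap <= window:
                out.append((del_id, gene_id, gap))
    return out


def correlate_pairs(
    expression: "np.ndarray | Dict[str, Sequence[float]]",
    del_ids: Sequence[str],
    deg_ids: Sequence[str],
    ndg: Optional[Dict[Tuple[str, str], float]] = None,
    prob: Optional[Dict[Tuple[str, str], float]] = None,
) -> List[InteractionScore]:
    """All DEL x DEG Pearson correlations with binding-score joins.

    ``expression`` maps feature_id -> per-sample abundances (same sample
    order for every feature).
    """
    ndg = ndg or {}
    prob = prob or {}
    pairs: List[InteractionScore] = []
    for del_id in del_ids:
        for deg_id in deg_ids:
            rp = pearson_with_p(expression[del_id], expression[deg_id])
            pair = InteractionScore(
                del_id=del_id,
                deg_id=deg_id,
                ndg=ndg.get((del_id, deg_id)),
                binding_prob=prob.get((del_id, deg_id)),
            )
            if rp is not None:
                pair.r, pair.p_corr = rp
            pairs.append(pair)
    return pairs
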