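"""cis/trans target prediction for differentially expressed lncRNAs.

A protein-coding gene is a *cis* candidate of a lncRNA when it lies within
10 kb upstream or 100 kb downstream of the lncRNA (strand-aware, measured
as the gap between the closest span boundaries; overlap counts as distance
0) on the same chromosome; every other gene — farther away or on another
chromosome — is a *trans* candidate.  Geometry alone decides the relation;
a pair is reported only if both the Pearson and the Spearman correlation of
expression across samples reach the threshold (default 0.8, positive sign
only, both gates configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GeneModel, TranscriptModel

__all__ = [
    "TargetParams",
    "pearson",
    "spearman",
    "cis_candidates",
    "predict_targets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetParams:
    """Distance windows and correlation gates for target prediction.

    upstream_window / downstream_window: nt, relative to the lncRNA's 5'/3'
    direction by default (``strand_aware=False`` switches to genomic
    left/right, for sensitivity analysis).
    corr_threshold: both PCC and SCC must reach it.
    absolute_corr: gate on |r| instead of signed r.
    trans_requires_corr: apply the correlation gate to trans pairs too.
    min_samples: minimum number of samples for a correlation to be computed.
    """

    upstream_window: int = 10_000
    downstream_window: int = 100_000
    corr_threshold: float = 0.8
    min_samples: int = 6
    strand_aware: bool = True
    absolute_corr: bool = False
    trans_requires_corr: bool = True

    def __post_init__(self) -> None:
        if self.upstream_window < 0 or self.downstream_window < 0:
            raise ValueError("windows must be >= 0")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")


def pearson(x, y) -> float | None:
    """Product-moment correlation; None for constant vectors (pair skipped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float | None:
    """Rank correlation with average ranks for ties; None for constants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.spearmanr(x, y).statistic)


def cis_candidates(lncrna: TranscriptModel, coding_genes: Iterable[GeneModel],
                   params: TargetParams = TargetParams(),
                   ) -> dict[str, int]:
    """Coding genes within the cis windows of one lncRNA.

    Returns ``{gene_id: signed distance}``: negative = upstream of the
    lncRNA, positive = downstream, 0 = overlapping.  Upstream/downstream
    follow the lncRNA's strand when ``params.strand_aware``.
    """
    out: dict[str, int] = {}
    for g in coding_genes:
        if g.chrom != lncrna.chrom:
            continue
        d = _signed_distance(lncrna, g, params.strand_aware)
        if d == 0:
            out[g.gene_id] = 0
        elif d < 0 and -d <= params.upstream_window:
            out[g.gene_id] = d
        elif d > 0 and d <= params.downstream_window:
            out[g.gene_id] = d
    return out


def _signed_distance(lncrna: TranscriptModel, g: GeneModel,
                     strand_aware: bool) -> int:
    """Boundary gap, negative on the lncRNA's upstream side."""
    if g.start >= lncrna.end:       # gene to the genomic right
        gap = g.start - lncrna.end
        right_is_downstream = (not strand_aware) or lncrna.strand == "+"
        return gap if right_is_downstream else -gap
    if g.end <= lncrna.start:       # gene to the genomic left
        gap = lncrna.start - g.end
        left_is_upstream = (not strand_aware) or lncrna.strand == "+"
        return -gap if left_is_upstream else gap
    return 0


def predict_targets(de_lncrnas: Sequence[TranscriptModel],
                    genes: Sequence[GeneModel],
                    gene_expression: pd.DataFrame,
                    lncrna_expression: pd.DataFrame,
                    params: TargetParams = TargetParams(),
                    ) -> pd.DataFrame:
    """Predict cis and trans targets for each DE lncRNA.

    ``lncrna_expression`` has one row per lncRNA transcript id and
    ``gene_expression`` one row per gene id, over the same sample columns.
    Returns a DataFrame (lncrna_id, gene_id, relation, distance, pcc, scc)
    sorted by lncrna_id then gene_id; ``distance`` is the signed cis gap
    for same-chromosome pairs and NaN for different-chromosome pairs.
    """
    missing = [t.transcript_id for t in de_lncrnas
               if t.transcript_id not in lncrna_expression.index]
    if missing:
        raise KeyError(f"lncRNAs without expression rows: {missing}")
    if not lncrna_expression.columns.equals(gene_expression.columns):
        raise ValueError("lncRNA and gene expression must share samples")
    if lncrna_expression.shape[1] < params.min_samples:
        raise ValueError(
            f"need >= {params.min_samples} samples for correlation gates")
    rows = []
    for t in de_lncrnas:
        lx = lncrna_expression.loc[t.transcript_id].to_numpy(dtype=float)
        cis = cis_candidates(t, genes, params)
        for g in genes:
            if g.gene_id not in gene_expression.index:
                continue
            gx = gene_expression.loc[g.gene_id].to_numpy(dtype=float)
            if g.gene_id in cis:
                relation, dist = "cis", float(cis[g.gene_id])
            else:
                relation = "trans"
                dist = (float(_signed_distance(t, g, params.strand_aware))
                        if g.chrom == t.chrom else np.nan)
            if relation == "trans" and not params.trans_requires_corr:
                rows.append((t.transcript_id, g.gene_id, relation, dist,
                             np.nan, np.nan))
                continue
            pcc = pearson(lx, gx)
            scc = spearman(lx, gx)
            if pcc is None or scc is None:
                log.info("skipping %s-%s: constant expression vector",
                         t.transcript_id, g.gene_id)
                continue
            pv, sv = ((abs(pcc), abs(scc)) if params.absolute_corr
                      else (pcc, scc))
            if pv >= params.corr_threshold and sv >= params.corr_threshold:
                rows.append((t.transcript_id, g.gene_id, relation, dist,
                             pcc, scc))
    df = pd.DataFrame(
        rows, columns=["lncrna_id", "gene_id", "relation", "distance",
                       "pcc", "scc"])
    return df.sort_values(["lncrna_id", "gene_id"], kind="mergesort",
                          ignore_index=True)
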