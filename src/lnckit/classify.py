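"""Positional classification of lncRNAs relative to protein-coding genes,
plus the descriptive characterization statistics (length, exon count,
isoforms per locus, expression on log10(FPKM+1)).

Classes and precedence
----------------------
A lncRNA gets exactly one label, decided in this order:

1. ``antisense``    — any of its exons overlaps a coding exon on the
                      opposite strand;
2. ``intronic``     — it lies entirely inside a single intron of one coding
                      transcript (either strand);
3. ``other``        — any remaining overlap with a coding gene span
                      (e.g. same-strand exonic overlap);
4. ``bidirectional``— no overlap, but its 5' end sits head-to-head
                      (divergent) with a coding gene's 5' end within
                      ``bidir_window`` nt on the opposite strand;
5. ``intergenic``   — none of the above.

The precedence is a declared convention: a transcript can satisfy several
textbook definitions at once and must still receive one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .formats import Annotation, ExpressionMatrix, TranscriptModel, CODING

__all__ = [
    "CLASSES",
    "ClassifiedTranscript",
    "CodingIndex",
    "classify_lncrna",
    "classify_all",
    "nearest_gene_distance",
    "CharacterizationSummary",
    "characterize",
]

CLASSES = ("intergenic", "intronic", "antisense", "bidirectional", "other")


@dataclass(frozen=True)
class ClassifiedTranscript:
    transcript_id: str
    label: str
    nearest_coding_gene: str = ""
    distance: int | None = None  # None iff no coding gene on the chromosome

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        if self.distance is not None and self.distance < 0:
            raise ValueError("distance must be >= 0")


class CodingIndex:
    """Interval indexes over a coding annotation for fast geometry queries."""

    def __init__(self, coding: Annotation, biotype: str = CODING) -> None:
        self.genes = [g for g in coding.genes.values()
                      if g.biotype == biotype or biotype is None]
        gene_ids = {g.gene_id for g in self.genes}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        self.intron_trees: dict[str, IntervalTree] = {}
        self.genes_by_chrom: dict[str, list] = {}
        for g in self.genes:
            self.span_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g)
            self.genes_by_chrom.setdefault(g.chrom, []).append(g)
        for t in coding.transcripts.values():
            if t.gene_id not in gene_ids:
                continue
            etree = self.exon_trees.setdefault(t.chrom, IntervalTree())
            for a, b in t.exons:
                etree.addi(a, b, t.strand)
            itree = self.intron_trees.setdefault(t.chrom, IntervalTree())
            for a, b in t.introns():
                itree.addi(a, b, t.transcript_id)


def _exonic_antisense(t: TranscriptModel, index: CodingIndex) -> bool:
    tree = index.exon_trees.get(t.chrom)
    if tree is None:
        return False
    return any(iv.data != t.strand
               for a, b in t.exons for iv in tree.overlap(a, b))


def _inside_one_intron(t: TranscriptModel, index: CodingIndex) -> bool:
    tree = index.intron_trees.get(t.chrom)
    if tree is None:
        return False
    return any(iv.begin <= t.start and t.end <= iv.end
               for iv in tree.overlap(t.start, t.end))


def _span_overlap(t: TranscriptModel, index: CodingIndex) -> bool:
    tree = index.span_trees.get(t.chrom)
    return tree is not None and bool(tree.overlap(t.start, t.end))


def _bidirectional(t: TranscriptModel, index: CodingIndex, window: int) -> bool:
    for g in index.genes_by_chrom.get(t.chrom, []):
        if g.strand == t.strand:
            continue
        if abs(t.five_prime - g.five_prime) > window:
            continue
        # divergent orientation: the two 5' ends face each other
        if t.strand == "+" and g.five_prime <= t.five_prime:
            return True
        if t.strand == "-" and g.five_prime >= t.five_prime:
            return True
    return False


def nearest_gene_distance(t: TranscriptModel, index: CodingIndex,
                          ) -> tuple[str, int | None]:
    """Nearest coding gene by span-to-span gap; 0 if overlapping.

    Ties break to the smaller gene_id.  Returns ``("", None)`` when the
    chromosome carries no coding gene.
    """
    best: tuple[int, str] | None = None
    for g in index.genes_by_chrom.get(t.chrom, []):
        gap = max(g.start - t.end, t.start - g.end, 0)
        key = (gap, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return "", None
    return best[1], best[0]


def classify_lncrna(t: TranscriptModel, index: CodingIndex | Annotation,
                    bidir_window: int = 1000) -> ClassifiedTranscript:
    """Assign the positional class of one lncRNA (precedence above)."""
    if isinstance(index, Annotation):
        index = CodingIndex(index)
    if _exonic_antisense(t, index):
        label = "antisense"
    elif _inside_one_intron(t, index):
        label = "intronic"
    elif _span_overlap(t, index):
        label = "other"
    elif _bidirectional(t, index, bidir_window):
        label = "bidirectional"
    else:
        label = "intergenic"
    gene_id, dist = nearest_gene_distance(t, index)
    return ClassifiedTranscript(t.transcript_id, label, gene_id, dist)


def classify_all(lncrnas: Iterable[TranscriptModel],
                 coding: Annotation | CodingIndex,
                 bidir_window: int = 1000) -> list[ClassifiedTranscript]:
    index = coding if isinstance(coding, CodingIndex) else CodingIndex(coding)
    return [classify_lncrna(t, index, bidir_window) for t in lncrnas]


@dataclass
class CharacterizationSummary:
    """Descriptive statistics contrasting lncRNAs with mRNAs."""

    class_counts: dict[str, int]
    n_lncrna: int
    n_mrna: int
    lengths: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    exon_counts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    isoforms_per_locus: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    log_expression: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def mean_isoforms_per_locus(self, group: str) -> float:
        return float(np.mean(self.isoforms_per_locus[group]))

    def to_dict(self) -> dict:
        out = {"class_counts": dict(self.class_counts),
               "n_lncrna": self.n_lncrna, "n_mrna": self.n_mrna}
        for group in ("lncRNA", "mRNA"):
            out[group] = {
                "median_length": float(np.median(self.lengths[group])),
                "mean_length": float(np.mean(self.lengths[group])),
                "mean_exon_count": float(np.mean(self.exon_counts[group])),
                "mean_isoforms_per_locus": self.mean_isoforms_per_locus(group),
                "mean_log10_fpkm_plus1": float(np.mean(self.log_expression[group])),
            }
        return out


def characterize(lncrnas: Sequence[TranscriptModel],
                 mrnas: Sequence[TranscriptModel],
                 expression: ExpressionMatrix,
                 classifications: Sequence[ClassifiedTranscript] = (),
                 ) -> CharacterizationSummary:
    """Compute the per-group length / exon-count / isoform / expression
    distributions; expression is summarized per transcript as
    log10(mean FPKM + 1)."""
    if not lncrnas or not mrnas:
        raise ValueError("need non-empty lncRNA and mRNA sets")
    counts = {c: 0 for c in CLASSES}
    for c in classifications:
        counts[c.label] += 1
    summary = CharacterizationSummary(
        class_counts=counts, n_lncrna=len(lncrnas), n_mrna=len(mrnas))
    for name, group in (("lncRNA", lncrnas), ("mRNA", mrnas)):
        ids = [t.transcript_id for t in group]
        missing = [i for i in ids if i not in expression.fpkm.index]
        if missing:
            raise KeyError(f"transcripts without expression rows: {missing}")
        summary.lengths[name] = np.array([t.length for t in group])
        summary.exon_counts[name] = np.array([t.exon_count for t in group])
        loci: dict[str, int] = {}
        for t in group:
            loci[t.gene_id] = loci.get(t.gene_id, 0) + 1
        summary.isoforms_per_locus[name] = np.array(sorted(loci.values()))
        mean_fpkm = expression.fpkm.loc[ids].mean(axis=1).to_numpy()
        summary.log_expression[name] = np.log10(mean_fpkm + 1.0)
    return summary
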