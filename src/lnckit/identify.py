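"""lncRNA candidate identification: basic filters, coding-potential screen,
and known/novel annotation against a reference lncRNA catalog.

The screen keeps assembled transcripts that are at least 200 nt long and
expressed above a floor, discards those with protein-coding capacity, and
then splits survivors into transcripts already present in a known-lncRNA
catalog versus novel ones.  Coding potential is assessed with a transparent
open-reading-frame heuristic (longest forward-frame ATG..stop ORF); a hook
accepts precomputed labels from any external classifier instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .formats import Annotation, ExpressionMatrix, TranscriptModel

__all__ = [
    "IdentificationParams",
    "CodingPotential",
    "NoveltyCall",
    "filter_candidates",
    "coding_potential",
    "read_coding_labels",
    "annotate_novelty",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class IdentificationParams:
    """Thresholds of the identification screen.

    min_length: minimum spliced transcript length in nt (lncRNA definition).
    min_fpkm: expression floor, required in at least one sample.
    orf_codon_cutoff / orf_coverage_cutoff: a transcript is called noncoding
    only if its longest ORF is below BOTH the codon count and the fraction
    of the transcript it covers.
    """

    min_length: int = 200
    min_fpkm: float = 0.5
    orf_codon_cutoff: int = 100
    orf_coverage_cutoff: float = 0.35

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_fpkm < 0 or self.orf_codon_cutoff <= 0 or \
           not (0 < self.orf_coverage_cutoff <= 1):
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class CodingPotential:
    label: str  # "coding" | "noncoding"
    orf_codons: int
    orf_coverage: float


@dataclass(frozen=True)
class NoveltyCall:
    transcript_id: str
    status: str  # "known" | "novel"
    matched_known_id: str = ""

    def __post_init__(self) -> None:
        if (self.status == "known") != bool(self.matched_known_id):
            raise ValueError("status 'known' iff matched_known_id non-empty")


def filter_candidates(transcripts: Iterable[TranscriptModel],
                      expression: ExpressionMatrix,
                      params: IdentificationParams = IdentificationParams(),
                      ) -> list[TranscriptModel]:
    """Keep transcripts with length >= min_length and max FPKM >= min_fpkm.

    Order-stable and idempotent.  Transcripts missing from the expression
    matrix are an error (all candidates are expected to be quantified).
    """
    transcripts = list(transcripts)
    missing = [t.transcript_id for t in transcripts
               if t.transcript_id not in expression.fpkm.index]
    if missing:
        raise KeyError(f"transcripts absent from expression matrix: {missing}")
    max_fpkm = expression.fpkm.max(axis=1)
    return [t for t in transcripts
            if t.length >= params.min_length
            and max_fpkm[t.transcript_id] >= params.min_fpkm]


def _longest_orf(seq: str) -> int:
    """Longest ATG..stop ORF across the three forward frames, in codons.

    The count includes the start codon and excludes the stop.  ORFs without
    an in-frame stop are not counted (open-ended fragments carry no reliable
    coding evidence).
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    best = max(best, (i - start) // 3)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return best


def coding_potential(sequence: str,
                     params: IdentificationParams = IdentificationParams(),
                     ) -> CodingPotential:
    """ORF-based coding-potential call for a stranded transcript sequence.

    Scans the three forward frames only (assembled transcripts are already
    stranded).  Noncoding iff the longest ORF is shorter than
    ``orf_codon_cutoff`` codons AND covers less than ``orf_coverage_cutoff``
    of the transcript.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    codons = _longest_orf(seq)
    coverage = 3 * codons / len(seq)
    noncoding = codons < params.orf_codon_cutoff and \
        coverage < params.orf_coverage_cutoff
    return CodingPotential("noncoding" if noncoding else "coding",
                           codons, coverage)


def read_coding_labels(path: str | Path) -> dict[str, str]:
    """Load precomputed coding-potential labels (transcript_id TAB label).

    Lets an external classifier's verdicts replace the built-in ORF
    heuristic at the same decision point of the pipeline.
    """
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, label = line.split("\t")[:2]
            if label not in ("coding", "noncoding"):
                raise ValueError(f"label for {tid} must be coding/noncoding")
            labels[tid] = label
    return labels


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def annotate_novelty(candidates: Iterable[TranscriptModel],
                     known: Annotation,
                     min_reciprocal_overlap: float = 0.5,
                     ) -> list[NoveltyCall]:
    """Call each candidate known or novel against a reference lncRNA catalog.

    A multi-exon candidate is known iff a same-strand catalog transcript has
    the identical intron chain; a single-exon candidate is known iff a
    same-strand single-exon catalog transcript overlaps it reciprocally by
    at least ``min_reciprocal_overlap`` of both lengths.  Ties resolve to
    the lexicographically smallest matching catalog id.
    """
    chains: dict[tuple, list[str]] = {}
    singles: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in known.transcripts.values():
        if t.exon_count > 1:
            chains.setdefault((t.chrom, t.strand, t.intron_chain()), []).append(
                t.transcript_id)
        else:
            singles.setdefault((t.chrom, t.strand), []).append(t)
    calls: list[NoveltyCall] = []
    for c in candidates:
        match = ""
        if c.exon_count > 1:
            hits = chains.get((c.chrom, c.strand, c.intron_chain()), [])
            if hits:
                match = min(hits)
        else:
            hits = [k.transcript_id
                    for k in singles.get((c.chrom, c.strand), [])
                    if _reciprocal_overlap(c.span, k.span) >= min_reciprocal_overlap]
            if hits:
                match = min(hits)
        calls.append(NoveltyCall(c.transcript_id,
                                 "known" if match else "novel", match))
    return calls
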