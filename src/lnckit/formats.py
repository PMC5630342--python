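"""Readers, writers and in-memory models for the formats the pipeline touches.

Coordinate convention: all in-memory intervals are 0-based, half-open
``[start, end)``.  GTF on disk is 1-based, fully closed.  The conversion is
an exact bijection (``start_gtf = start + 1``, ``end_gtf = end``) and is
applied only at the I/O boundary, so interval arithmetic inside the package
never has to think about inclusive ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GeneModel",
    "TranscriptModel",
    "Annotation",
    "ExpressionMatrix",
    "read_gtf",
    "write_gtf",
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
    "read_term_map",
    "write_term_map",
]

CODING = "coding"
KNOWN_LNCRNA = "known_lncRNA"

#: default mapping from GTF biotype attribute values to internal biotypes
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": CODING,
    "coding": CODING,
    "mRNA": CODING,
    "lncRNA": KNOWN_LNCRNA,
    "lincRNA": KNOWN_LNCRNA,
    "known_lncRNA": KNOWN_LNCRNA,
    "noncoding": KNOWN_LNCRNA,
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class TranscriptModel:
    """An exon-resolved, stranded transcript.

    ``exons`` is a sorted list of non-overlapping 0-based half-open
    intervals, all on ``chrom``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if b <= a:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{a}, {b})"
                )
            if prev_end is not None and a < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = b

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        """Spliced length in nucleotides (sum of exon lengths)."""
        return sum(b - a for a, b in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (start for +, end for -)."""
        return self.start if self.strand == "+" else self.end

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, 5'-agnostic genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.introns())


@dataclass
class GeneModel:
    """A gene locus: the union span of its transcripts' exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str | None = None
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


class Annotation:
    """A set of genes and their transcripts with id-based lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel],
                 biotypes: Mapping[str, str] | None = None) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, GeneModel] = {}
        biotypes = biotypes or {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise FormatError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            g = self.genes.get(t.gene_id)
            if g is None:
                self.genes[t.gene_id] = GeneModel(
                    gene_id=t.gene_id, chrom=t.chrom, strand=t.strand,
                    start=t.start, end=t.end,
                    biotype=biotypes.get(t.gene_id),
                    transcript_ids=[t.transcript_id],
                )
            else:
                if g.chrom != t.chrom:
                    raise FormatError(
                        f"gene {t.gene_id} spans chromosomes {g.chrom}/{t.chrom}"
                    )
                g.start = min(g.start, t.start)
                g.end = max(g.end, t.end)
                g.transcript_ids.append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes[gene_id].transcript_ids]

    def subset(self, transcript_ids: Iterable[str]) -> "Annotation":
        ids = set(transcript_ids)
        return Annotation(
            (t for tid, t in self.transcripts.items() if tid in ids),
            biotypes={g.gene_id: g.biotype for g in self.genes.values()
                      if g.biotype is not None},
        )

    def genes_with_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == biotype]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_gtf(path: str | Path, biotype_key: str = "gene_biotype",
             biotype_map: Mapping[str, str] | None = None) -> Annotation:
    """Read a GTF file (GFF2 attribute dialect) into an :class:`Annotation`.

    Only ``exon`` features are used to build transcript models; other feature
    types are ignored.  Coordinates are converted from the file's 1-based
    inclusive convention to internal 0-based half-open intervals.  A gene's
    biotype is taken from the ``biotype_key`` attribute and translated through
    ``biotype_map`` (default :data:`DEFAULT_BIOTYPE_MAP`); genes without the
    attribute get ``biotype=None``.  Exon rows lacking ``gene_id`` are
    assigned a singleton synthetic gene named after the transcript.

    Raises :class:`FormatError` naming the offending line for malformed rows
    or inverted coordinates.
    """
    biotype_map = dict(DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map)
    exons: dict[str, dict] = {}
    biotypes: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if end <= start:
                raise FormatError(f"{path}:{lineno}: exon end {end1} <= start {start1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if not tid:
                raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
            gid = attrs.get("gene_id") or f"gene:{tid}"
            rec = exons.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise FormatError(
                    f"{path}:{lineno}: transcript {tid} switches chrom/strand"
                )
            rec["exons"].append((start, end))
            if biotype_key in attrs:
                mapped = biotype_map.get(attrs[biotype_key], attrs[biotype_key])
                biotypes[gid] = mapped
    transcripts = [
        TranscriptModel(transcript_id=tid, gene_id=rec["gene_id"],
                        chrom=rec["chrom"], strand=rec["strand"],
                        exons=rec["exons"])
        for tid, rec in exons.items()
    ]
    return Annotation(transcripts, biotypes=biotypes)


def write_gtf(annotation: Annotation, path: str | Path,
              biotype_key: str = "gene_biotype") -> None:
    """Write an annotation as GTF (1-based inclusive), one row per exon.

    ``read_gtf(write_gtf(x))`` reproduces ``x`` exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gtf produced by lnckit\n")
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            gene = annotation.genes[t.gene_id]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if gene.biotype is not None:
                attrs += f' {biotype_key} "{gene.biotype}";'
            for a, b in t.exons:
                fh.write(
                    f"{t.chrom}\tlnckit\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )


@dataclass
class ExpressionMatrix:
    """Per-transcript expression across samples with a two-group design.

    ``fpkm`` is always present; ``counts`` and ``library_sizes`` are kept
    when the matrix was built from raw fragment counts, which the exact
    count-based DE test needs.
    """

    fpkm: pd.DataFrame
    groups: dict[str, str]
    counts: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.groups if s not in self.fpkm.columns]
        if missing:
            raise FormatError(f"group samples absent from matrix: {missing}")
        labels = set(self.groups.values())
        if len(labels) != 2:
            raise FormatError(f"need exactly two groups, got {sorted(labels)}")
        if (self.fpkm.to_numpy() < 0).any():
            raise FormatError("negative expression values")
        if self.counts is not None:
            if not self.counts.index.equals(self.fpkm.index) or \
               not self.counts.columns.equals(self.fpkm.columns):
                raise FormatError("counts and fpkm dimensions differ")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    @property
    def group_labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.groups.values())))


def read_expression(path: str | Path, groups: Mapping[str, str],
                    kind: str = "fpkm",
                    library_sizes: Mapping[str, float] | None = None,
                    transcript_lengths: Mapping[str, int] | None = None,
                    ) -> ExpressionMatrix:
    """Read a TSV expression table (rows transcripts, columns samples).

    ``kind`` is ``"fpkm"`` or ``"counts"``; for counts, ``library_sizes``
    and ``transcript_lengths`` are required so FPKM can be derived.  Missing
    cells and negative values are rejected, never coerced.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise FormatError(f"missing values in expression table (rows {bad})")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric expression value: {e}") from None
    if (df.to_numpy() < 0).any():
        raise FormatError("negative expression values")
    df.index = df.index.astype(str)
    if kind == "fpkm":
        return ExpressionMatrix(fpkm=df, groups=dict(groups))
    if kind == "counts":
        if library_sizes is None or transcript_lengths is None:
            raise ValueError("counts tables need library_sizes and transcript_lengths")
        from .diffexpr import compute_fpkm

        counts = df.round().astype(int)
        if not np.allclose(df.to_numpy(), counts.to_numpy()):
            raise FormatError("counts table contains non-integer values")
        lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
        if lib.isna().any():
            raise FormatError("library size missing for some samples")
        lengths = pd.Series(transcript_lengths).reindex(counts.index)
        if lengths.isna().any():
            raise FormatError("transcript length missing for some transcripts")
        fpkm = compute_fpkm(counts, lengths, lib)
        return ExpressionMatrix(fpkm=fpkm, groups=dict(groups),
                                counts=counts, library_sizes=lib)
    raise ValueError(f"kind must be 'fpkm' or 'counts', got {kind!r}")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercase sequence}``; duplicate ids are errors."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (term_id, gene_id) into term -> gene-id set."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return terms
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            terms.setdefault(parts[0], set()).add(parts[1])
    return terms


def write_term_map(terms: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(terms):
            for gid in sorted(terms[term]):
                fh.write(f"{term}\t{gid}\n")
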