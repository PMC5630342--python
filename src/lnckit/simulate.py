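"""Synthetic fixtures with planted truth for every pipeline stage.

The generator emits a desk-scale genome — protein-coding genes, a known
lncRNA catalog, and candidate lncRNA transcripts placed constructively to
realize each positional class — together with transcript sequences (long
ORFs for coding transcripts, ORF-poor sequences for lncRNAs) and a
two-group expression matrix that mirrors the emulated study design:
3 vs 3 samples, log-normal baseline FPKM, Poisson fragment counts, a
planted fraction of differentially expressed transcripts at a fixed fold,
and planted cis lncRNA-gene pairs whose expression shares a latent factor
strong enough to push both Pearson and Spearman correlations above the
target-prediction gate.

Everything is deterministic given the seed; writing the same simulation
twice produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CLASSES, CodingIndex, classify_lncrna
from .diffexpr import compute_fpkm
from .formats import (Annotation, ExpressionMatrix, TranscriptModel,
                      CODING, KNOWN_LNCRNA, write_gtf, write_fasta,
                      write_expression)
from .identify import IdentificationParams, coding_potential
from .targets import TargetParams, cis_candidates

__all__ = [
    "SimulationParams",
    "PlantedTruth",
    "SyntheticGenome",
    "generate_annotation",
    "simulate_expression",
    "simulate_counts",
    "write_fixture",
]

GROUP_A = "HBV_neg"
GROUP_B = "HBV_pos"

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join((a, b, c))
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults emulate the study design
    (two groups of three samples) at desk scale.

    baseline_log_mean/sd parameterize the natural-log FPKM baseline
    (median ~1.6 FPKM); library_size is fragments per sample;
    de_fraction/de_fold plant the differential-expression truth;
    cis_latent_sd is the ln-scale strength of the factor shared by planted
    cis pairs (1.5 dominates the 0.1 residual noise, driving PCC and SCC
    well above 0.8 across the six samples); planted pair members are
    well-expressed — their expected per-sample fragment count is floored
    at cis_min_base_count, since at three replicates per group a
    correlation signature is only recoverable for abundant transcripts;
    overdispersion > 0 switches
    Poisson counts to negative binomial with that dispersion.
    """

    n_chroms: int = 3
    chrom_length: int = 3_000_000
    n_coding_genes: int = 60
    n_known_lncrnas: int = 40
    n_novel_lncrnas: int = 40
    class_mix: tuple[tuple[str, float], ...] = (
        ("intergenic", 0.66), ("intronic", 0.06), ("antisense", 0.09),
        ("bidirectional", 0.01), ("other", 0.18),
    )
    samples_per_group: int = 3
    baseline_log_mean: float = 0.5
    baseline_log_sd: float = 1.2
    de_fraction: float = 0.10
    de_fold: float = 4.0
    n_cis_pairs: int = 20
    cis_latent_sd: float = 1.5
    cis_min_base_count: float = 2000.0
    residual_log_sd: float = 0.1
    library_size: int = 20_000_000
    overdispersion: float = 0.0
    bidir_window: int = 1000

    def __post_init__(self) -> None:
        mix = dict(self.class_mix)
        if set(mix) - set(CLASSES):
            raise ValueError(f"unknown classes in mix: {set(mix) - set(CLASSES)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")
        for name in ("n_chroms", "chrom_length", "n_coding_genes",
                     "samples_per_group", "library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, serializable as JSON."""

    de: dict[str, dict] = field(default_factory=dict)        # tid -> {direction, fold}
    classes: dict[str, str] = field(default_factory=dict)    # lnc tid -> class
    novelty: dict[str, str] = field(default_factory=dict)    # lnc tid -> known/novel
    cis_pairs: list[dict] = field(default_factory=list)      # {lncrna_id, gene_id}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class SyntheticGenome:
    """Annotation bundle produced by :func:`generate_annotation`."""

    reference: Annotation   # coding genes + known lncRNA catalog
    candidates: Annotation  # assembled candidate lncRNAs
    sequences: dict[str, str]  # candidate and coding transcript sequences
    truth: PlantedTruth

    @property
    def coding_transcripts(self) -> list[TranscriptModel]:
        coding_genes = {g.gene_id for g in self.reference.genes.values()
                        if g.biotype == CODING}
        return [t for t in self.reference.transcripts.values()
                if t.gene_id in coding_genes]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _noncoding_seq(rng: np.random.Generator, n: int) -> str:
    params = IdentificationParams()
    for _ in range(100):
        s = _random_seq(rng, n)
        if coding_potential(s, params).label == "noncoding":
            return s
    raise RuntimeError(f"could not draw an ORF-poor sequence of length {n}")


def _coding_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence of length n containing an ORF of >= 120 codons."""
    if n < 380:
        raise ValueError("coding transcripts must be >= 380 nt")
    utr5 = int(rng.integers(5, 30))
    n_codons = min((n - utr5 - 3) // 3, max(120, (n - utr5 - 3) // 3 - 10))
    orf = "ATG" + "".join(rng.choice(_SENSE_CODONS)
                          for _ in range(n_codons - 1)) + "TAA"
    tail = n - utr5 - len(orf)
    return _random_seq(rng, utr5) + orf + _random_seq(rng, tail)


def _class_counts(mix: Mapping[str, float], total: int) -> dict[str, int]:
    # largest-remainder apportionment so counts sum exactly to total
    raw = {c: mix.get(c, 0.0) * total for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = total - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True):
        if short == 0:
            break
        counts[c] += 1
        short -= 1
    return counts


def _make_coding_transcripts(rng: np.random.Generator, chrom: str,
                             slot: tuple[int, int], gid: str,
                             ) -> list[TranscriptModel]:
    slot_start, slot_end = slot
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 13))
    if n_exons == 1:
        exon_lens = [int(rng.integers(600, 2000))]
        intron_lens: list[int] = []
    else:
        exon_lens = list(rng.integers(150, 300, n_exons))
        if sum(exon_lens) < 500:
            exon_lens[0] += 500 - sum(exon_lens)
        intron_lens = list(rng.integers(200, 2000, n_exons - 1))
    footprint = sum(exon_lens) + sum(intron_lens)
    room = slot_end - slot_start - footprint
    if room <= 0:
        raise ValueError(
            f"chromosome too short: gene footprint {footprint} exceeds slot")
    start = slot_start + int(rng.integers(0, room))
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el) + (int(intron_lens[i]) if i < len(intron_lens) else 0)
    out = [TranscriptModel(f"{gid}.1", gid, chrom, strand, exons)]
    # occasional second isoform sharing the intron chain minus one exon
    if n_exons >= 3 and rng.random() < 0.4:
        out.append(TranscriptModel(f"{gid}.2", gid, chrom, strand, exons[:-1]))
    return out


def _overlaps_any(span: tuple[int, int],
                  occupied: Sequence[tuple[int, int]]) -> bool:
    return any(a < span[1] and span[0] < b for a, b in occupied)


def _propose_lncrna(rng: np.random.Generator, label: str, tid: str,
                    chroms: list[str], chrom_length: int,
                    coding: list[TranscriptModel],
                    params: SimulationParams) -> TranscriptModel | None:
    if label == "intergenic":
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(300, 2000))
        start = int(rng.integers(1000, chrom_length - length - 1000))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.3 and length > 700:  # occasional 2-exon lncRNA
            e1 = int(rng.integers(200, length - 400))
            gap = int(rng.integers(200, 1500))
            exons = [(start, start + e1),
                     (start + e1 + gap, start + gap + length)]
        else:
            exons = [(start, start + length)]
        return TranscriptModel(tid, f"gene:{tid}", chrom, strand, exons)
    host = coding[int(rng.integers(len(coding)))]
    if label == "intronic":
        introns = [iv for iv in host.introns() if iv[1] - iv[0] >= 1400]
        if not introns:
            return None
        a, b = introns[int(rng.integers(len(introns)))]
        length = int(rng.integers(300, min(1200, b - a - 250)))
        start = a + int(rng.integers(100, b - a - length - 100))
        strand = "+" if rng.random() < 0.5 else "-"
        return TranscriptModel(tid, f"gene:{tid}", host.chrom, strand,
                               [(start, start + length)])
    if label in ("antisense", "other"):
        a, b = host.exons[int(rng.integers(host.exon_count))]
        left = int(rng.integers(50, 400))
        right = int(rng.integers(50, 400))
        mid = (a + b) // 2
        strand = ({"+": "-", "-": "+"}[host.strand]
                  if label == "antisense" else host.strand)
        return TranscriptModel(tid, f"gene:{tid}", host.chrom, strand,
                               [(max(0, mid - left), mid + right)])
    if label == "bidirectional":
        gap = int(rng.integers(50, params.bidir_window - 200))
        length = int(rng.integers(300, 1500))
        if host.strand == "+":
            end = host.start - gap
            if end - length < 0:
                return None
            return TranscriptModel(tid, f"gene:{tid}", host.chrom, "-",
                                   [(end - length, end)])
        start = host.end + gap
        if start + length > chrom_length:
            return None
        return TranscriptModel(tid, f"gene:{tid}", host.chrom, "+",
                               [(start, start + length)])
    raise ValueError(f"unknown class {label!r}")


def generate_annotation(params: SimulationParams = SimulationParams(),
                        seed: int = 0) -> SyntheticGenome:
    """Build the synthetic genome: coding genes, known lncRNA catalog,
    candidate lncRNAs realizing the requested class mix, and sequences.

    Candidates are placed constructively and each placement is verified
    against :func:`lnckit.classify.classify_lncrna`; the first
    ``n_known_lncrnas`` placed candidates are copied (new ids) into the
    known catalog, planting the known/novel truth.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(params.n_chroms)]

    # --- coding genes on regular slots with jitter
    per_chrom = np.full(params.n_chroms, params.n_coding_genes // params.n_chroms)
    per_chrom[: params.n_coding_genes % params.n_chroms] += 1
    coding_transcripts: list[TranscriptModel] = []
    biotypes: dict[str, str] = {}
    g = 0
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        slot_w = params.chrom_length // n
        if slot_w < 40_000:
            raise ValueError(
                f"chromosome too short: {n} genes need >= {n * 40_000} bp, "
                f"have {params.chrom_length}")
        for s in range(n):
            gid = f"PCG{g:04d}"
            margin = slot_w // 5
            slot = (s * slot_w + margin, (s + 1) * slot_w - margin)
            coding_transcripts.extend(
                _make_coding_transcripts(rng, chrom, slot, gid))
            biotypes[gid] = CODING
            g += 1

    coding_ann = Annotation(coding_transcripts, biotypes=biotypes)
    index = CodingIndex(coding_ann)

    # --- lncRNA candidates, class by class, verified against the classifier
    n_cand = params.n_known_lncrnas + params.n_novel_lncrnas
    counts = _class_counts(dict(params.class_mix), n_cand)
    labels = [c for c in CLASSES for _ in range(counts[c])]
    labels = [labels[i] for i in rng.permutation(n_cand)]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    candidates: list[TranscriptModel] = []
    truth = PlantedTruth()
    for i, label in enumerate(labels):
        tid = f"LNC{i:04d}"
        placed = None
        for _ in range(500):
            t = _propose_lncrna(rng, label, tid, chroms, params.chrom_length,
                                coding_transcripts, params)
            if t is None or _overlaps_any(t.span, occupied[t.chrom]):
                continue
            if classify_lncrna(t, index, params.bidir_window).label == label:
                placed = t
                break
        if placed is None:
            raise RuntimeError(f"could not place a {label} lncRNA (id {tid})")
        occupied[placed.chrom].append(placed.span)
        candidates.append(placed)
        truth.classes[tid] = label

    # --- known catalog: copies of the first n_known candidates
    known_transcripts: list[TranscriptModel] = []
    for i, t in enumerate(candidates):
        if i < params.n_known_lncrnas:
            kid = f"KLNC{i:04d}"
            known_transcripts.append(TranscriptModel(
                kid, f"gene:{kid}", t.chrom, t.strand, list(t.exons)))
            biotypes[f"gene:{kid}"] = KNOWN_LNCRNA
            truth.novelty[t.transcript_id] = "known"
        else:
            truth.novelty[t.transcript_id] = "novel"

    reference = Annotation(coding_transcripts + known_transcripts,
                           biotypes=biotypes)
    cand_ann = Annotation(candidates)

    sequences = {t.transcript_id: _noncoding_seq(rng, t.length)
                 for t in candidates}
    for t in coding_transcripts:
        sequences[t.transcript_id] = _coding_seq(rng, max(t.length, 380))

    return SyntheticGenome(reference=reference, candidates=cand_ann,
                           sequences=sequences, truth=truth)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray,
                 overdispersion: float) -> np.ndarray:
    if overdispersion <= 0:
        return rng.poisson(lam)
    # NB with mean lam, variance lam + phi*lam^2
    r = 1.0 / overdispersion
    return rng.negative_binomial(r, r / (r + lam))


def _simulate_core(tids: list[str], lengths: np.ndarray,
                   cis_groups: list[tuple[str, list[str], str]],
                   forced_de: list[list[str]],
                   params: SimulationParams, rng: np.random.Generator,
                   truth: PlantedTruth) -> ExpressionMatrix:
    n = len(tids)
    n_samples = 2 * params.samples_per_group
    samples = [f"{GROUP_A}_{i + 1}" for i in range(params.samples_per_group)] + \
              [f"{GROUP_B}_{i + 1}" for i in range(params.samples_per_group)]
    groups = {s: (GROUP_A if s.startswith(GROUP_A) else GROUP_B)
              for s in samples}
    b_cols = np.arange(params.samples_per_group, n_samples)
    pos = {tid: i for i, tid in enumerate(tids)}

    mu = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, n)
    mean = np.tile(mu[:, None], (1, n_samples))

    # planted DE: forced blocks (cis pairs) first, then random fill
    n_de = int(round(params.de_fraction * n))
    forced_ids = [tid for block in forced_de for tid in block]
    free = [i for i, tid in enumerate(tids) if tid not in set(forced_ids)]
    n_fill = max(0, n_de - len(forced_ids))
    fill_idx = rng.choice(len(free), size=min(n_fill, len(free)),
                          replace=False) if n_fill else np.array([], dtype=int)
    de_blocks = [[tids[free[i]]] for i in sorted(fill_idx)] + forced_de
    for block in de_blocks:
        up = bool(rng.random() < 0.5)
        factor = params.de_fold if up else 1.0 / params.de_fold
        for tid in block:
            mean[pos[tid], b_cols] = mu[pos[tid]] * factor
            truth.de[tid] = {"direction": "up" if up else "down",
                             "fold": params.de_fold}

    # shared latent factor for planted cis pairs; members get an expected-
    # count floor and the factor is drawn stratified (permuted normal
    # quantiles) so counting noise cannot scramble the planted rank order
    a = params.cis_latent_sd
    depth = params.library_size / 1e6
    quantiles = stats.norm.ppf((np.arange(n_samples) + 0.5) / n_samples)
    for lnc_tid, gene_tids, gene_id in cis_groups:
        for tid in [lnc_tid, *gene_tids]:
            base = mu[pos[tid]] * lengths[pos[tid]] / 1e3 * depth
            if base < params.cis_min_base_count:
                boost = params.cis_min_base_count / base
                mean[pos[tid], :] *= boost
                mu[pos[tid]] *= boost
        f = quantiles[rng.permutation(n_samples)]
        scale = np.exp(a * f - a * a / 2.0)
        for tid in [lnc_tid, *gene_tids]:
            eps = rng.normal(0.0, params.residual_log_sd, n_samples)
            mean[pos[tid], :] *= scale * np.exp(eps)
        truth.cis_pairs.append({"lncrna_id": lnc_tid, "gene_id": gene_id})

    lam = mean * (lengths[:, None] / 1e3) * (params.library_size / 1e6)
    counts = _draw_counts(rng, lam, params.overdispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                             columns=samples)
    libs = pd.Series(float(params.library_size), index=samples)
    fpkm = compute_fpkm(counts_df, pd.Series(lengths, index=tids), libs)
    return ExpressionMatrix(fpkm=fpkm, groups=groups, counts=counts_df,
                            library_sizes=libs)


def simulate_expression(genome: SyntheticGenome,
                        params: SimulationParams = SimulationParams(),
                        seed: int = 0,
                        ) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate counts/FPKM for all candidate lncRNAs and coding transcripts.

    Plants ``n_cis_pairs`` cis lncRNA-gene pairs among candidates that have
    a coding gene within the cis windows; pair members share a latent
    factor and a common differential-expression shift (the paired gene is
    regulated by its lncRNA), and planted cis lncRNAs are always part of
    the DE truth so the downstream target-prediction stage sees them.
    """
    rng = np.random.default_rng(seed)
    truth = PlantedTruth(classes=dict(genome.truth.classes),
                         novelty=dict(genome.truth.novelty))
    coding = genome.coding_transcripts
    lnc = [genome.candidates.transcripts[tid]
           for tid in sorted(genome.candidates.transcripts)]
    tids = [t.transcript_id for t in lnc] + [t.transcript_id for t in coding]
    lengths = np.array([genome.candidates.transcripts[t].length for t in
                        (x.transcript_id for x in lnc)] +
                       [t.length for t in coding], dtype=float)

    coding_genes = [g for g in genome.reference.genes.values()
                    if g.biotype == CODING]
    tp = TargetParams()
    eligible: list[tuple[str, list[str], str]] = []
    for t in lnc:
        cis = cis_candidates(t, coding_genes, tp)
        if not cis:
            continue
        gene_id = min(cis, key=lambda g: (abs(cis[g]), g))
        gene_tids = genome.reference.genes[gene_id].transcript_ids
        eligible.append((t.transcript_id, list(gene_tids), gene_id))
    used_genes: set[str] = set()
    cis_groups = []
    if params.n_cis_pairs:
        for i in rng.permutation(len(eligible)):
            lnc_tid, gene_tids, gene_id = eligible[i]
            if gene_id in used_genes:  # one latent factor per gene
                continue
            used_genes.add(gene_id)
            cis_groups.append((lnc_tid, gene_tids, gene_id))
            if len(cis_groups) == params.n_cis_pairs:
                break
        else:
            raise RuntimeError(
                f"only {len(cis_groups)} lncRNAs pair with a distinct gene "
                f"within the cis windows; cannot plant "
                f"{params.n_cis_pairs} pairs")
        cis_groups.sort(key=lambda g: g[0])
    forced_de = [[lnc_tid, *gene_tids] for lnc_tid, gene_tids, _ in cis_groups]
    matrix = _simulate_core(tids, lengths, cis_groups, forced_de,
                            params, rng, truth)
    return matrix, truth


def simulate_counts(n_transcripts: int,
                    params: SimulationParams = SimulationParams(),
                    seed: int = 0) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Annotation-free expression simulation for calibration studies.

    Draws transcript lengths log-normally (median ~1.1 kb) and plants DE
    per ``params`` with no cis structure; useful for type-I-error and
    power analyses of the DE stage alone.
    """
    rng = np.random.default_rng(seed)
    tids = [f"T{i:05d}" for i in range(n_transcripts)]
    lengths = np.clip(rng.lognormal(7.0, 0.6, n_transcripts), 200, 20_000)
    lengths = np.round(lengths)
    truth = PlantedTruth()
    matrix = _simulate_core(tids, lengths, [], [], params, rng, truth)
    return matrix, truth


def write_fixture(outdir: str | Path, genome: SyntheticGenome,
                  expression: ExpressionMatrix, truth: PlantedTruth,
                  force: bool = False) -> dict[str, Path]:
    """Materialize a fixture: reference.gtf, candidates.gtf, sequences.fa,
    counts.tsv, samples.tsv, truth.json.  Refuses to write into a
    non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    paths = {name: outdir / fname for name, fname in [
        ("reference", "reference.gtf"), ("candidates", "candidates.gtf"),
        ("sequences", "sequences.fa"), ("counts", "counts.tsv"),
        ("samples", "samples.tsv"), ("truth", "truth.json")]}
    write_gtf(genome.reference, paths["reference"])
    write_gtf(genome.candidates, paths["candidates"])
    write_fasta(dict(sorted(genome.sequences.items())), paths["sequences"])
    write_expression(expression.counts, paths["counts"])
    samples = pd.DataFrame({
        "sample_id": expression.sample_ids,
        "group": [expression.groups[s] for s in expression.sample_ids],
        "library_size": [int(expression.library_sizes[s])
                         for s in expression.sample_ids],
    })
    samples.to_csv(paths["samples"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
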