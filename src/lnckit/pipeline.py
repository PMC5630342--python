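"""End-to-end orchestration: identify -> classify -> diffexpr -> targets ->
enrich, with every intermediate materialized as TSV so any stage can be
re-run in isolation, and a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CodingIndex, classify_all, characterize
from .diffexpr import DEParams, call_de
from .enrich import enrich
from .formats import (CODING, KNOWN_LNCRNA, read_gtf, read_fasta,
                      read_term_map, read_expression)
from .identify import (IdentificationParams, filter_candidates,
                       coding_potential, read_coding_labels, annotate_novelty)
from .targets import TargetParams, predict_targets

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_all",
           "volcano_table"]

log = logging.getLogger(__name__)

P_CAP = 1e-300  # p = 0 is reported as -log10(P_CAP) in the volcano table


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters; loadable from YAML or JSON."""

    reference_gtf: str
    candidates_gtf: str
    sequences_fasta: str
    counts_tsv: str
    samples_tsv: str
    out_dir: str
    term_map_tsv: str | None = None
    coding_labels_tsv: str | None = None
    seed: int = 0
    bidir_window: int = 1000
    enrich_method: str = "wallenius"
    identification: IdentificationParams = field(
        default_factory=IdentificationParams)
    de: DEParams = field(default_factory=DEParams)
    targets: TargetParams = field(default_factory=TargetParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key, klass in [("identification", IdentificationParams),
                           ("de", DEParams), ("targets", TargetParams)]:
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Per-stage counts plus a parameter echo; internally consistent
    (class counts sum to classified transcripts, up+down = DE total)."""

    counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """(transcript_id, log2fc, -log10 p, significant) from a DE table."""
    neglog = -np.log10(np.maximum(de["p"].to_numpy(), P_CAP))
    return pd.DataFrame({
        "transcript_id": de.index,
        "log2fc": de["log2fc"].to_numpy(),
        "neg_log10_p": neglog,
        "significant": (de["direction"] != "ns").to_numpy(),
    })


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, e) from e
            log.info("stage %-9s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _read_samples(path: str | Path) -> tuple[dict[str, str], dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group", "library_size"):
        if col not in df.columns:
            raise ValueError(f"samples table lacks column {col!r}")
    groups = dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))
    libs = dict(zip(df["sample_id"].astype(str),
                    df["library_size"].astype(float)))
    return groups, libs


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the whole pipeline; writes all tables into ``out_dir`` and
    returns the run report (also written as ``report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(params=config.echo(), seed=config.seed)

    @_stage("load")
    def load():
        reference = read_gtf(config.reference_gtf)
        candidates = read_gtf(config.candidates_gtf)
        sequences = read_fasta(config.sequences_fasta)
        groups, libs = _read_samples(config.samples_tsv)
        lengths = {t.transcript_id: t.length
                   for ann in (reference, candidates)
                   for t in ann.transcripts.values()}
        expression = read_expression(config.counts_tsv, groups, kind="counts",
                                     library_sizes=libs,
                                     transcript_lengths=lengths)
        return reference, candidates, sequences, expression

    reference, candidates, sequences, expression = load()
    coding_ann = reference.subset(
        tid for g in reference.genes.values() if g.biotype == CODING
        for tid in g.transcript_ids)
    known_lnc = reference.subset(
        tid for g in reference.genes.values() if g.biotype == KNOWN_LNCRNA
        for tid in g.transcript_ids)

    @_stage("identify")
    def identify():
        cand_list = [candidates.transcripts[t] for t in
                     sorted(candidates.transcripts)]
        survivors = filter_candidates(cand_list, expression,
                                      config.identification)
        labels = (read_coding_labels(config.coding_labels_tsv)
                  if config.coding_labels_tsv else {})
        kept = []
        for t in survivors:
            label = labels.get(t.transcript_id)
            if label is None:
                seq = sequences.get(t.transcript_id)
                if seq is None:
                    raise KeyError(f"no sequence for {t.transcript_id}")
                label = coding_potential(seq, config.identification).label
            if label == "noncoding":
                kept.append(t)
        novelty = annotate_novelty(kept, known_lnc)
        df = pd.DataFrame({
            "transcript_id": [t.transcript_id for t in kept],
            "length": [t.length for t in kept],
            "exon_count": [t.exon_count for t in kept],
            "status": [c.status for c in novelty],
            "matched_known_id": [c.matched_known_id for c in novelty],
        })
        df.to_csv(out / "identified.tsv", sep="\t", index=False)
        report.counts.update(
            n_candidates=len(cand_list), n_after_basic_filters=len(survivors),
            n_noncoding=len(kept),
            n_known=sum(c.status == "known" for c in novelty),
            n_novel=sum(c.status == "novel" for c in novelty))
        return kept

    lncrnas = identify()

    @_stage("classify")
    def classify_stage():
        index = CodingIndex(coding_ann)
        classes = classify_all(lncrnas, index, config.bidir_window)
        df = pd.DataFrame({
            "transcript_id": [c.transcript_id for c in classes],
            "class": [c.label for c in classes],
            "nearest_gene": [c.nearest_coding_gene for c in classes],
            "distance": [(-1 if c.distance is None else c.distance)
                         for c in classes],
        })
        df.to_csv(out / "classification.tsv", sep="\t", index=False)
        mrnas = [coding_ann.transcripts[t] for t in
                 sorted(coding_ann.transcripts)]
        summary = characterize(lncrnas, mrnas, expression, classes)
        with open(out / "characterization.json", "w", encoding="utf-8") as fh:
            json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        report.counts["class_counts"] = summary.class_counts
        return classes

    classify_stage()

    @_stage("diffexpr")
    def de_stage():
        de = call_de(expression, config.de)
        de.to_csv(out / "de.tsv", sep="\t")
        volcano_table(de).to_csv(out / "volcano.tsv", sep="\t", index=False)
        lnc_ids = {t.transcript_id for t in lncrnas}
        de_lnc = de.loc[de.index.isin(lnc_ids) & (de["direction"] != "ns")]
        de_mrna = de.loc[~de.index.isin(set(candidates.transcripts)) &
                         (de["direction"] != "ns")]
        report.counts.update(
            n_de_lncrna=int(len(de_lnc)),
            n_de_lncrna_up=int((de_lnc["direction"] == "up").sum()),
            n_de_lncrna_down=int((de_lnc["direction"] == "down").sum()),
            n_de_mrna=int(len(de_mrna)))
        return de

    de = de_stage()

    @_stage("targets")
    def targets_stage():
        lnc_ids = [t.transcript_id for t in lncrnas]
        de_lnc_ids = [i for i in de.index
                      if i in set(lnc_ids) and de.loc[i, "direction"] != "ns"]
        de_lnc = [t for t in lncrnas if t.transcript_id in set(de_lnc_ids)]
        genes = sorted((g for g in coding_ann.genes.values()),
                       key=lambda g: g.gene_id)
        # gene-level expression: sum of the gene's transcript FPKM rows
        rows = {g.gene_id: expression.fpkm.loc[g.transcript_ids].sum(axis=0)
                for g in genes}
        gene_expr = pd.DataFrame(rows).T
        lnc_expr = expression.fpkm.loc[lnc_ids]
        pairs = predict_targets(de_lnc, genes, gene_expr, lnc_expr,
                                config.targets)
        pairs.to_csv(out / "targets.tsv", sep="\t", index=False)
        report.counts.update(
            n_cis_pairs=int((pairs["relation"] == "cis").sum()),
            n_trans_pairs=int((pairs["relation"] == "trans").sum()))
        return pairs

    pairs = targets_stage()

    @_stage("enrich")
    def enrich_stage():
        if not config.term_map_tsv:
            report.counts["n_enriched_terms"] = 0
            return None
        term_map = read_term_map(config.term_map_tsv)
        expressed = [g.gene_id for g in coding_ann.genes.values()
                     if expression.fpkm.loc[g.transcript_ids].to_numpy().max() > 0]
        de_genes = {coding_ann.transcripts[tid].gene_id
                    for tid in de.index[de["direction"] != "ns"]
                    if tid in coding_ann.transcripts}
        de_genes &= set(expressed)
        lengths = {g.gene_id: float(np.median(
            [coding_ann.transcripts[t].length for t in g.transcript_ids]))
            for g in coding_ann.genes.values()}
        table = enrich(de_genes, expressed, term_map, gene_lengths=lengths,
                       method=config.enrich_method)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report.counts["n_enriched_terms"] = int((table["q"] <= 0.05).sum())
        return table

    enrich_stage()
    report.to_json(out / "report.json")
    return report
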