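"""Correlations, cis windows, and target prediction on planted fixtures."""

import numpy as np
import pandas as pd
import pytest

from lnckit.formats import GeneModel, TranscriptModel, CODING
from lnckit.targets import (TargetParams, cis_candidates, pearson,
                            predict_targets, spearman)

from conftest import random_toy_genome
from oracles import cis_candidates_brute


class TestCorrelations:
    def test_linear_relation(self):
        x = np.arange(1, 7)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert spearman(x, 2 * x + 1) == pytest.approx(1.0)

    def test_reversal(self):
        x = np.arange(1, 7, dtype=float)
        assert pearson(x, x[::-1]) == pytest.approx(-1.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_ranks_manual_oracle(self):
        # ranks of x=(1,2,2,3) are (1, 2.5, 2.5, 4); hand-expanded Pearson
        # of the rank vectors gives 4.5 / sqrt(4.5 * 5)
        want = 4.5 / np.sqrt(4.5 * 5.0)
        assert spearman([1, 2, 2, 3], [1, 3, 2, 4]) == pytest.approx(want)

    def test_constant_vector_signals_undefined(self):
        assert pearson([1, 1, 1, 1], [1, 2, 3, 4]) is None
        assert spearman([1, 2, 3, 4], [2, 2, 2, 2]) is None

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


def _gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, chrom, strand, start, end, biotype=CODING,
                     transcript_ids=[f"{gid}.1"])


class TestCisCandidates:
    def test_upstream_and_downstream_boundaries(self):
        lnc = TranscriptModel("l", "lg", "chr1", "+", [(100_000, 102_000)])
        genes = [
            _gene("up_in", "chr1", 80_000, 95_000),      # gap 5000 upstream
            _gene("up_out", "chr1", 70_000, 89_999),     # gap 10001
            _gene("up_edge", "chr1", 70_000, 90_000),    # gap exactly 10000
            _gene("down_in", "chr1", 150_000, 160_000),  # gap 48000 downstream
            _gene("down_edge", "chr1", 202_000, 210_000),  # gap exactly 100000
            _gene("down_out", "chr1", 202_001, 210_000),   # gap 100001
            _gene("overlap", "chr1", 101_000, 103_000),
            _gene("elsewhere", "chr2", 100_000, 101_000),
        ]
        got = cis_candidates(lnc, genes)
        assert got == {"up_in": -5000, "up_edge": -10_000,
                       "down_in": 48_000, "down_edge": 100_000, "overlap": 0}

    def test_strand_awareness_flips_windows(self):
        lnc = TranscriptModel("l", "lg", "chr1", "-", [(100_000, 102_000)])
        genes = [_gene("left", "chr1", 40_000, 50_000),    # 50 kb genomic-left
                 _gene("right", "chr1", 107_000, 110_000)]  # 5 kb genomic-right
        got = cis_candidates(lnc, genes)
        # for a - strand lncRNA, genomic-left is downstream, right is upstream
        assert got == {"left": 50_000, "right": -5000}
        agnostic = cis_candidates(lnc, genes,
                                  TargetParams(strand_aware=False))
        assert agnostic == {"right": 5000}

    def test_matches_exhaustive_scan_on_random_genomes(self):
        rng = np.random.default_rng(31)
        mismatches = 0
        for _ in range(100):
            coding, lncs = random_toy_genome(
                rng, n_coding=int(rng.integers(3, 15)),
                n_lnc=int(rng.integers(3, 15)), chrom_length=400_000)
            genes = []
            spans = {}
            for t in coding:
                s, e = spans.get(t.gene_id, (t.start, t.end))
                spans[t.gene_id] = (min(s, t.start), max(e, t.end))
            for t in coding:
                if t.gene_id in spans:
                    s, e = spans.pop(t.gene_id)
                    genes.append(GeneModel(t.gene_id, t.chrom, t.strand,
                                           s, e, biotype=CODING))
            for lnc in lncs:
                got = cis_candidates(lnc, genes)
                want = cis_candidates_brute(lnc, genes)
                mismatches += got != want
        assert mismatches == 0


class TestPredictTargets:
    def _setup(self):
        lnc = TranscriptModel("l1", "lg", "chr1", "+", [(100_000, 101_000)])
        near = _gene("near", "chr1", 150_000, 155_000)   # 49 kb downstream
        far = _gene("far", "chr1", 900_000, 905_000)
        other = _gene("other", "chr2", 100_000, 105_000)
        rng = np.random.default_rng(0)
        base = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        noise = rng.normal(0, 0.01, 6)
        samples = [f"s{i}" for i in range(6)]
        lnc_expr = pd.DataFrame([base], index=["l1"], columns=samples)
        gene_expr = pd.DataFrame(
            [base * 2 + noise, 100.0 - 2 * base, base * 1.5],
            index=["near", "far", "other"], columns=samples)
        return lnc, [near, far, other], gene_expr, lnc_expr

    def test_cis_and_trans_relations(self):
        lnc, genes, gene_expr, lnc_expr = self._setup()
        pairs = predict_targets([lnc], genes, gene_expr, lnc_expr)
        rel = dict(zip(pairs["gene_id"], pairs["relation"]))
        assert rel == {"near": "cis", "other": "trans"}  # far: anticorrelated
        assert pairs.set_index("gene_id").loc["near", "distance"] == 49_000
        assert np.isnan(pairs.set_index("gene_id").loc["other", "distance"])

    def test_identical_vectors_on_other_chromosome_are_trans(self):
        lnc, genes, gene_expr, lnc_expr = self._setup()
        gene_expr.loc["other"] = lnc_expr.loc["l1"]
        pairs = predict_targets([lnc], genes, gene_expr, lnc_expr)
        row = pairs[pairs["gene_id"] == "other"].iloc[0]
        assert row["relation"] == "trans"
        assert row["pcc"] == pytest.approx(1.0)

    def test_anticorrelated_gene_admitted_only_with_absolute_gate(self):
        lnc, genes, gene_expr, lnc_expr = self._setup()
        default = predict_targets([lnc], genes, gene_expr, lnc_expr)
        assert "far" not in set(default["gene_id"])
        absolute = predict_targets([lnc], genes, gene_expr, lnc_expr,
                                   TargetParams(absolute_corr=True))
        assert "far" in set(absolute["gene_id"])

    def test_raising_threshold_never_adds_pairs(self):
        lnc, genes, gene_expr, lnc_expr = self._setup()
        loose = predict_targets([lnc], genes, gene_expr, lnc_expr,
                                TargetParams(corr_threshold=0.5))
        tight = predict_targets([lnc], genes, gene_expr, lnc_expr,
                                TargetParams(corr_threshold=0.95))
        loose_set = set(zip(loose["lncrna_id"], loose["gene_id"]))
        tight_set = set(zip(tight["lncrna_id"], tight["gene_id"]))
        assert tight_set <= loose_set

    def test_missing_expression_row_is_an_error(self):
        lnc, genes, gene_expr, lnc_expr = self._setup()
        with pytest.raises(KeyError, match="l1"):
            predict_targets([lnc], genes, gene_expr,
                            lnc_expr.drop(index="l1"))

    def test_planted_cis_pairs_recovered(self, default_dataset):
        """Planted pairs pass both gates; no pair is called cis outside the
        windows; no pair is both cis and trans."""
        genome, matrix, truth = default_dataset
        genes = sorted((g for g in genome.reference.genes.values()
                        if g.biotype == CODING), key=lambda g: g.gene_id)
        gene_expr = pd.DataFrame(
            {g.gene_id: matrix.fpkm.loc[g.transcript_ids].sum(axis=0)
             for g in genes}).T
        lnc_ids = sorted(genome.candidates.transcripts)
        planted_lnc = {p["lncrna_id"] for p in truth.cis_pairs}
        de_lnc = [genome.candidates.transcripts[t] for t in lnc_ids
                  if t in planted_lnc]
        pairs = predict_targets(de_lnc, genes, gene_expr,
                                matrix.fpkm.loc[lnc_ids])
        cis = pairs[pairs["relation"] == "cis"]
        planted = {(p["lncrna_id"], p["gene_id"]) for p in truth.cis_pairs}
        recovered = set(zip(cis["lncrna_id"], cis["gene_id"]))
        assert len(planted & recovered) / len(planted) >= 0.9
        # geometry check: every cis call is within the windows
        for _, row in cis.iterrows():
            lnc = genome.candidates.transcripts[row["lncrna_id"]]
            window = cis_candidates(lnc, genes)
            assert row["gene_id"] in window
        both = set(zip(cis["lncrna_id"], cis["gene_id"])) & set(
            zip(pairs[pairs["relation"] == "trans"]["lncrna_id"],
                pairs[pairs["relation"] == "trans"]["gene_id"]))
        assert not both
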