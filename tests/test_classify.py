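"""Positional classification vs per-base brute force, plus characterization."""

import numpy as np
import pytest

from lnckit.classify import (CodingIndex, characterize, classify_all,
                             classify_lncrna, nearest_gene_distance, CLASSES)
from lnckit.formats import Annotation, TranscriptModel

from conftest import make_expression, random_toy_genome
from oracles import classify_brute, nearest_gene_brute


def _coding_ann(transcripts):
    return Annotation(transcripts,
                      biotypes={t.gene_id: "coding" for t in transcripts})


@pytest.fixture
def two_gene_index():
    coding = [
        TranscriptModel("c1", "cg1", "chr1", "+",
                        [(1000, 1500), (3000, 3500), (5000, 6000)]),
        TranscriptModel("c2", "cg2", "chr1", "-", [(20_000, 22_000)]),
    ]
    return coding, CodingIndex(_coding_ann(coding))


class TestDefinitionalCases:
    def test_intronic_either_strand(self, two_gene_index):
        _, index = two_gene_index
        for strand in "+-":
            t = TranscriptModel("t", "g", "chr1", strand, [(1700, 2500)])
            assert classify_lncrna(t, index).label == "intronic"

    def test_antisense_beats_intronic(self, two_gene_index):
        _, index = two_gene_index
        t = TranscriptModel("t", "g", "chr1", "-", [(1400, 1600)])
        assert classify_lncrna(t, index).label == "antisense"

    def test_same_strand_exon_overlap_is_other(self, two_gene_index):
        _, index = two_gene_index
        t = TranscriptModel("t", "g", "chr1", "+", [(1400, 1600)])
        assert classify_lncrna(t, index).label == "other"

    def test_bidirectional_head_to_head_within_window(self, two_gene_index):
        _, index = two_gene_index
        # c1 is + with 5' at 1000; a - lncRNA ending 600 nt before is divergent
        t = TranscriptModel("t", "g", "chr1", "-", [(100, 400)])
        assert classify_lncrna(t, index).label == "bidirectional"
        far = TranscriptModel("t", "g", "chr1", "-", [(100, 399)])
        assert classify_lncrna(t, index, bidir_window=601).label == "bidirectional"
        assert classify_lncrna(far, index, bidir_window=600).label == "intergenic"

    def test_convergent_neighbors_are_not_bidirectional(self, two_gene_index):
        _, index = two_gene_index
        # + lncRNA just left of + gene: tandem, and facing away if - gene
        t = TranscriptModel("t", "g", "chr1", "+", [(100, 900)])
        assert classify_lncrna(t, index).label == "intergenic"

    def test_intergenic_far_from_everything(self, two_gene_index):
        _, index = two_gene_index
        t = TranscriptModel("t", "g", "chr1", "+", [(40_000, 41_000)])
        assert classify_lncrna(t, index).label == "intergenic"


class TestNearestGene:
    def test_gap_overlap_and_tie_break(self):
        coding = [TranscriptModel("c1", "gB", "chr1", "+", [(300, 400)]),
                  TranscriptModel("c2", "gA", "chr1", "+", [(500, 600)])]
        index = CodingIndex(_coding_ann(coding))
        t = TranscriptModel("t", "g", "chr1", "+", [(100, 200)])
        assert nearest_gene_distance(t, index) == ("gB", 100)
        over = TranscriptModel("t", "g", "chr1", "+", [(350, 550)])
        # overlapping both: distance 0, tie broken by smaller gene_id
        assert nearest_gene_distance(over, index) == ("gA", 0)

    def test_no_coding_gene_on_chromosome(self):
        index = CodingIndex(_coding_ann(
            [TranscriptModel("c", "g", "chr9", "+", [(0, 100)])]))
        t = TranscriptModel("t", "g", "chr1", "+", [(100, 200)])
        assert nearest_gene_distance(t, index) == ("", None)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            coding, lncs = random_toy_genome(rng, n_coding=8, n_lnc=10)
            index = CodingIndex(_coding_ann(coding))
            for t in lncs:
                assert nearest_gene_distance(t, index) == \
                    nearest_gene_brute(t, coding)


class TestOracleEquivalence:
    def test_matches_per_base_brute_force_on_random_genomes(self):
        """0 mismatches vs the per-base classifier over 100 random genomes."""
        rng = np.random.default_rng(99)
        mismatches = 0
        for _ in range(100):
            coding, lncs = random_toy_genome(
                rng, n_coding=int(rng.integers(3, 21)),
                n_lnc=int(rng.integers(5, 31)))
            index = CodingIndex(_coding_ann(coding))
            for t in lncs:
                got = classify_lncrna(t, index).label
                want = classify_brute(t, coding)
                mismatches += got != want
        assert mismatches == 0

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        coding, lncs = random_toy_genome(rng, n_coding=15, n_lnc=40)
        calls = classify_all(lncs, _coding_ann(coding))
        assert len(calls) == len(lncs)
        assert all(c.label in CLASSES for c in calls)

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        coding, lncs = random_toy_genome(rng, n_coding=10, n_lnc=15)
        shift = 12_345
        coding2 = [TranscriptModel(t.transcript_id, t.gene_id, t.chrom,
                                   t.strand,
                                   [(a + shift, b + shift) for a, b in t.exons])
                   for t in coding]
        before = [c.label for c in classify_all(lncs, _coding_ann(coding))]
        lncs2 = [TranscriptModel(t.transcript_id, t.gene_id, t.chrom, t.strand,
                                 [(a + shift, b + shift) for a, b in t.exons])
                 for t in lncs]
        after = [c.label for c in classify_all(lncs2, _coding_ann(coding2))]
        assert before == after

    def test_mirror_reflection_with_strand_flip_invariance(self):
        rng = np.random.default_rng(22)
        coding, lncs = random_toy_genome(rng, n_coding=10, n_lnc=15)
        L = 100_000
        flip = {"+": "-", "-": "+"}

        def mirror(t):
            return TranscriptModel(
                t.transcript_id, t.gene_id, t.chrom, flip[t.strand],
                [(L - b, L - a) for a, b in t.exons])

        before = [c.label for c in classify_all(lncs, _coding_ann(coding))]
        after = [c.label for c in classify_all(
            [mirror(t) for t in lncs],
            _coding_ann([mirror(t) for t in coding]))]
        assert before == after


class TestCharacterize:
    def test_singleton_loci_mean_isoforms(self):
        lncs = [TranscriptModel(f"l{i}", f"lg{i}", "chr1", "+",
                                [(i * 1000, i * 1000 + 300)])
                for i in range(10)]
        mrnas = [TranscriptModel("m1", "mg1", "chr1", "+", [(0, 500)]),
                 TranscriptModel("m2", "mg1", "chr1", "+", [(0, 400)])]
        expr = make_expression(
            {t.transcript_id: [1.0, 2.0] for t in lncs + mrnas})
        s = characterize(lncs, mrnas, expr)
        assert s.mean_isoforms_per_locus("lncRNA") == 1.0
        assert s.mean_isoforms_per_locus("mRNA") == 2.0

    def test_zero_fpkm_gives_degenerate_log_expression(self):
        lncs = [TranscriptModel("l", "lg", "chr1", "+", [(0, 300)])]
        mrnas = [TranscriptModel("m", "mg", "chr1", "+", [(0, 500)])]
        expr = make_expression({"l": [0, 0], "m": [0, 0]})
        s = characterize(lncs, mrnas, expr)
        assert np.all(s.log_expression["lncRNA"] == 0.0)

    def test_empty_input_is_an_error(self):
        mrnas = [TranscriptModel("m", "mg", "chr1", "+", [(0, 500)])]
        expr = make_expression({"m": [1, 1]})
        with pytest.raises(ValueError):
            characterize([], mrnas, expr)

    def test_planted_distribution_moments(self, default_dataset):
        """Summary moments track the generator's length settings."""
        genome, matrix, _ = default_dataset
        lncs = [genome.candidates.transcripts[t]
                for t in sorted(genome.candidates.transcripts)]
        mrnas = genome.coding_transcripts
        s = characterize(lncs, mrnas, matrix)
        # lncRNAs are drawn shorter and with fewer exons than coding genes
        assert np.mean(s.lengths["lncRNA"]) < np.mean(s.lengths["mRNA"])
        assert np.mean(s.exon_counts["lncRNA"]) < np.mean(s.exon_counts["mRNA"])
        assert 200 <= np.median(s.lengths["lncRNA"]) <= 2000
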