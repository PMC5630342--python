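import pandas as pd
import pytest

from lnckit.formats import ExpressionMatrix, TranscriptModel
from lnckit.simulate import (SimulationParams, generate_annotation,
                             simulate_expression)


def random_toy_genome(rng, n_coding=12, n_lnc=20, chrom_length=60_000,
                      chroms=("chrA", "chrB")):
    """Unstructured random genome: genes and lncRNAs thrown anywhere,
    overlaps allowed — a stress input for the classifier oracles."""
    coding = []
    for i in range(n_coding):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 5))
        pos = int(rng.integers(0, chrom_length - 8000))
        exons = []
        for _ in range(n_ex):
            el = int(rng.integers(100, 500))
            exons.append((pos, pos + el))
            pos += el + int(rng.integers(100, 1500))
        coding.append(TranscriptModel(f"c{i}", f"cg{i}", chrom, strand, exons))
    lncs = []
    for i in range(n_lnc):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(200, 3000))
        start = int(rng.integers(0, chrom_length - length))
        if rng.random() < 0.3:
            e1 = max(100, length // 3)
            gap = int(rng.integers(50, 800))
            exons = [(start, start + e1), (start + e1 + gap, start + gap + length)]
        else:
            exons = [(start, start + length)]
        lncs.append(TranscriptModel(f"l{i}", f"lg{i}", chrom, strand, exons))
    return coding, lncs


def make_expression(values, samples=None, groups=None, **kwargs):
    """Small FPKM-only ExpressionMatrix from a dict of rows."""
    df = pd.DataFrame(values).T.astype(float)
    if samples is not None:
        df.columns = samples
    if groups is None:
        cols = list(df.columns)
        half = len(cols) // 2
        groups = {c: ("A" if i < half else "B") for i, c in enumerate(cols)}
    return ExpressionMatrix(fpkm=df, groups=groups, **kwargs)


@pytest.fixture(scope="session")
def default_genome():
    return generate_annotation(SimulationParams(), seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_genome):
    matrix, truth = simulate_expression(default_genome, SimulationParams(),
                                        seed=12)
    return default_genome, matrix, truth
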