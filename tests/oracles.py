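"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — per-base sets, exhaustive scans,
direct summation, sequential-draw enumeration — and shares no code with
the package's own algorithms.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln


# ---------------------------------------------------------------- classify

def classify_brute(t, coding_transcripts, bidir_window=1000):
    """Per-base reimplementation of the positional classifier."""
    same_chrom = [c for c in coding_transcripts if c.chrom == t.chrom]
    t_bases = set()
    for a, b in t.exons:
        t_bases.update(range(a, b))
    # 1. antisense: exonic overlap on the opposite strand
    for c in same_chrom:
        if c.strand != t.strand:
            for a, b in c.exons:
                if t_bases & set(range(a, b)):
                    return "antisense"
    # 2. intronic: t entirely inside one intron of one coding transcript
    span_bases = set(range(t.start, t.end))
    for c in same_chrom:
        for i in range(len(c.exons) - 1):
            intron = set(range(c.exons[i][1], c.exons[i + 1][0]))
            if span_bases <= intron:
                return "intronic"
    # 3. other: remaining overlap with a coding gene span
    genes = {}
    for c in same_chrom:
        s, e = genes.get(c.gene_id, (c.start, c.end))
        genes[c.gene_id] = (min(s, c.start), max(e, c.end))
    gene_strand = {c.gene_id: c.strand for c in same_chrom}
    for gid, (s, e) in genes.items():
        if span_bases & set(range(s, e)):
            return "other"
    # 4. bidirectional: divergent 5' ends within the window, opposite strand
    t5 = t.start if t.strand == "+" else t.end
    for gid, (s, e) in genes.items():
        gs = gene_strand[gid]
        if gs == t.strand:
            continue
        g5 = s if gs == "+" else e
        if abs(t5 - g5) > bidir_window:
            continue
        if t.strand == "+" and g5 <= t5:
            return "bidirectional"
        if t.strand == "-" and g5 >= t5:
            return "bidirectional"
    return "intergenic"


def nearest_gene_brute(t, coding_transcripts):
    genes = {}
    for c in coding_transcripts:
        if c.chrom != t.chrom:
            continue
        s, e = genes.get(c.gene_id, (c.start, c.end))
        genes[c.gene_id] = (min(s, c.start), max(e, c.end))
    best = None
    for gid in sorted(genes):
        s, e = genes[gid]
        gap = max(s - t.end, t.start - e, 0)
        if best is None or gap < best[1]:
            best = (gid, gap)
    return best if best else ("", None)


# ---------------------------------------------------------------- identify

def longest_orf_brute(seq: str) -> int:
    """Exhaustive scan: every ATG, walk to the first in-frame stop."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            if seq[j:j + 3] in stops and j > i:
                best = max(best, (j - i) // 3)
                break
            j += 3
    return best


# ---------------------------------------------------------------- diffexpr

def ac_two_sided_brute(x: int, y: int, n1: float, n2: float) -> float:
    """Direct summation of the conditional mass, both orientations."""

    def raw(x, y, n1, n2):
        r = n2 / n1
        j = np.arange(0, y + 1)
        logmass = (j * math.log(r) + gammaln(x + j + 1) - gammaln(x + 1)
                   - gammaln(j + 1) - (x + j + 1) * math.log1p(r))
        mass = np.exp(logmass)
        lower = mass.sum()
        upper = 1.0 - mass[:-1].sum()
        return min(1.0, 2.0 * min(lower, upper))

    return min(raw(x, y, n1, n2), raw(y, x, n2, n1))


def bh_step_up_brute(p):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------- targets

def cis_candidates_brute(lnc, genes, up=10_000, down=100_000):
    """All-pairs distance scan, strand-aware windows."""
    out = {}
    for g in genes:
        if g.chrom != lnc.chrom:
            continue
        if g.start < lnc.end and lnc.start < g.end:
            out[g.gene_id] = 0
            continue
        if g.start >= lnc.end:
            gap, side = g.start - lnc.end, ("down" if lnc.strand == "+" else "up")
        else:
            gap, side = lnc.start - g.end, ("up" if lnc.strand == "+" else "down")
        if side == "up" and gap <= up:
            out[g.gene_id] = -gap
        elif side == "down" and gap <= down:
            out[g.gene_id] = gap
    return out


# ----------------------------------------------------------------- enrich

def wallenius_sf_brute(k: int, K: int, n: int, N: int, odds: float) -> float:
    """P(X >= k) by enumerating the sequential weighted draw process."""

    @lru_cache(maxsize=None)
    def f(drawn_in: int, drawn_out: int) -> float:
        if drawn_in + drawn_out == n:
            return 1.0 if drawn_in >= k else 0.0
        rem_in = K - drawn_in
        rem_out = (N - K) - drawn_out
        w_in = odds * rem_in
        total = w_in + rem_out
        p = 0.0
        if rem_in > 0:
            p += w_in / total * f(drawn_in + 1, drawn_out)
        if rem_out > 0:
            p += rem_out / total * f(drawn_in, drawn_out + 1)
        return p

    return f(0, 0)
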