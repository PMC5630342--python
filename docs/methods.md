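# Methods

## Scope and data model

The package operates downstream of read alignment and transcript
assembly: its inputs are an assembled candidate GTF, a reference GTF of
protein-coding genes and known lncRNAs, transcript sequences, and a
transcripts × samples table of fragment counts with a two-group sample
map. Internally all intervals are 0-based half-open; GTF I/O converts to
and from the on-disk 1-based inclusive convention, a bijection tested by
round trips. Readers reject malformed input (naming the offending line)
rather than coercing it.

## Identification

A candidate survives the basic screen if its spliced length is ≥ 200 nt
(the operational lncRNA definition) and its FPKM reaches 0.5 in at least
one sample. The expression floor is a configurable convention — it sits
where a pipeline would otherwise propagate assembly noise, and 0.5 FPKM
is a common working value for "reproducibly detected".

Coding potential is assessed by a transparent ORF heuristic: the longest
ATG→stop open reading frame over the three forward frames (assembled
transcripts are stranded, so reverse frames carry no information; ORFs
without an in-frame stop are not counted). A transcript is *noncoding*
iff that ORF is shorter than 100 codons **and** covers less than 35 % of
the transcript. These two cutoffs mirror classic coding/noncoding
screens; both are parameters, and precomputed labels from any external
coding-potential classifier can be supplied per transcript instead,
replacing the heuristic at the same decision point.

Known-versus-novel annotation against a reference lncRNA catalog uses
the standard transcript-matching conventions: identical intron chain
(same strand) for multi-exon transcripts, ≥ 50 % reciprocal span overlap
(same strand) for single-exon ones. The catalog side of a single-exon
comparison is restricted to single-exon entries.

## Positional classification

Every lncRNA receives exactly one label through a fixed precedence:

1. **antisense** — any exonic overlap with a coding exon, opposite strand;
2. **intronic** — contained in a single intron of one coding transcript
   (either strand: strand only separates the antisense class, which is
   defined by exon overlap);
3. **other** — any remaining overlap with a coding gene span, e.g.
   same-strand exonic overlap;
4. **bidirectional** — no overlap, but the 5′ end faces a coding gene's
   5′ end (divergent orientation, opposite strand) within 1 kb;
5. **intergenic** — none of the above.

A transcript can satisfy several textbook definitions simultaneously;
the precedence (most specific evidence first) is a declared convention,
as is the 1 kb promoter window — both configurable. The implementation
queries per-chromosome interval trees and is validated, in the test
suite, against a per-base brute-force classifier over randomized toy
genomes (zero mismatches required), and checked for invariance under
coordinate translation and mirror reflection with strand flip.

## Differential expression

FPKM is computed exactly as count ∕ (length/10³ × library/10⁶). The
default test is the Audic–Claverie exact test on group-pooled counts —
the appropriate exact test when within-group variation is counting noise,
which is also precisely what the default simulator produces. Conditional
on x fragments in a pooled library of size N1, the count y in a library
of size N2 follows the negative binomial NB(x+1, N1/(N1+N2)); tails are
computed through that identity. The two-sided p doubles the smaller
inclusive tail (capped at 1); because that construction is not symmetric
in the two libraries, the reported value is the minimum over both
orientations, making the test exactly symmetric under swapping
(x, N1) ↔ (y, N2). A two-sample t-test on log₂(FPKM+1) is available for
data with biological overdispersion.

Benjamini–Hochberg step-up q-values control FDR. A transcript is called
DE when it jointly clears |log₂FC| ≥ log₂(2), p ≤ 0.05 and q ≤ 0.001;
the three gates are independent parameters (the FDR gate is deliberately
strict by default — at three replicates per group, fold-change estimates
are noisy and a permissive FDR gate admits too many low-count
artifacts). Group means are pseudocounted (+0.01 FPKM) before the log
ratio. Measured behaviour on the simulator at the default design
(3 vs 3, Poisson counts, 2000 transcripts): null fraction of p ≤ 0.05
≈ 0.04–0.055; with 10 % of transcripts planted at fold 4 and the FDR
gate at the conventional 0.05, sensitivity ≈ 0.92–0.97 at false
discovery proportion ≤ 0.02. These numbers are recomputed by the test
suite and `scripts/acceptance.py`, not asserted from memory.

## cis/trans target prediction

Geometry alone fixes the relation: a coding gene whose span lies within
10 kb upstream or 100 kb downstream of the lncRNA (distances are gaps
between closest span boundaries; overlap = 0; upstream/downstream follow
the lncRNA's strand, with a genomic-left/right mode for sensitivity
analysis) is *cis*; everything else — farther on the same chromosome or
on a different one — is *trans*. Correlation then gates reporting only:
a pair appears iff Pearson **and** Spearman correlation of expression
across samples are ≥ 0.8. The gate defaults to signed (positive)
correlation, with an absolute-value mode; it applies to trans pairs as
well by default, and can be switched off for them. Gene-level expression
is the sum of the gene's transcript FPKM rows. Pairs with a constant
expression vector are skipped and logged, not crashed on.

With six samples a correlation threshold of 0.8 is fragile: Spearman on
n = 6 can only take values in steps of ≈ 0.057 and a single distant rank
swap drops it below 0.8. This is a real property of the design size, not
of the implementation, and drives two generator choices described below.

## Enrichment with length-bias correction

Long genes accumulate more fragments and are easier to call DE, which
biases naive enrichment toward categories of long genes. The correction
estimates P(DE | length): genes are sorted by length and split into
equal-count bins (≥ 100 genes per bin; default at most 15 bins), bin DE
rates are shrunk toward the global rate with a prior worth one bin of
genes (so single-bin sampling noise cannot pose as trend), and the rates
are smoothed by isotonic regression along length, direction chosen by
the observed trend. Normalized to mean 1, the smoothed probabilities act
as per-gene weights; each term's odds ratio (mean weight inside ∕
outside the term) parameterizes a Wallenius noncentral hypergeometric
upper tail. At odds 1 this reduces exactly to the central hypergeometric
test. The Wallenius tail comes from scipy's implementation, which the
test suite validates against exhaustive enumeration of the sequential
weighted draw process at N ≤ 20 (agreement to ~1e-14). Note the
direction of the correction: higher odds make large in-term counts more
likely under the null, so the corrected p of a long-gene term is
*larger* (less significant) than the naive one.

Term-to-gene maps are user-supplied TSV; no ontology parsing or DAG
propagation is attempted. The default background is the expressed gene
set; which universe a study should use is a scientific choice surfaced
as an argument.

## Synthetic data

The generator emulates the motivating study design at desk scale:

- **Genome**: 3 chromosomes × 3 Mb; 60 coding genes (1–12 exons,
  exons 150–300 nt, introns 0.2–2 kb, occasional second isoform) on
  regular slots with jitter; chromosomes too short for the requested
  gene count are an error.
- **lncRNA candidates**: 80 (40 copied into the known catalog under new
  ids, 40 novel), placed constructively to realize a class mix chosen to
  echo the proportions such surveys report (66 % intergenic, 18 % other,
  9 % antisense, 6 % intronic, 1 % bidirectional); every placement is
  verified against the package's own classifier and retried on mismatch.
- **Sequences**: coding transcripts carry an embedded ≥ 120-codon ORF;
  lncRNA sequences are redrawn until the ORF screen calls them noncoding.
- **Expression**: baseline FPKM ~ log-normal (ln-mean 0.5, ln-sd 1.2;
  median ≈ 1.6 FPKM); two groups of three samples; library size 2×10⁷
  fragments (the scale of the emulated study, reduced for desk runs);
  counts ~ Poisson(FPKM × length/10³ × library/10⁶), with an
  overdispersion knob (negative binomial) that defaults off so the exact
  test's assumptions match the generator. 10 % of transcripts are DE at
  fold 4 (group B multiplied or divided at random).
- **cis pairs**: 20 lncRNA–gene pairs whose members share a latent
  ln-scale factor (sd 1.5, plus 0.1 residual noise) and a common DE
  shift (the gene is "regulated by" its lncRNA). Two choices keep the
  planted correlation realizable at n = 6: the factor is drawn as a
  random permutation of normal quantiles (N(0,1) marginals with
  guaranteed spread, so near-tied factor values cannot let noise scramble
  the rank order), and pair members' expected per-sample count is floored
  at 2000 fragments (Poisson noise at single-digit counts otherwise
  flips Spearman ranks). The flip side is explicit: a low-abundance cis
  relation is *not* recoverable at this design size, and the generator
  does not pretend otherwise.

Everything is deterministic given the seed, down to byte-identical
fixture files. What the simulator does **not** model: read-level effects
(GC/positional bias, mapping ambiguity), isoform quantification
uncertainty, batch structure, and biological replicate variance beyond
the optional overdispersion — so passing tests demonstrate algorithmic
correctness and calibration under the stated model, not robustness to
every artifact of real libraries.

## Numerical and degenerate-input conventions

- BH q-values and Pearson/Spearman/hypergeometric/Wallenius tails
  delegate to statsmodels/scipy; the test suite cross-checks each
  against an independent implementation (step-up pass, hand-expanded
  rank formula, direct combinatorics, draw enumeration).
- Volcano tables cap p at 1e-300 before −log₁₀.
- Constant vectors yield "correlation undefined" (pair skipped), not NaN.
- Empty candidate sets, empty backgrounds, all-DE weight fits, zero
  library sizes and inconsistent count tables raise typed errors early.
- Tie-breaks are deterministic everywhere (lexicographic ids); stage
  outputs are sorted; reports exclude wall-clock timings so identical
  configurations produce byte-identical outputs.

## Known limitations

- The Audic–Claverie default treats replicates as technical: with real
  biological dispersion it is anti-conservative; use the t alternative
  or the overdispersion knob to probe this.
- Classification precedence and the bidirectional window are
  conventions; surveys differ, and absolute class counts move with them.
- The ORF heuristic is deliberately simple (no hexamer or conservation
  features); it is a screen, not a classifier, and is replaceable by
  precomputed labels.
- Correlation gates at n = 6 have low power and coarse granularity; the
  package reports what passes, it cannot rescue the design.
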