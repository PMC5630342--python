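"""Two-group differential expression on FPKM/counts.

The default test is the Audic–Claverie exact test on group-pooled fragment
counts, the classic choice for small-replicate digital expression designs;
a two-sample t-test on log2(FPKM+1) is available as an alternative.
Multiple testing is controlled with Benjamini–Hochberg.  A transcript is
called differentially expressed when it jointly clears a fold-change gate,
a raw-p gate and an FDR gate (each configurable).

Audic–Claverie details
----------------------
Conditional on observing ``x`` fragments in a library of ``N1``, the count
``y`` in a library of ``N2`` follows

    p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1+N2/N1)^(x+y+1)),

which is the negative binomial NB(x+1, N1/(N1+N2)) — tails are computed
through that identity.  The two-sided p doubles the smaller inclusive tail
(capped at 1); because that construction is not symmetric in the two
libraries, the reported p is the minimum over both orientations, which
makes ``ac_test(x, y, N1, N2) == ac_test(y, x, N2, N1)`` exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionMatrix

__all__ = [
    "DEParams",
    "compute_fpkm",
    "ac_test",
    "bh_fdr",
    "call_de",
]


@dataclass(frozen=True)
class DEParams:
    """Gates and options for the DE call.

    fc_threshold: minimum fold change (on pseudocounted group-mean FPKM).
    p_threshold / fdr_threshold: raw p and BH q gates, enforced jointly.
    pseudocount_fpkm: added to both group means before the log2 ratio.
    test: "audic_claverie" (pooled counts) or "log_t" (t on log2(FPKM+1)).
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.001
    pseudocount_fpkm: float = 0.01
    test: str = "audic_claverie"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        for v in (self.p_threshold, self.fdr_threshold):
            if not (0 < v <= 1):
                raise ValueError("p/fdr thresholds must lie in (0, 1]")
        if self.pseudocount_fpkm <= 0:
            raise ValueError("pseudocount must be positive")
        if self.test not in ("audic_claverie", "log_t"):
            raise ValueError(f"unknown test {self.test!r}")


def compute_fpkm(counts: pd.DataFrame, transcript_lengths: pd.Series,
                 library_sizes: pd.Series) -> pd.DataFrame:
    """FPKM = count / (length/1e3 * library_size/1e6), exactly.

    ``transcript_lengths`` is indexed like the rows of ``counts``,
    ``library_sizes`` like its columns.
    """
    counts_arr = counts.to_numpy()
    if (counts_arr < 0).any():
        raise ValueError("negative counts")
    lengths = transcript_lengths.reindex(counts.index).to_numpy(dtype=float)
    libs = library_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(lengths).any() or (lengths < 1).any():
        raise ValueError("every transcript needs a length >= 1")
    if np.isnan(libs).any() or (libs < 1).any():
        raise ValueError("every sample needs a library size >= 1")
    fpkm = counts_arr / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def _ac_oriented(x: np.ndarray, y: np.ndarray,
                 n1: float, n2: float) -> np.ndarray:
    # inclusive two tails of y ~ NB(x+1, N1/(N1+N2)), doubled and capped
    q = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, q)
    upper = stats.nbinom.sf(y - 1, x + 1, q)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def ac_test(x, y, n1: float, n2: float):
    """Two-sided Audic–Claverie p for counts ``x`` vs ``y`` from libraries
    of total size ``n1`` and ``n2``.  Accepts scalars or arrays.
    """
    x_arr = np.atleast_1d(np.asarray(x))
    y_arr = np.atleast_1d(np.asarray(y))
    if np.any(x_arr < 0) or np.any(y_arr < 0):
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = np.minimum(_ac_oriented(x_arr, y_arr, n1, n2),
                   _ac_oriented(y_arr, x_arr, n2, n1))
    if np.ndim(x) == 0 and np.ndim(y) == 0:
        return float(p[0])
    return p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(expression: ExpressionMatrix,
            params: DEParams = DEParams()) -> pd.DataFrame:
    """Per-transcript DE table for the matrix's two groups.

    Returns a DataFrame with columns ``mean_fpkm_A``, ``mean_fpkm_B``,
    ``log2fc`` (B over A, pseudocounted), ``p``, ``q`` and ``direction``
    (up / down / ns), indexed by transcript id.  Group A is the
    lexicographically first group label.
    """
    label_a, label_b = expression.group_labels
    samples_a = expression.samples_in_group(label_a)
    samples_b = expression.samples_in_group(label_b)
    if not samples_a or not samples_b:
        raise ValueError("both groups must have at least one sample")
    fpkm = expression.fpkm
    mean_a = fpkm[samples_a].mean(axis=1)
    mean_b = fpkm[samples_b].mean(axis=1)
    pc = params.pseudocount_fpkm
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))

    if params.test == "audic_claverie":
        if expression.counts is None or expression.library_sizes is None:
            raise ValueError("audic_claverie test needs counts and library sizes")
        pooled_a = expression.counts[samples_a].sum(axis=1).to_numpy()
        pooled_b = expression.counts[samples_b].sum(axis=1).to_numpy()
        n1 = float(expression.library_sizes[samples_a].sum())
        n2 = float(expression.library_sizes[samples_b].sum())
        p = ac_test(pooled_a, pooled_b, n1, n2)
    else:
        log_a = np.log2(fpkm[samples_a] + 1.0)
        log_b = np.log2(fpkm[samples_b] + 1.0)
        p = stats.ttest_ind(log_b, log_a, axis=1).pvalue
        p = np.nan_to_num(p, nan=1.0)  # zero-variance rows carry no evidence

    q = bh_fdr(p)
    significant = (np.abs(log2fc) >= np.log2(params.fc_threshold)) & \
        (p <= params.p_threshold) & (q <= params.fdr_threshold)
    direction = np.where(~significant, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {"mean_fpkm_A": mean_a, "mean_fpkm_B": mean_b,
         "log2fc": log2fc, "p": p, "q": q, "direction": direction},
        index=fpkm.index.rename("transcript_id"),
    )
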