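"""Differential expression calling with explicit, reproducible thresholds.

The stage mirrors the common bulk RNA-seq screening recipe for bacterial
two-condition designs: library-size (CPM) normalisation, a mean-CPM
expression filter, log2 fold changes on pseudocounted means, a pooled exact
binomial test per gene, Benjamini-Hochberg FDR control, and sign labels
(up / down / ns) from joint fold-change and q-value cutoffs.

The exact test pools counts within each condition: conditional on the total
n = x_treated + x_control, the treated count is Binomial(n, s_t/(s_t+s_c))
under the null, where s_t and s_c are the pooled library sizes.  This is the
classical conditional binomial test for comparing two Poisson rates; it is
exactly computable and brute-force verifiable, at the price of ignoring
between-replicate overdispersion (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_FC_CUT = 1.0
DEFAULT_CPM_MIN = 1.0
DEFAULT_PSEUDOCOUNT = 0.5

#: Thresholds as stated alongside the fold-change table this package ships:
#: raw p < 0.001 and |log2FC| > 1.  The default rule instead uses
#: BH-adjusted q <= 0.05; both readings circulate for this kind of screen,
#: so the alternative is kept as an explicit preset.
RESULTS_RULE_PRESET = {"alpha": 0.001, "fc_cut": 1.0, "use_qvalue": False}


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential expression summary."""

    gene_id: str
    mean_cpm: float
    log2fc: float
    pvalue: float
    qvalue: float
    sign: str = "ns"  # one of {"up", "down", "ns"}


def compute_cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million: counts[g, j] / libsize_j * 1e6.

    Every output column sums to 1e6.  A sample with zero library size is an
    error (CPM undefined).
    """
    libsize = counts.counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"sample {counts.sample_ids[zero[0]]} has zero library size"
        )
    return counts.counts / libsize * 1e6


def filter_expressed(
    cpm: np.ndarray, gene_ids: list[str], threshold: float = DEFAULT_CPM_MIN
) -> set[str]:
    """Genes whose mean CPM across all samples reaches ``threshold``."""
    keep = cpm.mean(axis=1) >= threshold
    return {g for g, k in zip(gene_ids, keep) if k}


def log2_fold_change(
    cpm: np.ndarray,
    counts: CountMatrix,
    treated: str,
    control: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, float]:
    """log2((mean CPM treated + pc) / (mean CPM control + pc)) per gene."""
    mt = cpm[:, counts.samples_of(treated)].mean(axis=1)
    mc = cpm[:, counts.samples_of(control)].mean(axis=1)
    lfc = np.log2((mt + pseudocount) / (mc + pseudocount))
    return dict(zip(counts.gene_ids, lfc))


def exact_count_test(
    counts: CountMatrix, treated: str, control: str
) -> dict[str, float]:
    """Two-sided pooled exact binomial test per gene.

    p = min(1, 2 * min(P[X <= x_t], P[X >= x_t])) with
    X ~ Binomial(x_t + x_c, s_t / (s_t + s_c)); p = 1 for an all-zero gene.
    """
    jt = counts.samples_of(treated)
    jc = counts.samples_of(control)
    libsize = counts.counts.sum(axis=0)
    s_t = libsize[jt].sum()
    s_c = libsize[jc].sum()
    ratio = s_t / (s_t + s_c)
    x_t = counts.counts[:, jt].sum(axis=1)
    x_c = counts.counts[:, jc].sum(axis=1)
    n = x_t + x_c
    lower = stats.binom.cdf(x_t, n, ratio)
    upper = stats.binom.sf(x_t - 1, n, ratio)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p[n == 0] = 1.0
    return dict(zip(counts.gene_ids, p))


def bh_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    genes = list(pvalues)
    p = np.array([pvalues[g] for g in genes], dtype=float)
    if p.size == 0:
        return {}
    if ((p < 0) | (p > 1)).any():
        bad = genes[int(np.flatnonzero((p < 0) | (p > 1))[0])]
        raise ValueError(f"p-value outside [0, 1] for {bad}")
    q = multipletests(p, method="fdr_bh")[1]
    return dict(zip(genes, q))


def call_degs(
    records: list[DERecord],
    alpha: float = DEFAULT_ALPHA,
    fc_cut: float = DEFAULT_FC_CUT,
    use_qvalue: bool = True,
) -> list[DERecord]:
    """Assign up / down / ns labels from q-value (or raw p) and |log2fc|."""
    out = []
    for r in records:
        stat = r.qvalue if use_qvalue else r.pvalue
        if stat <= alpha and r.log2fc > fc_cut:
            sign = "up"
        elif stat <= alpha and r.log2fc < -fc_cut:
            sign = "down"
        else:
            sign = "ns"
        out.append(replace(r, sign=sign))
    return out


def run_differential_expression(
    counts: CountMatrix,
    treated: str = "treated",
    control: str = "control",
    alpha: float = DEFAULT_ALPHA,
    fc_cut: float = DEFAULT_FC_CUT,
    cpm_min: float = DEFAULT_CPM_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    use_qvalue: bool = True,
) -> list[DERecord]:
    """Full DE stage: CPM filter, fold changes, exact test, BH, sign labels.

    Only genes passing the mean-CPM filter are tested and adjusted (the
    filter defines the multiple-testing universe); filtered-out genes are
    not reported.
    """
    cpm = compute_cpm(counts)
    expressed = filter_expressed(cpm, counts.gene_ids, cpm_min)
    lfc = log2_fold_change(cpm, counts, treated, control, pseudocount)
    pvals = exact_count_test(counts, treated, control)
    pvals = {g: pvals[g] for g in counts.gene_ids if g in expressed}
    qvals = bh_adjust(pvals)
    mean_cpm = dict(zip(counts.gene_ids, cpm.mean(axis=1)))
    records = [
        DERecord(
            gene_id=g, mean_cpm=float(mean_cpm[g]), log2fc=float(lfc[g]),
            pvalue=float(pvals[g]), qvalue=float(qvals[g]),
        )
        for g in counts.gene_ids
        if g in expressed
    ]
    return call_degs(records, alpha=alpha, fc_cut=fc_cut, use_qvalue=use_qvalue)
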