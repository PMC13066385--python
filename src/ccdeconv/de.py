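"""Compartment-specific differential expression with a permutation null.

The DE score contrasts how strongly a gene's expression changes between two
cohorts in the cancer versus the stroma compartment:

    DE = log2( |e_c2 / e_c1| / |e_s2 / e_s1| )

where ``e`` are group-level deconvoluted log2 expression values for cancer
(c) and stroma (s) in cohorts 1 and 2.  Positive scores mean the change is
larger in the cancer compartment, negative in the stroma.  A small epsilon
is added to every term so the ratio is always finite.

Significance comes from a label-permutation null: sample-to-cohort labels
are shuffled (group sizes preserved), the two-compartment deconvolution is
re-run on each shuffle, and the two-tailed empirical p-value is the
fraction of null scores at least as extreme as the observed one, with the
add-one (k+1)/(n+1) correction so p is never zero.  One shuffle scores all
genes; by default each gene's observed score is compared against the null
scores of *all* genes pooled across shuffles ("pooled" mode), which keeps
resolution high and avoids the null inflation a strongly differential gene
induces on its own shuffle distribution.  A strictly gene-wise null is
available via ``null_mode="gene"``.

The ``direction`` column attributes each gene's change to the compartment
with the larger absolute log2 fold-change (ties go to cancer); the score's
sign itself follows the formula above.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix
from .deconvolution import fit_two_compartment

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 50_000
DEFAULT_EPSILON = 1e-6


def de_score(e_c1, e_c2, e_s1, e_s2, epsilon: float = DEFAULT_EPSILON):
    """Evaluate the compartment DE score (vectorized over array inputs)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    e_c1, e_c2, e_s1, e_s2 = (np.asarray(x, dtype=float) for x in (e_c1, e_c2, e_s1, e_s2))
    cancer_ratio = np.abs((e_c2 + epsilon) / (e_c1 + epsilon))
    stroma_ratio = np.abs((e_s2 + epsilon) / (e_s1 + epsilon))
    return np.log2(cancer_ratio / stroma_ratio)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _alternative_statistic(e_c1, e_c2, e_s1, e_s2, epsilon=DEFAULT_EPSILON):
    """Difference-of-log-fold-changes variant: (e_c2-e_c1) - (e_s2-e_s1)."""
    return (np.asarray(e_c2) - np.asarray(e_c1)) - (np.asarray(e_s2) - np.asarray(e_s1))


_STATISTICS = {"ratio": de_score, "difference": _alternative_statistic}


def _group_estimates(y: np.ndarray, purity: np.ndarray, idx: np.ndarray, scale: str):
    """(e_c, e_s) on the log2 scale for the samples selected by ``idx``."""
    sub = y[:, idx]
    p = purity[idx]
    if scale == "linear":
        ec, es, _ = fit_two_compartment(np.exp2(sub) - 1.0, p)
        return np.log2(ec + 1.0), np.log2(es + 1.0)
    ec, es, _ = fit_two_compartment(sub, p)
    return ec, es


def permutation_de_test(
    expr_log: ExpressionMatrix,
    purity: pd.Series,
    labels: pd.Series,
    groups: tuple[str, str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    statistic: str = "ratio",
    mixing_scale: str = "log2",
    null_mode: str = "pooled",
    exhaustive: bool | str = "auto",
) -> pd.DataFrame:
    """Observed DE scores plus permutation p-values and BH q-values.

    Parameters
    ----------
    expr_log
        log2(X+1) expression, genes x samples.
    purity, labels
        Sample-indexed purity and cohort labels.  Shuffles draw from the
        union of the two compared cohorts, preserving group sizes.
    groups
        (group1, group2); fold changes and the DE score are group2 vs group1.
    n_perm
        Monte-Carlo shuffles.  When ``n_perm`` is at least the number of
        distinct assignments (or ``exhaustive=True``), all C(n, n1)
        assignments are enumerated instead and p = count/total.
    statistic
        "ratio" (the DE score above, default) or "difference"
        ((e_c2-e_c1)-(e_s2-e_s1)).
    null_mode
        "pooled" (default): each gene's |score| is ranked against the null
        scores of all genes across shuffles.  "gene": only against its own
        null scores.

    Returns
    -------
    DataFrame with one row per gene: de_score, cancer_log2fc,
    stroma_log2fc, p_empirical, q_bh, n_permutations, direction.
    """
    expr_log.require_log()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat_fn = _STATISTICS[statistic]
    g1, g2 = groups
    s1 = [s for s in labels.index[labels == g1] if s in expr_log.sample_ids]
    s2 = [s for s in labels.index[labels == g2] if s in expr_log.sample_ids]
    samples = s1 + s2
    pur = purity.reindex(samples)
    keep = pur.notna().to_numpy()
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("both groups need at least 2 samples")
    y = expr_log.values[samples].to_numpy(dtype=float)[:, keep]
    p = pur.to_numpy(dtype=float)[keep]
    n1 = int(keep[: len(s1)].sum())
    n = y.shape[1]
    if n1 < 2 or n - n1 < 2:
        raise ValueError("both groups need at least 2 samples with known purity")

    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n)
    ec1, es1 = _group_estimates(y, p, idx1, mixing_scale)
    ec2, es2 = _group_estimates(y, p, idx2, mixing_scale)
    obs = stat_fn(ec1, ec2, es1, es2, epsilon)
    abs_obs = np.abs(obs)

    if null_mode not in ("pooled", "gene"):
        raise ValueError("null_mode must be 'pooled' or 'gene'")
    n_genes = y.shape[0]
    n_distinct = math.comb(n, n1)
    use_exhaustive = exhaustive is True or (exhaustive == "auto" and n_perm >= n_distinct)

    # pooled mode counts, for each gene, how many null scores across the whole
    # pool (all genes x all shuffles) are >= its |observed| score; gene mode
    # counts only the gene's own shuffle scores.  Both accumulate per shuffle.
    # A relative tie tolerance keeps "at least as extreme" robust to the
    # ulp-level noise of summation order (complementary label splits are
    # mathematically tied with the observed assignment).
    thresh = abs_obs - 1e-9 * (1.0 + abs_obs)
    order = np.argsort(thresh)
    sorted_thresh = thresh[order]
    pooled_hist = np.zeros(n_genes + 1, dtype=np.int64)
    gene_exceed = np.zeros(n_genes, dtype=np.int64)

    def accumulate(null_scores: np.ndarray) -> None:
        a = np.abs(null_scores)
        if null_mode == "gene":
            gene_exceed[:] += a >= thresh
        else:
            pooled_hist[:] += np.bincount(
                np.searchsorted(sorted_thresh, a, side="right"), minlength=n_genes + 1
            )

    if use_exhaustive:
        logger.info(
            "permutation_de_test: enumerating all %d assignments exhaustively", n_distinct
        )
        iterator = (np.array(c) for c in combinations(range(n), n1))
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        iterator = (rng.permutation(n)[:n1] for _ in range(n_perm))
        n_used = n_perm
    for i1 in iterator:
        mask = np.ones(n, dtype=bool)
        mask[i1] = False
        i2 = np.flatnonzero(mask)
        nec1, nes1 = _group_estimates(y, p, i1, mixing_scale)
        nec2, nes2 = _group_estimates(y, p, i2, mixing_scale)
        accumulate(stat_fn(nec1, nec2, nes1, nes2, epsilon))

    if null_mode == "gene":
        exceed = gene_exceed
        pool_size = n_used
    else:
        # null values v with searchsorted index > k satisfy v >= thresh[k]
        below = np.cumsum(pooled_hist)[:-1]  # per sorted gene: #null < threshold
        exceed_sorted = pooled_hist.sum() - below
        exceed = np.empty(n_genes, dtype=np.int64)
        exceed[order] = exceed_sorted
        pool_size = n_used * n_genes
    if use_exhaustive:
        p_emp = exceed / pool_size
    else:
        p_emp = (1 + exceed) / (1 + pool_size)

    q = bh_adjust(p_emp)
    cancer_fc = ec2 - ec1
    stroma_fc = es2 - es1
    return pd.DataFrame(
        {
            "gene": expr_log.gene_ids,
            "de_score": obs,
            "cancer_log2fc": cancer_fc,
            "stroma_log2fc": stroma_fc,
            "p_empirical": p_emp,
            "q_bh": q,
            "n_permutations": n_used,
            "direction": np.where(np.abs(cancer_fc) >= np.abs(stroma_fc), "cancer", "stroma"),
        }
    ).set_index("gene")
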