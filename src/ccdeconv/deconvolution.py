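"""Two-compartment (cancer/stroma) group-level expression deconvolution.

A bulk tumor sample is modelled as a purity-weighted mixture of a cancer and
a stromal compartment.  For each gene, within one sample group, the observed
expression ``b_i`` of sample ``i`` with tumor purity ``p_i`` is fit as

    b_i  ~=  p_i * e_c  +  (1 - p_i) * e_s

by least squares across the group's samples, yielding one cancer (``e_c``)
and one stroma (``e_s``) expression estimate per gene per group.  Estimates
are constrained nonnegative by an active-set step: a negative unconstrained
solution is clamped to zero and the remaining free parameter re-solved.

By default the regression runs on log2(X+1) values.  Because mixing of
transcript abundances is physically linear, a ``mixing_scale="linear"``
switch de-logs the observations, fits on the linear scale, and re-logs the
estimates; this is the estimator matched to a linear generative mixture.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import CompartmentProfile, ExpressionMatrix

logger = logging.getLogger(__name__)

_MIXING_SCALES = ("log2", "linear")


def prepare_expression(
    expr: ExpressionMatrix, min_median: float = 2.0
) -> ExpressionMatrix:
    """Filter low-abundance genes and log-transform.

    Genes whose median linear expression is strictly below ``min_median``
    (default 2, FPKM-like units) are removed; remaining values are
    log2(X+1)-transformed.  A gene with median exactly at the threshold is
    retained.
    """
    expr.require_linear()
    medians = expr.values.median(axis=1)
    kept = expr.values.loc[medians >= min_median]
    n_dropped = expr.values.shape[0] - kept.shape[0]
    if n_dropped:
        logger.info("prepare_expression: dropped %d genes below median %g", n_dropped, min_median)
    return ExpressionMatrix(np.log2(kept + 1.0), log_scale=True)


def consensus_purity(table: pd.DataFrame) -> pd.Series:
    """Aggregate per-method tumor purity estimates into a consensus.

    Parameters
    ----------
    table
        Sample-indexed DataFrame with one column per estimation method;
        values in (0, 1] or missing.

    Returns
    -------
    Per-sample median of the available method estimates; NA where fewer
    than two methods report (a single estimate is insufficient evidence
    for a consensus).
    """
    if table.shape[1] < 1:
        raise ValueError("purity table has no method columns")
    arr = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr <= 0) | (arr > 1)
    if np.any(bad & ~np.isnan(arr)):
        raise ValueError("purity estimates must lie in (0, 1]")
    n_methods = np.sum(~np.isnan(arr), axis=1)
    consensus = np.nanmedian(np.where(np.isnan(arr), np.nan, arr), axis=1)
    consensus[n_methods < 2] = np.nan
    return pd.Series(consensus, index=table.index, name="consensus_purity")


def fit_two_compartment(
    y: np.ndarray, purity: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nonnegative least squares for the 2-parameter mixture model.

    Parameters
    ----------
    y
        (n_genes, n_samples) observations on the fitting scale.
    purity
        (n_samples,) purity values in (0, 1].

    Returns
    -------
    ``(e_c, e_s, rss)`` arrays of length n_genes.  On a two-parameter
    problem the nonnegativity-constrained optimum is one of four
    candidates (unconstrained, either parameter clamped to 0, both 0);
    the feasible candidate with minimal residual sum of squares is taken.
    """
    p = np.asarray(purity, dtype=float)
    w = 1.0 - p
    y = np.asarray(y, dtype=float)

    pp = p @ p
    ww = w @ w
    pw = p @ w
    det = pp * ww - pw * pw
    yy = np.einsum("gs,gs->g", y, y)
    py = y @ p
    wy = y @ w

    def rss_of(ec: np.ndarray, es: np.ndarray) -> np.ndarray:
        return yy - 2 * (ec * py + es * wy) + ec * ec * pp + 2 * ec * es * pw + es * es * ww

    candidates: list[tuple[np.ndarray, np.ndarray]] = []
    if det > 1e-12 * max(pp * ww, 1.0):
        ec_u = (ww * py - pw * wy) / det
        es_u = (pp * wy - pw * py) / det
        candidates.append((ec_u, es_u))
    # one-parameter fits with the other clamped to 0
    zeros = np.zeros(y.shape[0])
    candidates.append((np.maximum(py / pp, 0.0), zeros))
    if ww > 0:
        candidates.append((zeros, np.maximum(wy / ww, 0.0)))
    candidates.append((zeros, zeros))

    best_ec = np.full(y.shape[0], np.nan)
    best_es = np.full(y.shape[0], np.nan)
    best_rss = np.full(y.shape[0], np.inf)
    for ec, es in candidates:
        feasible = (ec >= 0) & (es >= 0)
        r = np.where(feasible, rss_of(ec, es), np.inf)
        better = r < best_rss - 1e-12
        best_ec = np.where(better, ec, best_ec)
        best_es = np.where(better, es, best_es)
        best_rss = np.where(better, r, best_rss)
    return best_ec, best_es, np.maximum(best_rss, 0.0)


def deconvolute_group(
    expr_log: ExpressionMatrix,
    purity: pd.Series,
    group_samples: Iterable[str],
    group_name: str = "group",
    mixing_scale: str = "log2",
) -> CompartmentProfile:
    """Estimate per-gene cancer and stroma expression for one sample group.

    Samples with missing purity are dropped with a logged warning.  A group
    whose remaining purities are all identical leaves the two-column design
    singular and raises, except in the pure-tumor limit (all purities 1)
    where ``e_c`` is the group mean and ``e_s`` is undefined (NA).
    """
    expr_log.require_log()
    if mixing_scale not in _MIXING_SCALES:
        raise ValueError(f"mixing_scale must be one of {_MIXING_SCALES}")
    samples = [s for s in group_samples if s in expr_log.sample_ids]
    pur = purity.reindex(samples)
    na_samples = pur.index[pur.isna()]
    if len(na_samples):
        logger.warning(
            "deconvolute_group(%s): dropping %d samples with missing purity: %s",
            group_name, len(na_samples), list(na_samples),
        )
        pur = pur.dropna()
    if len(pur) < 2:
        raise ValueError(f"group {group_name!r} has fewer than 2 usable samples")

    b = expr_log.values[pur.index].to_numpy(dtype=float)
    p = pur.to_numpy(dtype=float)
    n = len(p)

    if np.ptp(p) == 0:
        if np.allclose(p, 1.0):
            e_c = b.mean(axis=1)
            rss = ((b - e_c[:, None]) ** 2).sum(axis=1)
            table = pd.DataFrame({
                "gene": expr_log.gene_ids, "group": group_name,
                "e_c": e_c, "e_s": np.nan, "rss": rss, "n_samples": n,
            })
            return CompartmentProfile(table, scale=mixing_scale)
        raise ValueError(
            f"singular design for group {group_name!r}: all purities equal ({p[0]:g})"
        )

    if mixing_scale == "linear":
        y = np.exp2(b) - 1.0
        ec_lin, es_lin, rss = fit_two_compartment(y, p)
        e_c = np.log2(ec_lin + 1.0)
        e_s = np.log2(es_lin + 1.0)
    else:
        e_c, e_s, rss = fit_two_compartment(b, p)

    table = pd.DataFrame({
        "gene": expr_log.gene_ids, "group": group_name,
        "e_c": e_c, "e_s": e_s, "rss": rss, "n_samples": n,
    })
    return CompartmentProfile(table, scale=mixing_scale)


def deconvolute(
    expr_log: ExpressionMatrix,
    purity: pd.Series,
    groups: Mapping[str, Iterable[str]] | pd.Series,
    mixing_scale: str = "log2",
) -> CompartmentProfile:
    """Deconvolute several sample groups into one CompartmentProfile.

    ``groups`` is either a mapping of group name to sample ids or a
    sample-indexed Series of group labels.
    """
    if isinstance(groups, pd.Series):
        groups = {str(g): list(idx) for g, idx in groups.groupby(groups).groups.items()}
    parts = [
        deconvolute_group(expr_log, purity, samples, group_name=name,
                          mixing_scale=mixing_scale).table
        for name, samples in groups.items()
    ]
    return CompartmentProfile(pd.concat(parts, ignore_index=True), scale=mixing_scale)
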