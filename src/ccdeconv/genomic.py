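"""Association tests on genomic and abundance inputs.

Covers the association stages around the deconvolution analysis: mapping
segmented copy number to gene-level values, two-group Wilcoxon rank-sum
locus tests (also reused for bulk expression and cell-type abundances),
Fisher exact mutation-frequency tests, CNA-expression Pearson correlation,
and one-sided Fisher pathway enrichment against a defined background.

All coordinates are 0-based half-open.  q-values are Benjamini-Hochberg,
corrected within each invocation's set of tested rows.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .de import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.25

#: MAF variant classes counted as non-silent (carrier-defining) by default
NON_SILENT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins",
    "In_Frame_Del", "In_Frame_Ins", "Splice_Site", "Translation_Start_Site",
    "Nonstop_Mutation",
})


def map_segments_to_genes(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map SEG records to gene-level copy-number values.

    Each gene's value per sample is the overlap-length-weighted mean of the
    segment means overlapping it; genes in unsegmented gaps get NA.

    Parameters
    ----------
    segments
        Columns sample, chrom, start, end, seg_mean (0-based half-open).
    genes
        Gene-indexed coordinate table with chrom, start, end.
    """
    required = {"sample", "chrom", "start", "end", "seg_mean"}
    if missing := required - set(segments.columns):
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    samples = list(dict.fromkeys(segments["sample"]))
    out = pd.DataFrame(np.nan, index=genes.index, columns=samples)
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        on_chrom = (genes["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        gs, ge = gstart[on_chrom], gend[on_chrom]
        ss = seg["start"].to_numpy()[:, None]
        se = seg["end"].to_numpy()[:, None]
        overlap = np.clip(np.minimum(ge, se) - np.maximum(gs, ss), 0, None)  # segs x genes
        total = overlap.sum(axis=0)
        means = seg["seg_mean"].to_numpy()
        with np.errstate(invalid="ignore"):
            vals = np.where(total > 0, means @ overlap / np.where(total > 0, total, 1), np.nan)
        out.loc[on_chrom, sample] = vals
    return out


def _wilcoxon_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed rank-sum p; exact when both n <= 10 and no ties."""
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 0.0, 1.0
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (no_ties and len(x) <= 10 and len(y) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def abundance_filter(values: pd.DataFrame, min_fraction: float = 0.10,
                     min_samples: int = 5) -> pd.DataFrame:
    """Keep rows whose value exceeds ``min_fraction`` in >= ``min_samples`` samples."""
    keep = (values > min_fraction).sum(axis=1) >= min_samples
    return values.loc[keep]


def two_group_locus_test(
    values: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str],
    apply_abundance_filter: bool = False,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-row two-tailed Wilcoxon rank-sum between two sample groups.

    Rows with fewer than 2 non-NA values in either group are skipped.  With
    ``apply_abundance_filter`` the cell-type abundance rule (fraction > 10%
    in at least 5 samples) is applied before testing.
    """
    g1, g2 = groups
    if apply_abundance_filter:
        values = abundance_filter(values)
    c1 = [s for s in labels.index[labels == g1] if s in values.columns]
    c2 = [s for s in labels.index[labels == g2] if s in values.columns]
    if len(c1) < 2 or len(c2) < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    for row_id, row in values.iterrows():
        x = row[c1].dropna().to_numpy(dtype=float)
        y = row[c2].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            continue
        stat, p = _wilcoxon_two_sided(x, y)
        rows.append((row_id, stat, p, np.median(y) - np.median(x)))
    if not rows:
        raise ValueError("no rows left to test after filtering")
    out = pd.DataFrame(rows, columns=["row", "statistic", "p", "median_diff"]).set_index("row")
    out["q"] = bh_adjust(out["p"].clip(lower=np.nextafter(0, 1)))
    out["significant"] = out["q"] < q_threshold
    return out


def carriers_from_maf(
    maf: pd.DataFrame,
    samples: Iterable[str],
    variant_classes: frozenset[str] | set[str] = NON_SILENT_CLASSES,
) -> pd.DataFrame:
    """Gene x sample binary carrier matrix from MAF-lite records.

    A carrier is a sample with any variant of an accepted class in the gene.
    """
    samples = list(samples)
    kept = maf[maf["variant_class"].isin(variant_classes)]
    mat = pd.crosstab(kept["gene"], kept["sample"]).clip(upper=1)
    return mat.reindex(columns=samples, fill_value=0).fillna(0).astype(int)


def mutation_fisher_test(
    mut: pd.DataFrame, labels: pd.Series, groups: tuple[str, str]
) -> pd.DataFrame:
    """Per-gene two-sided Fisher exact test of carrier frequencies.

    Two-sided p follows the point-probability rule (sum of table
    probabilities <= the observed table's).
    """
    g1, g2 = groups
    c1 = [s for s in labels.index[labels == g1] if s in mut.columns]
    c2 = [s for s in labels.index[labels == g2] if s in mut.columns]
    if not c1 or not c2:
        raise ValueError("both groups need samples present in the mutation matrix")
    rows = []
    for gene, row in mut.iterrows():
        a = int(row[c1].sum())
        b = int(row[c2].sum())
        table = [[a, len(c1) - a], [b, len(c2) - b]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((gene, a, len(c1), b, len(c2), odds, p))
    out = pd.DataFrame(
        rows, columns=["gene", f"carriers_{g1}", f"n_{g1}", f"carriers_{g2}", f"n_{g2}",
                       "odds_ratio", "p"],
    ).set_index("gene")
    out["q"] = bh_adjust(out["p"])
    return out


def cna_expression_correlation(
    cna: pd.DataFrame,
    expr: ExpressionMatrix,
    labels: pd.Series | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between copy number and bulk expression.

    Computed overall and, when ``labels`` is given, within each cohort.
    Zero-variance vectors yield NA (with a warning) rather than an error.
    """
    shared_samples = [s for s in cna.columns if s in expr.sample_ids]
    shared_genes = cna.index.intersection(expr.gene_ids)
    cohorts: dict[str, list[str]] = {"all": shared_samples}
    if labels is not None:
        for grp, idx in labels.groupby(labels).groups.items():
            cohorts[str(grp)] = [s for s in idx if s in shared_samples]
    rows = []
    n_degenerate = 0
    for gene in shared_genes:
        rec: dict[str, object] = {"gene": gene}
        for name, cols in cohorts.items():
            x = cna.loc[gene, cols].to_numpy(dtype=float)
            y = expr.values.loc[gene, cols].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < min_pairs or np.ptp(x) == 0 or np.ptp(y) == 0:
                rec[f"r_{name}"], rec[f"p_{name}"] = np.nan, np.nan
                n_degenerate += len(x) >= min_pairs
                continue
            r, p = stats.pearsonr(x, y)
            rec[f"r_{name}"], rec[f"p_{name}"] = float(r), float(p)
        rows.append(rec)
    if n_degenerate:
        logger.warning("cna_expression_correlation: %d zero-variance gene/cohort pairs -> NA",
                       n_degenerate)
    return pd.DataFrame(rows).set_index("gene")


def pathway_enrichment(
    sig_genes: Iterable[str],
    collection: Mapping[str, set[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper-tail) pathway enrichment.

    Significant genes outside the background universe are dropped (count
    logged); gene sets are intersected with the background and empty sets
    skipped.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene universe")
    sig = set(sig_genes)
    dropped = sig - background
    if dropped:
        logger.info("pathway_enrichment: dropped %d significant genes outside background",
                    len(dropped))
    sig &= background
    n_draw = len(sig)
    rows = []
    for name, members in collection.items():
        in_bg = set(members) & background
        if not in_bg:
            logger.info("pathway_enrichment: set %r empty after background intersection", name)
            continue
        k = len(sig & in_bg)
        p = float(stats.hypergeom.sf(k - 1, len(background), len(in_bg), n_draw))
        rows.append((name, len(in_bg), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    out["q"] = bh_adjust(out["p"])
    return out
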