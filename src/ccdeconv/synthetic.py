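"""Synthetic ccRCC-like cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be tested against known truth:

* three cohorts — indolent (IN), metachronous metastatic (MM), synchronous
  metastatic (SM) — with per-sample tumor purity;
* bulk expression built by *linear-scale* purity-weighted mixing of true
  cancer- and stroma-compartment abundances, with Gaussian noise added on
  the log2 scale (mixtures of transcript abundances are physically linear;
  measurement noise is closer to multiplicative);
* group-restricted fold changes planted in the cancer and/or stroma
  compartment of the MM cohort;
* a contiguous copy-number-loss region enriched in MM with a dosage effect
  on cancer-compartment expression;
* right-censored time-to-metastasis with hazards linked to planted genes.

Compartment expression values are parameterized on the log2(X+1) scale
throughout, matching what the deconvolution stage estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ccio
from .datatypes import ExpressionMatrix, GroundTruth

# rng stream tags so standalone sub-stage calls reproduce the orchestrated run
_TAG_EXPR, _TAG_CNA, _TAG_SURV = 11, 13, 17


@dataclass(frozen=True)
class CNARegionConfig:
    """A contiguous copy-number loss region planted on the synthetic genome."""

    chrom: str = "chr1"
    start: int = 100
    end: int = 300
    loss_frequency_per_group: dict[str, float] = field(
        default_factory=lambda: {"IN": 0.1, "MM": 0.6, "SM": 0.3}
    )
    dosage_slope: float = 1.0
    loss_seg_mean: float = -0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Cohort sizes default to the real study's stratification (IN 68, MM 44,
    SM 80).  Purity is uniform on (0.25, 0.85), matching the reported
    purity range of primary ccRCC tumors.  Follow-up is administratively
    censored at 96 months (8 years) with uniform loss-to-follow-up from 6
    months, which puts the median follow-up of event-free patients at
    ~51 months.
    """

    n_in: int = 68
    n_mm: int = 44
    n_sm: int = 80
    n_genes: int = 1000
    purity_range: tuple[float, float] = (0.25, 0.85)
    frac_cancer_de: float = 0.05
    frac_stroma_de: float = 0.05
    frac_both_de: float = 0.02
    log2fc_magnitude: float = 1.0
    noise_sd: float = 0.2
    cna_region: CNARegionConfig | None = field(default_factory=CNARegionConfig)
    baseline_hazard_rate: float = 0.01  # events per month
    planted_betas: dict[str, float] | None = None  # None -> 5-gene default
    censor_time_months: float = 96.0
    min_followup_months: float = 6.0
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from plain dict/YAML data (cna_region as dict or null)."""
        raw = dict(raw)
        if "cna_region" in raw and isinstance(raw["cna_region"], dict):
            raw["cna_region"] = CNARegionConfig(**raw["cna_region"])
        if "purity_range" in raw:
            raw["purity_range"] = tuple(raw["purity_range"])
        return cls(**raw)

    def __post_init__(self) -> None:
        fracs = (self.frac_cancer_de, self.frac_stroma_de, self.frac_both_de)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("DE fractions must lie in [0,1] and sum to <= 1")
        lo, hi = self.purity_range
        if not (0 < lo < hi < 1):
            raise ValueError("purity_range must be a non-degenerate interval inside (0,1)")
        if min(self.n_in, self.n_mm, self.n_sm) < 2:
            raise ValueError("each cohort needs at least 2 samples")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline hazard must be positive")


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def gene_coordinates(n_genes: int) -> pd.DataFrame:
    """Deterministic synthetic genome: 1000 unit-width genes per chromosome."""
    idx = np.arange(n_genes)
    coords = pd.DataFrame(
        {
            "chrom": [f"chr{i // 1000 + 1}" for i in idx],
            "start": idx % 1000,
            "end": idx % 1000 + 1,
        },
        index=pd.Index(gene_ids(n_genes), name="gene"),
    )
    return coords


def _sample_ids(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    ids, groups = [], []
    for grp, n in (("IN", config.n_in), ("MM", config.n_mm), ("SM", config.n_sm)):
        ids += [f"{grp}_{i:03d}" for i in range(n)]
        groups += [grp] * n
    return ids, np.array(groups)


def _plant_truth(config: SimulationConfig, rng: np.random.Generator):
    """Draw baseline compartment expression and plant MM fold changes."""
    n = config.n_genes
    base_c = np.clip(rng.normal(6.0, 1.5, n), 1.0, None)
    base_s = np.clip(base_c + rng.normal(0.0, 1.0, n), 1.0, None)

    n_c = round(config.frac_cancer_de * n)
    n_s = round(config.frac_stroma_de * n)
    n_b = round(config.frac_both_de * n)
    chosen = rng.choice(n, size=n_c + n_s + n_b, replace=False)
    labels = np.full(n, "none", dtype=object)
    labels[chosen[:n_c]] = "cancer"
    labels[chosen[n_c:n_c + n_s]] = "stroma"
    labels[chosen[n_c + n_s:]] = "both"
    signs = rng.choice([-1.0, 1.0], size=n)
    fc = signs * config.log2fc_magnitude

    genes = gene_ids(n)
    cancer = pd.DataFrame({g: base_c.copy() for g in ("IN", "MM", "SM")}, index=genes)
    stroma = pd.DataFrame({g: base_s.copy() for g in ("IN", "MM", "SM")}, index=genes)
    in_cancer = np.isin(labels, ("cancer", "both"))
    in_stroma = np.isin(labels, ("stroma", "both"))
    cancer.loc[in_cancer, "MM"] = np.clip(base_c[in_cancer] + fc[in_cancer], 0.0, None)
    stroma.loc[in_stroma, "MM"] = np.clip(base_s[in_stroma] + fc[in_stroma], 0.0, None)
    de_labels = pd.Series(labels, index=genes, name="de_label")
    return cancer, stroma, de_labels


def simulate_cna_segments(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant a contiguous copy-number loss region enriched per group.

    Returns the SEG-style segment table (0-based half-open coordinates) and
    the gene x sample copy-number matrix.  Carrier status is Bernoulli per
    sample with the group's configured loss frequency; carriers get the
    configured segment mean across the whole region.
    """
    region = config.cna_region
    coords = gene_coordinates(config.n_genes)
    if region is not None:
        on_chrom = coords.loc[coords["chrom"] == region.chrom]
        chrom_size = int(on_chrom["end"].max()) if len(on_chrom) else 0
        if region.start < 0 or region.end > chrom_size or region.start >= region.end:
            raise ValueError(
                f"CNA region {region.chrom}:{region.start}-{region.end} lies outside "
                "the simulated coordinate space"
            )
    rng = np.random.default_rng([config.seed, _TAG_CNA])
    samples = list(annotation.index)
    groups = annotation["group"]

    cna = pd.DataFrame(0.0, index=coords.index, columns=samples)
    seg_rows: list[tuple] = []
    chrom_sizes = coords.groupby("chrom", sort=False)["end"].max()
    for sample in samples:
        carrier = False
        if region is not None:
            freq = region.loss_frequency_per_group.get(str(groups.loc[sample]), 0.0)
            carrier = bool(rng.random() < freq)
        for chrom, size in chrom_sizes.items():
            if region is not None and chrom == region.chrom and carrier:
                if region.start > 0:
                    seg_rows.append((sample, chrom, 0, region.start, 0.0))
                seg_rows.append((sample, chrom, region.start, region.end, region.loss_seg_mean))
                if region.end < size:
                    seg_rows.append((sample, chrom, region.end, size, 0.0))
            else:
                seg_rows.append((sample, chrom, 0, size, 0.0))
        if carrier:
            in_region = (
                (coords["chrom"] == region.chrom)
                & (coords["start"] >= region.start)
                & (coords["end"] <= region.end)
            )
            cna.loc[in_region, sample] = region.loss_seg_mean
    segments = pd.DataFrame(seg_rows, columns=ccio.SEG_COLUMNS)
    return segments, cna


def simulate_survival_labels(
    config: SimulationConfig, expr: ExpressionMatrix
) -> pd.DataFrame:
    """Simulate right-censored time-to-metastasis from bulk expression.

    Event times are exponential with per-sample hazard
    ``baseline * exp(sum_g beta_g * z_g)`` where ``z_g`` is the z-scored
    log2(X+1) bulk expression of planted gene ``g``.  Follow-up is the
    minimum of administrative censoring and uniform loss-to-follow-up;
    event = 1 means metastasis observed within follow-up.
    """
    rng = np.random.default_rng([config.seed, _TAG_SURV])
    betas = resolve_planted_betas(config)
    missing = [g for g in betas if g not in expr.gene_ids]
    if missing:
        raise ValueError(f"planted_betas reference unknown genes: {missing}")

    vals = expr.values
    logv = vals if expr.log_scale else np.log2(vals + 1.0)
    lp = np.zeros(logv.shape[1])
    for gene, beta in betas.items():
        row = logv.loc[gene].to_numpy(dtype=float)
        sd = row.std()
        z = (row - row.mean()) / sd if sd > 0 else np.zeros_like(row)
        lp += beta * z
    hazard = config.baseline_hazard_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    loss_fu = rng.uniform(config.min_followup_months, config.censor_time_months,
                          size=len(hazard))
    censor = np.minimum(config.censor_time_months, loss_fu)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return pd.DataFrame(
        {"time_months": time, "event": event}, index=vals.columns
    )


def resolve_planted_betas(config: SimulationConfig) -> dict[str, float]:
    """Default planted hazard: a 5-gene signature at log(1.8) per SD.

    When ``planted_betas`` is None the five lowest-index cancer-compartment
    DE genes carry the hazard (falling back to the first five genes of the
    panel if fewer exist), mirroring a compact expression signature whose
    members are themselves compartment-DE.
    """
    if config.planted_betas is not None:
        return dict(config.planted_betas)
    rng = np.random.default_rng([config.seed, _TAG_EXPR])
    _, _, de_labels = _plant_truth(config, rng)
    cancer_genes = sorted(de_labels.index[de_labels.isin(["cancer", "both"])])
    pool = cancer_genes if len(cancer_genes) >= 5 else list(de_labels.index)
    return {g: math.log(1.8) for g in pool[:5]}


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns the linear-scale bulk :class:`ExpressionMatrix`, the sample
    annotation (group, purity, time_months, event) and the planted
    :class:`GroundTruth`.  Identical config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng([config.seed, _TAG_EXPR])
    cancer, stroma, de_labels = _plant_truth(config, rng)
    samples, groups = _sample_ids(config)
    purity = rng.uniform(*config.purity_range, size=len(samples))

    annotation = pd.DataFrame(
        {"group": groups, "purity": purity}, index=pd.Index(samples, name="sample")
    )
    segments, cna = simulate_cna_segments(config, annotation)

    # per-sample compartment abundances (linear scale)
    ec = cancer[groups].to_numpy()  # genes x samples, log2(X+1)
    es = stroma[groups].to_numpy()
    if config.cna_region is not None and config.cna_region.dosage_slope != 0:
        ec = np.clip(ec + config.cna_region.dosage_slope * cna.to_numpy(), 0.0, None)
    mix = purity * (np.exp2(ec) - 1.0) + (1.0 - purity) * (np.exp2(es) - 1.0)
    log_bulk = np.log2(mix + 1.0)
    if config.noise_sd > 0:
        log_bulk = log_bulk + rng.normal(0.0, config.noise_sd, size=log_bulk.shape)
    bulk = np.clip(np.exp2(log_bulk) - 1.0, 0.0, None)

    expr = ExpressionMatrix(
        pd.DataFrame(bulk, index=cancer.index, columns=samples), log_scale=False
    )
    surv = simulate_survival_labels(config, expr)
    annotation = annotation.join(surv)

    truth = GroundTruth(
        cancer_expr=cancer,
        stroma_expr=stroma,
        de_labels=de_labels,
        cna_matrix=cna,
        true_betas=resolve_planted_betas(config),
        segments=segments,
    )
    return expr, annotation, truth


def write_cohort(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the cohort bundle as TSV/SEG files and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "purity": out / "purity.tsv",
        "segments": out / "segments.seg",
        "gene_coords": out / "gene_coords.bed",
        "truth_cancer": out / "truth_cancer_expr.tsv",
        "truth_stroma": out / "truth_stroma_expr.tsv",
        "truth_de_labels": out / "truth_de_labels.tsv",
        "truth_cna": out / "truth_cna_matrix.tsv",
        "truth_betas": out / "truth_betas.tsv",
    }
    ccio.write_expression(expr, paths["expression"])
    ccio.write_annotation(annotation, paths["annotation"])
    # method columns replicate the true purity: estimation error is out of scope
    purity = pd.DataFrame(
        {m: annotation["purity"] for m in ("m1", "m2", "m3", "m4")},
        index=annotation.index,
    )
    purity.to_csv(paths["purity"], sep="\t", index_label="sample")
    ccio.write_seg(truth.segments, paths["segments"])
    ccio.write_gene_coordinates(gene_coordinates(len(expr.gene_ids)), paths["gene_coords"])
    truth.cancer_expr.to_csv(paths["truth_cancer"], sep="\t", index_label="gene")
    truth.stroma_expr.to_csv(paths["truth_stroma"], sep="\t", index_label="gene")
    truth.de_labels.to_frame().to_csv(paths["truth_de_labels"], sep="\t", index_label="gene")
    truth.cna_matrix.to_csv(paths["truth_cna"], sep="\t", index_label="gene")
    pd.Series(truth.true_betas, name="beta").to_csv(
        paths["truth_betas"], sep="\t", index_label="gene"
    )
    return paths
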