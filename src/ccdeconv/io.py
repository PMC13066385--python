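"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated.  SEG input follows the usual 1-based inclusive
convention and is converted to 0-based half-open coordinates on read; every
internal coordinate is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import ExpressionMatrix

SEG_COLUMNS = ["sample", "chrom", "start", "end", "seg_mean"]


def read_expression(path: str | Path, log_scale: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, log_scale=log_scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Sample annotation TSV indexed by sample id.

    Expected columns include ``group`` (IN/MM/SM), ``purity``,
    ``time_months`` and ``event`` where the stage needs them.
    """
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="sample")


def read_purity(path: str | Path) -> pd.DataFrame:
    """Purity TSV: sample id column plus one column per estimation method."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read SEG records, converting 1-based inclusive to 0-based half-open."""
    seg = pd.read_csv(path, sep="\t", header=0)
    if seg.shape[1] < 5:
        raise ValueError(
            f"malformed SEG file {path}: expected >= 5 columns, got {seg.shape[1]}"
        )
    seg = seg.iloc[:, :5]
    seg.columns = SEG_COLUMNS
    seg["start"] = seg["start"].astype(int) - 1
    seg["end"] = seg["end"].astype(int)
    return seg


def write_seg(seg: pd.DataFrame, path: str | Path) -> None:
    """Write SEG with 0-based half-open coordinates converted back to 1-based."""
    out = seg[SEG_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1
    out.columns = ["ID", "chrom", "loc.start", "loc.end", "seg.mean"]
    out.to_csv(path, sep="\t", index=False)


def read_gene_coordinates(path: str | Path) -> pd.DataFrame:
    """BED-like gene coordinate table: chrom, start, end, gene (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene"]
    return df.set_index("gene")


def write_gene_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    out = coords.reset_index()[["chrom", "start", "end", "gene"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_maf_lite(path: str | Path) -> pd.DataFrame:
    """MAF-lite TSV with at least columns sample, gene, variant_class."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "variant_class"} - set(df.columns)
    if missing:
        raise ValueError(f"MAF-lite file missing columns: {sorted(missing)}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_gpr_rules(path: str | Path) -> pd.DataFrame:
    """Rule TSV: reaction_id, subsystem, rule."""
    df = pd.read_csv(path, sep="\t")
    missing = {"reaction_id", "rule"} - set(df.columns)
    if missing:
        raise ValueError(f"GPR rule file missing columns: {sorted(missing)}")
    if "subsystem" not in df.columns:
        df["subsystem"] = ""
    return df[["reaction_id", "subsystem", "rule"]]
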