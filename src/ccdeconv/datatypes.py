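"""Core in-memory containers shared across the pipeline.

Expression data travels as a genes x samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix`, which carries the one piece of state a
bare frame cannot: whether values are linear (FPKM-like) or already
log2(X+1)-transformed.  Every transformation that changes scale goes through
this wrapper so downstream stages can refuse wrongly-scaled input instead of
silently producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COHORTS = ("IN", "MM", "SM")


class ScaleError(ValueError):
    """Raised when an operation receives expression on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene identifiers with unique sample
        columns.  Linear-scale values must be nonnegative.
    log_scale
        ``False`` for linear (FPKM-like) values, ``True`` for log2(X+1).
    """

    values: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        if not self.log_scale:
            arr = self.values.to_numpy()
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("negative values in linear-scale expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def require_linear(self) -> None:
        if self.log_scale:
            raise ScaleError("operation requires linear-scale expression, got log2(X+1)")

    def require_log(self) -> None:
        if not self.log_scale:
            raise ScaleError("operation requires log2(X+1) expression, got linear scale")


@dataclass
class CompartmentProfile:
    """Group-level deconvoluted compartment expression.

    ``table`` has one row per (gene, group) with columns ``e_c`` (cancer
    log2 expression), ``e_s`` (stroma log2 expression), ``rss`` (residual sum
    of squares of the per-gene fit) and ``n_samples``.  ``scale`` records the
    scale the regression ran on ("log2" or "linear"), which matters when the
    profile feeds reaction scoring.
    """

    table: pd.DataFrame
    scale: str = "log2"

    def group(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == name]
        if sub.empty:
            raise KeyError(f"no deconvoluted profile for group {name!r}")
        return sub.set_index("gene")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))


@dataclass
class GroundTruth:
    """Planted parameters emitted alongside a simulated cohort."""

    cancer_expr: pd.DataFrame  # genes x groups, true log2(X+1) cancer expression
    stroma_expr: pd.DataFrame  # genes x groups, true log2(X+1) stroma expression
    de_labels: pd.Series  # gene -> {"cancer", "stroma", "both", "none"}
    cna_matrix: pd.DataFrame | None = None  # genes x samples copy-number values
    true_betas: dict[str, float] = field(default_factory=dict)
    segments: pd.DataFrame | None = None  # SEG-style table backing cna_matrix
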