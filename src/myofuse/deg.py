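"""Downstream differential-expression logic: FDR correction, cutoff
filtering, and opposing-direction classification across two contrasts.

The inputs are per-gene statistics (gene id, log2 fold-change, raw p-value,
optionally an adjusted p-value) from any upstream DE fit; the negative-
binomial model fit itself is out of scope here.  Within each contrast,
p-values are corrected with the Benjamini-Hochberg step-up procedure, genes
passing |log2FC| >= 0.8 and adjusted p <= 0.05 (both boundaries inclusive)
are labelled up/down, and genes significant in both contrasts are classified
into joint-direction quadrants; the down-in-A / up-in-B quadrant is flagged
as the candidate set for opposing regulation.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError

__all__ = [
    "DegThresholds",
    "OpposingClassification",
    "bh_adjust",
    "filter_deg",
    "classify_opposing",
]


@dataclass(frozen=True)
class DegThresholds:
    """|log2FC| >= 0.8 (a 1.74-fold change on the linear scale) and BH-adjusted
    p <= 0.05, both inclusive."""

    min_abs_log2fc: float = 0.8
    max_padj: float = 0.05

    def __post_init__(self):
        if self.min_abs_log2fc < 0:
            raise ParameterError("min_abs_log2fc must be >= 0")
        if not 0.0 < self.max_padj <= 1.0:
            raise ParameterError("max_padj must be in (0, 1]")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the top
    by cumulative minimum, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ParameterError("p-values must all lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


_REQUIRED_COLUMNS = ("gene_id", "log2fc", "pvalue")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"DE table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise SchemaError(f"duplicate gene ids in DE table (e.g. {dups})")


def filter_deg(table: pd.DataFrame, thresholds: DegThresholds = DegThresholds()) -> pd.DataFrame:
    """Significant genes with direction labels.

    If ``padj`` is absent it is computed with :func:`bh_adjust` over the full
    table (BH depends on the total number of tests m, so the correction is
    never applied to a pre-filtered subset).  A gene is kept when
    |log2fc| >= min_abs_log2fc and padj <= max_padj, both inclusive;
    direction is "up" for log2fc > 0 and "down" otherwise (a log2fc of
    exactly 0 can never pass a positive cutoff, so the convention is inert).
    """
    _check_table(table)
    df = table.copy()
    if "padj" not in df.columns or df["padj"].isna().all():
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    keep = (df["log2fc"].abs() >= thresholds.min_abs_log2fc) & \
           (df["padj"] <= thresholds.max_padj)
    out = df.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class OpposingClassification:
    """Joint-direction classification of genes significant in both contrasts."""

    table: pd.DataFrame  # columns: gene_id, direction_a, direction_b, quadrant
    quadrant_counts: dict
    overlap: int

    @property
    def fusion_candidates(self) -> list:
        """The down-in-A / up-in-B genes — the opposing-regulation candidate set."""
        q = self.table
        return sorted(q.loc[q["quadrant"] == "down_a_up_b", "gene_id"])

    def to_summary_dict(self) -> dict:
        return {"overlap": self.overlap, "quadrant_counts": dict(self.quadrant_counts)}


def classify_opposing(sig_a: pd.DataFrame, sig_b: pd.DataFrame) -> OpposingClassification:
    """Intersect two filtered tables and assign each shared gene a quadrant.

    Inputs are outputs of :func:`filter_deg` (they must carry a ``direction``
    column).  Quadrants: down_a_up_b, up_a_down_b, up_both, down_both.
    """
    for name, t in (("A", sig_a), ("B", sig_b)):
        if "direction" not in t.columns:
            raise SchemaError(f"contrast {name} table lacks a 'direction' column; "
                              "run filter_deg first")
        if t["gene_id"].duplicated().any():
            raise SchemaError(f"duplicate gene ids in contrast {name}")
    merged = sig_a[["gene_id", "direction"]].merge(
        sig_b[["gene_id", "direction"]], on="gene_id", suffixes=("_a", "_b"))

    def quadrant(row):
        if row["direction_a"] == "down" and row["direction_b"] == "up":
            return "down_a_up_b"
        if row["direction_a"] == "up" and row["direction_b"] == "down":
            return "up_a_down_b"
        return "up_both" if row["direction_a"] == "up" else "down_both"

    if len(merged):
        merged["quadrant"] = merged.apply(quadrant, axis=1)
    else:
        merged["quadrant"] = pd.Series(dtype=object)
    merged = merged.sort_values("gene_id", ignore_index=True)
    counts = {q: int((merged["quadrant"] == q).sum())
              for q in ("down_a_up_b", "up_a_down_b", "up_both", "down_both")}
    return OpposingClassification(table=merged, quadrant_counts=counts, overlap=len(merged))
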