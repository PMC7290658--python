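"""Synthetic two-contrast differential-expression tables with planted truth.

Emulates the situation analysed downstream: two knockdown-vs-control
contrasts over the same gene universe, in which a subset of genes is
significantly deregulated in *both* contrasts ("shared"), and a further
subset of those moves in opposite directions ("opposing": down in contrast A,
up in contrast B).  Non-planted genes are null: log2 fold-changes from a
centred normal and p-values from Uniform(0, 1).

Planted genes are constructed to pass the (|log2FC| >= planted_abs_lfc_min,
p <= planted_p_max) filter in both contrasts, with p-values drawn log-uniform
on [1e-12, planted_p_max] (spans realistic significance without ties).
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["DegSimParams", "generate_deg_tables", "QUADRANTS"]

QUADRANTS = ("down_a_up_b", "up_a_down_b", "up_both", "down_both")

_PLANTED_P_FLOOR = 1e-12
_PLANTED_LFC_SPAN = 4.2  # planted |log2FC| uniform on [min, min + span]


@dataclass(frozen=True)
class DegSimParams:
    """Defaults mirror the analysed scale: 1,000 genes, 98 planted shared
    between the two contrasts, 46 of them opposing (down-in-A / up-in-B)."""

    n_genes: int = 1000
    n_shared_planted: int = 98
    n_opposing_planted: int = 46
    planted_abs_lfc_min: float = 0.8
    null_lfc_sd: float = 0.3
    planted_p_max: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ParameterError("n_genes must be positive")
        if self.n_shared_planted < 0 or self.n_opposing_planted < 0:
            raise ParameterError("planted counts must be non-negative")
        if self.n_opposing_planted > self.n_shared_planted:
            raise ParameterError("n_opposing_planted must not exceed n_shared_planted")
        if self.n_shared_planted > self.n_genes:
            raise ParameterError("n_shared_planted must not exceed n_genes")
        if self.null_lfc_sd <= 0:
            raise ParameterError("null_lfc_sd must be positive")
        if not 0.0 < self.planted_p_max < 1.0:
            raise ParameterError("planted_p_max must be in (0, 1)")


def _planted_pvalues(rng: np.random.Generator, n: int, p_max: float) -> np.ndarray:
    lo, hi = np.log(_PLANTED_P_FLOOR), np.log(p_max)
    return np.exp(rng.uniform(lo, hi, size=n))


def generate_deg_tables(params: DegSimParams = DegSimParams()):
    """Generate (table_a, table_b, planted_labels).

    Both tables have columns ``gene_id, log2fc, pvalue`` over the same gene
    universe; the labels table has ``gene_id, quadrant`` for every planted
    shared gene (quadrant = the intended joint direction).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    gene_ids = np.array([f"gene{i:05d}" for i in range(n)])

    lfc_a = rng.normal(0.0, params.null_lfc_sd, size=n)
    lfc_b = rng.normal(0.0, params.null_lfc_sd, size=n)
    p_a = rng.uniform(0.0, 1.0, size=n)
    p_b = rng.uniform(0.0, 1.0, size=n)

    planted_idx = rng.choice(n, size=params.n_shared_planted, replace=False)
    quadrants = np.empty(params.n_shared_planted, dtype=object)
    quadrants[:params.n_opposing_planted] = "down_a_up_b"
    n_rest = params.n_shared_planted - params.n_opposing_planted
    quadrants[params.n_opposing_planted:] = rng.choice(
        ["up_a_down_b", "up_both", "down_both"], size=n_rest)
    # shuffle so quadrant membership is not correlated with gene index order
    shuffle = rng.permutation(params.n_shared_planted)
    planted_idx, quadrants = planted_idx[shuffle], quadrants[shuffle]

    mag_a = params.planted_abs_lfc_min + rng.uniform(
        0.0, _PLANTED_LFC_SPAN, size=params.n_shared_planted)
    mag_b = params.planted_abs_lfc_min + rng.uniform(
        0.0, _PLANTED_LFC_SPAN, size=params.n_shared_planted)
    sign_a = np.where(np.isin(quadrants, ("down_a_up_b", "down_both")), -1.0, 1.0)
    sign_b = np.where(np.isin(quadrants, ("up_a_down_b", "down_both")), -1.0, 1.0)
    lfc_a[planted_idx] = sign_a * mag_a
    lfc_b[planted_idx] = sign_b * mag_b
    p_a[planted_idx] = _planted_pvalues(rng, params.n_shared_planted, params.planted_p_max)
    p_b[planted_idx] = _planted_pvalues(rng, params.n_shared_planted, params.planted_p_max)

    table_a = pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc_a, "pvalue": p_a})
    table_b = pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc_b, "pvalue": p_b})
    labels = pd.DataFrame({"gene_id": gene_ids[planted_idx], "quadrant": quadrants})
    labels = labels.sort_values("gene_id", ignore_index=True)
    return table_a, table_b, labels
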