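"""Single-sample gene-set scoring of TIL abundance (ssGSEA-style).

Each cell type's abundance in a sample is summarized by a rank-based
enrichment score of its marker set: genes are ranked by expression
(average ranks on ties), walked in descending order, and the score is the
sum over positions of the difference between the weighted in-set
cumulative fraction (weights rank^alpha, alpha=0.25) and the uniform
out-of-set cumulative fraction.  Scores are comparable across samples
within a cell type, not across cell types; optional min-max normalization
rescales each cell type's scores to [0, 1].

The scoring function is pluggable in :func:`til_profile` so an alternative
single-sample statistic (e.g. mean marker z-score) can be swapped in.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gene_sets import GeneSetCollection

__all__ = ["ssgsea_score", "til_profile"]


def ssgsea_score(
    values: Sequence[float] | pd.Series,
    genes: Sequence[str] | None = None,
    gene_set: Sequence[str] = (),
    alpha: float = 0.25,
) -> float:
    """Rank-based enrichment score of ``gene_set`` in one sample.

    ``values`` may be a pandas Series indexed by gene, or an array paired
    with ``genes``.  The set must overlap the measured genes and must not
    cover all of them (the out-of-set complement would be empty).
    """
    if isinstance(values, pd.Series):
        genes = list(values.index)
        x = values.to_numpy(dtype=float)
    else:
        if genes is None:
            raise ValueError("genes must be given when values is not a Series")
        genes = list(genes)
        x = np.asarray(values, dtype=float)
    if len(genes) != x.size:
        raise ValueError("genes and values length mismatch")
    in_set = np.isin(genes, list(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not overlap the measured genes")
    if n_in == x.size:
        raise ValueError("gene set covers every measured gene; complement is empty")

    ranks = rankdata(x)  # ascending, ties averaged -> top gene has rank N
    order = np.lexsort((np.arange(x.size), -x))  # descending, stable on ties
    in_sorted = in_set[order]
    weights = np.where(in_sorted, ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_sorted) / (x.size - n_in)
    return float(np.sum(p_in - p_out))


def _rank_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks and stable descending sort order per sample column."""
    ranks = rankdata(values, axis=0)
    order = np.argsort(-values, axis=0, kind="stable")
    return np.take_along_axis(ranks, order, axis=0), order


def _ssgsea_matrix(
    ranks_sorted: np.ndarray,
    order: np.ndarray,
    in_set: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Vectorized :func:`ssgsea_score` over the columns of a genes x samples
    matrix; identical tie handling (stable descending sort, average ranks)."""
    n_genes = in_set.size
    in_sorted = in_set[order]
    weights = np.where(in_sorted, ranks_sorted**alpha, 0.0)
    p_in = np.cumsum(weights, axis=0) / weights.sum(axis=0, keepdims=True)
    p_out = np.cumsum(~in_sorted, axis=0) / (n_genes - in_set.sum())
    return (p_in - p_out).sum(axis=0)


def til_profile(
    expr: pd.DataFrame,
    marker_sets: GeneSetCollection,
    normalize: bool = False,
    alpha: float = 0.25,
    score_fn: Callable[..., float] | None = None,
) -> pd.DataFrame:
    """Score every sample against every marker set (samples x cell types).

    Marker-set names are taken as cell-type names, with a ``til_`` prefix
    stripped when present.  ``normalize=True`` min-max scales each cell
    type's scores across samples into [0, 1].
    """
    genes = list(expr.index)
    values = expr.to_numpy(dtype=float)
    ranks_sorted, order = (None, None) if score_fn else _rank_order(values)
    columns: dict[str, np.ndarray] = {}
    for set_name in marker_sets.names():
        cell_type = set_name.removeprefix("til_")
        in_set = np.isin(genes, marker_sets[set_name])
        n_in = int(in_set.sum())
        if n_in == 0:
            raise ValueError(
                f"cell type {cell_type!r}: gene set does not overlap the measured genes"
            )
        if n_in == len(genes):
            raise ValueError(
                f"cell type {cell_type!r}: gene set covers every measured gene"
            )
        if score_fn is not None:
            columns[cell_type] = np.array(
                [
                    score_fn(
                        values[:, j],
                        genes=genes,
                        gene_set=marker_sets[set_name],
                        alpha=alpha,
                    )
                    for j in range(values.shape[1])
                ]
            )
        else:
            columns[cell_type] = _ssgsea_matrix(ranks_sorted, order, in_set, alpha)
    profile = pd.DataFrame(columns, index=pd.Index(expr.columns, name="sample"))
    if normalize:
        lo = profile.min(axis=0)
        span = profile.max(axis=0) - lo
        span[span == 0] = 1.0
        profile = (profile - lo) / span
    return profile
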