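"""TIME subtype classification and cross-cohort label transfer.

Tumors are clustered on immune-panel expression — log10(x+1) transform,
agglomerative clustering with average linkage on 1 - Pearson correlation
distance, tree cut at k=3 — and clusters are named rich / intermediate /
poor by descending mean transformed panel expression.  Differential genes
of the NK cell-mediated cytotoxicity and Wnt pathways (Welch t, BH-FDR,
rich vs intermediate+poor) form a signature used to assign external
cohorts to {rich, intermediate/poor} with a correlation-distance kNN vote
on per-cohort z-scored signature expression.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist

from ._utils import bh_q
from .gene_sets import GeneSetCollection

__all__ = [
    "SubtypeAssignment",
    "cluster_time_subtypes",
    "signature_genes",
    "knn_assign",
    "COLLAPSED_OTHER",
]

COLLAPSED_OTHER = "intermediate/poor"
_K3_LABELS = ("rich", "intermediate", "poor")


@dataclasses.dataclass
class SubtypeAssignment:
    """Sample -> subtype labels plus the clustering metadata that made them."""

    labels: pd.Series
    cluster_ids: pd.Series
    method: str = "average"
    metric: str = "correlation"
    k: int = 3

    def samples_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def collapsed(self) -> pd.Series:
        """Labels collapsed to {rich, intermediate/poor}."""
        out = self.labels.where(self.labels == "rich", COLLAPSED_OTHER)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "cluster_id": self.cluster_ids}
        ).rename_axis("sample")


def _log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    return np.log10(expr + 1.0)


def cluster_time_subtypes(
    expr: pd.DataFrame,
    panel: list[str],
    k: int = 3,
    method: str = "average",
    metric: str = "correlation",
) -> SubtypeAssignment:
    """Hierarchically cluster samples on panel-gene expression into subtypes.

    Clusters are ordered by descending mean log10(x+1) panel expression;
    with k=3 they are named rich, intermediate, poor.
    """
    n_samples = expr.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
    present = [g for g in panel if g in expr.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 panel genes present in the expression matrix")
    if len(present) < 0.5 * len(panel):
        warnings.warn(
            f"only {len(present)}/{len(panel)} panel genes present", stacklevel=2
        )
    x = _log_transform(expr.loc[present]).to_numpy().T  # samples x genes
    dist = pdist(x, metric=metric)
    link = hierarchy.linkage(dist, method=method)
    cluster_ids = hierarchy.fcluster(link, t=k, criterion="maxclust")

    means = {
        cid: float(x[cluster_ids == cid].mean()) for cid in np.unique(cluster_ids)
    }
    order = sorted(means, key=lambda cid: -means[cid])
    if len(order) == 3:
        names = dict(zip(order, _K3_LABELS))
    else:
        names = {cid: f"level{rank}" for rank, cid in enumerate(order)}
    labels = pd.Series(
        [names[cid] for cid in cluster_ids], index=expr.columns, name="label"
    )
    return SubtypeAssignment(
        labels=labels,
        cluster_ids=pd.Series(cluster_ids, index=expr.columns, name="cluster_id"),
        method=method,
        metric=metric,
        k=k,
    )


def signature_genes(
    expr: pd.DataFrame,
    assignment: SubtypeAssignment,
    pathway_sets: GeneSetCollection,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Differential pathway genes between rich and intermediate+poor tumors.

    Two-sided Welch t on log10(x+1) per gene restricted to the union of the
    supplied pathway sets; Benjamini-Hochberg over that family; rows with
    q <= q_max are returned sorted by q (columns: gene, t, p, q, direction).
    """
    rich = assignment.samples_with("rich")
    other = [s for s in assignment.labels.index if s not in set(rich)]
    if len(rich) < 2 or len(other) < 2:
        raise ValueError("both comparison groups need >= 2 samples")
    family: list[str] = []
    seen: set[str] = set()
    for name in pathway_sets.names():
        for g in pathway_sets[name]:
            if g not in seen and g in expr.index:
                seen.add(g)
                family.append(g)
    if not family:
        raise ValueError("no pathway gene present in the expression matrix")
    x = _log_transform(expr.loc[family, rich]).to_numpy()
    y = _log_transform(expr.loc[family, other]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    # genes with identical constant values in both groups yield nan: no signal
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_q(p)
    out = pd.DataFrame(
        {
            "gene": family,
            "t": t_stat,
            "p": p,
            "q": q,
            "direction": np.sign(t_stat).astype(int),
        }
    )
    out = out[out["q"] <= q_max].sort_values(["q", "gene"], kind="stable")
    return out.reset_index(drop=True)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def knn_assign(
    expr_query: pd.DataFrame,
    expr_ref: pd.DataFrame,
    assignment_ref: SubtypeAssignment,
    signature: pd.DataFrame | list[str],
    k: int = 5,
) -> pd.Series:
    """Assign query samples to {rich, intermediate/poor} by kNN vote.

    Both cohorts are restricted to the signature genes and per-gene z-scored
    within cohort (cross-platform harmonization); neighbors are found under
    1 - Pearson correlation; ties break toward intermediate/poor.
    """
    genes = list(signature["gene"]) if isinstance(signature, pd.DataFrame) else list(signature)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > expr_ref.shape[1]:
        raise ValueError(f"k={k} exceeds reference size ({expr_ref.shape[1]})")
    shared = [g for g in genes if g in expr_query.index and g in expr_ref.index]
    if not shared:
        raise ValueError("no signature gene shared by query and reference matrices")
    if len(shared) < 0.8 * len(genes):
        warnings.warn(
            f"only {len(shared)}/{len(genes)} signature genes shared", stacklevel=2
        )
    xq = _zscore_rows(_log_transform(expr_query.loc[shared]).to_numpy()).T
    xr = _zscore_rows(_log_transform(expr_ref.loc[shared]).to_numpy()).T
    dist = cdist(xq, xr, metric="correlation")
    ref_is_rich = (assignment_ref.labels.loc[expr_ref.columns] == "rich").to_numpy()
    labels = []
    for row in dist:
        nn = np.argsort(row, kind="stable")[:k]
        rich_votes = int(ref_is_rich[nn].sum())
        labels.append("rich" if rich_votes * 2 > k else COLLAPSED_OTHER)
    return pd.Series(labels, index=expr_query.columns, name="label")
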