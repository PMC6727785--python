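"""Downstream association statistics.

Survival is compared with the Mantel-Cox log-rank test built from explicit
risk tables: at every distinct event time the observed events and the
hypergeometric expectation/variance are accumulated, giving
chi2 = (O1 - E1)^2 / V, a hazard-ratio estimate (O1/E1)/(O2/E2) (the
Pike O/E estimator, with a log-scale CI from variance 1/E1 + 1/E2), and
Kaplan-Meier product-limit curves per group.  The module also covers the
burden-TIL correlation, ligand stratification of the burden tails, Fisher
subtype enrichment, the case-control mutation comparison, a seeded
randomization (permutation) null for gene-set association, and
hypergeometric over-representation of pathways.
"""

from __future__ import annotations

import dataclasses
import warnings
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import bh_q
from .gene_sets import GeneSetCollection
from .subtypes import SubtypeAssignment

__all__ = [
    "SurvivalComparison",
    "split_quantile_groups",
    "logrank_test",
    "kaplan_meier",
    "burden_til_correlation",
    "ligand_stratification",
    "fisher_subtype_enrichment",
    "case_control_test",
    "randomization_test",
    "hypergeom_enrichment",
]


def split_quantile_groups(
    burden: pd.Series,
    top_frac: float = 0.30,
    bottom_frac: float = 0.30,
) -> dict[str, list[str]]:
    """Top/bottom burden groups (default the 30% tails).

    Samples are sorted by burden with ties broken by sample id; the high
    group is the ceil(top_frac * n) largest, the low group the
    ceil(bottom_frac * n) smallest.
    """
    n = len(burden)
    if n < 4:
        raise ValueError("need at least 4 samples to form groups")
    if not (0 < top_frac and 0 < bottom_frac and top_frac + bottom_frac <= 1):
        raise ValueError("fractions must be positive and sum to at most 1")
    if burden.nunique() == 1:
        warnings.warn(
            "all burdens equal; groups determined solely by sample-id order",
            stacklevel=2,
        )
    order = burden.sort_index().sort_values(kind="stable")
    n_low = ceil(bottom_frac * n)
    n_high = ceil(top_frac * n)
    return {
        "high": list(order.index[-n_high:]),
        "low": list(order.index[:n_low]),
    }


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve: columns time, at_risk, events, survival."""
    order = np.argsort(time, kind="stable")
    time, event = np.asarray(time)[order], np.asarray(event)[order]
    rows = []
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


@dataclasses.dataclass
class SurvivalComparison:
    """Log-rank components and derived quantities for a two-group contrast."""

    n1: int
    n2: int
    observed1: float
    expected1: float
    observed2: float
    expected2: float
    variance: float
    chi2: float
    p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    km1: pd.DataFrame
    km2: pd.DataFrame


def logrank_test(
    clinical: pd.DataFrame, groups: dict[str, list[str]]
) -> SurvivalComparison:
    """Mantel-Cox log-rank test between two sample groups.

    ``groups`` maps two labels to sample-id lists; the first group in
    insertion order is group 1 (its O/E ratio is the HR numerator).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (label1, ids1), (label2, ids2) = groups.items()
    if not ids1 or not ids2:
        raise ValueError("both groups must be non-empty")
    missing = [s for s in [*ids1, *ids2] if s not in clinical.index]
    if missing:
        raise ValueError(f"samples missing from clinical table: {missing[:5]}")
    t1 = clinical.loc[ids1, "time"].to_numpy()
    e1 = clinical.loc[ids1, "event"].to_numpy()
    t2 = clinical.loc[ids2, "time"].to_numpy()
    e2 = clinical.loc[ids2, "event"].to_numpy()
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group")

    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o1 = e1.sum()
    o2 = e2.sum()
    exp1 = 0.0
    exp2 = 0.0
    var = 0.0
    for t in event_times:
        r1 = int((t1 >= t).sum())
        r2 = int((t2 >= t).sum())
        r = r1 + r2
        d = int(((t1 == t) & (e1 == 1)).sum() + ((t2 == t) & (e2 == 1)).sum())
        exp1 += d * r1 / r
        exp2 += d * r2 / r
        if r > 1:
            var += d * (r1 / r) * (r2 / r) * (r - d) / (r - 1)
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - exp1) ** 2 / var
        p = float(sps.chi2.sf(chi2, df=1))
    if o1 == 0 or o2 == 0 or exp1 == 0 or exp2 == 0:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    else:
        hr = (o1 / exp1) / (o2 / exp2)
        se = np.sqrt(1.0 / exp1 + 1.0 / exp2)
        ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    return SurvivalComparison(
        n1=len(ids1),
        n2=len(ids2),
        observed1=float(o1),
        expected1=float(exp1),
        observed2=float(o2),
        expected2=float(exp2),
        variance=float(var),
        chi2=float(chi2),
        p=float(p),
        hazard_ratio=float(hr),
        hr_ci=ci,
        km1=kaplan_meier(t1, e1),
        km2=kaplan_meier(t2, e2),
    )


def burden_til_correlation(burden: pd.Series, profile: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of burden with each cell type's TIL score.

    Returns per-cell-type r and two-sided p (t transform, n-2 df) plus a
    ``mean`` row averaging r across cell types.
    """
    shared = [s for s in profile.index if s in burden.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    b = burden.loc[shared].to_numpy(dtype=float)
    if np.all(b == b[0]):
        raise ValueError("burden is constant; correlation undefined")
    rows = []
    for cell_type in profile.columns:
        r, p = sps.pearsonr(b, profile.loc[shared, cell_type].to_numpy())
        rows.append({"cell_type": cell_type, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {"cell_type": "mean", "r": out["r"].mean(), "p": float("nan")}
    return out


def _median_split(scores: pd.Series) -> tuple[list[str], list[str]]:
    """Split by score into low/high halves differing in size by at most 1."""
    order = scores.sort_index().sort_values(kind="stable")
    half = len(order) // 2
    return list(order.index[:half]), list(order.index[half:])


def ligand_stratification(
    burden: pd.Series,
    expr: pd.DataFrame,
    ligand_set: list[str],
    profile: pd.DataFrame,
    bottom_frac: float = 0.10,
    top_frac: float = 0.10,
) -> pd.DataFrame:
    """Ligand high/low TIL contrast within the burden tails.

    Within the bottom-``bottom_frac`` (and separately top-``top_frac``)
    burden samples, samples are scored by mean log10(x+1) expression of
    the NK-activating-receptor ligands and median-split into high/low
    ligand groups; each TIL cell type is compared between ligand groups
    with a Welch t test.  Rows: tail x cell type.
    """
    ligands = [g for g in ligand_set if g in expr.index]
    if not ligands:
        raise ValueError("ligand set does not overlap the expression matrix")
    n = len(burden)
    order = burden.sort_index().sort_values(kind="stable")
    tails = {
        "bottom": list(order.index[: ceil(bottom_frac * n)]),
        "top": list(order.index[-ceil(top_frac * n) :]),
    }
    rows = []
    for tail, ids in tails.items():
        if len(ids) < 4:
            raise ValueError(f"{tail} burden tail has fewer than 4 samples")
        ligand_score = np.log10(expr.loc[ligands, ids] + 1.0).mean(axis=0)
        low_ids, high_ids = _median_split(ligand_score)
        for cell_type in profile.columns:
            hi = profile.loc[high_ids, cell_type].to_numpy()
            lo = profile.loc[low_ids, cell_type].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = sps.ttest_ind(hi, lo, equal_var=False)
            rows.append(
                {
                    "tail": tail,
                    "cell_type": cell_type,
                    "n_high": len(high_ids),
                    "n_low": len(low_ids),
                    "mean_high": float(hi.mean()),
                    "mean_low": float(lo.mean()),
                    "t": float(t) if np.isfinite(t) else 0.0,
                    "p": float(p) if np.isfinite(p) else 1.0,
                }
            )
    return pd.DataFrame(rows)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample OR of [[a, b], [c, d]] with Haldane-Anscombe 0.5 on zero cells."""
    if min(a, b, c, d) == 0:
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_subtype_enrichment(
    matrix: pd.DataFrame,
    assignment: SubtypeAssignment,
    gene: str,
) -> dict[str, float]:
    """Fisher exact test of one gene's mutations, intermediate+poor vs rich."""
    if gene not in matrix.index:
        raise ValueError(f"gene {gene!r} not in mutation matrix")
    rich = [s for s in assignment.samples_with("rich") if s in matrix.columns]
    other = [
        s
        for s in assignment.labels.index
        if s not in set(rich) and s in matrix.columns
    ]
    if not rich or not other:
        raise ValueError("both strata must be non-empty")
    a = int(matrix.loc[gene, other].sum())
    b = len(other) - a
    c = int(matrix.loc[gene, rich].sum())
    d = len(rich) - c
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"odds_ratio": _sample_odds_ratio(a, b, c, d), "p": float(p)}


def case_control_test(
    matrix_cases: pd.DataFrame,
    matrix_controls: pd.DataFrame,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene mutation comparison, patients vs no-cancer controls.

    Chi-squared without continuity correction, switching to Fisher's exact
    test when an expected count is below 5; OR with Haldane-Anscombe
    correction on zero cells; BH q over the tested genes.
    """
    from .discovery import _test_2x2  # shared expected-count switch rule

    shared = [g for g in genes if g in matrix_cases.index and g in matrix_controls.index]
    missing = sorted(set(genes) - set(shared))
    if missing:
        warnings.warn(f"genes absent from a matrix skipped: {missing[:5]}", stacklevel=2)
    n_cases = matrix_cases.shape[1]
    n_controls = matrix_controls.shape[1]
    rows = []
    for gene in shared:
        a = int(matrix_cases.loc[gene].sum())
        b = n_cases - a
        c = int(matrix_controls.loc[gene].sum())
        d = n_controls - c
        statistic, p, test = _test_2x2(a, b, c, d)
        rows.append(
            {
                "gene": gene,
                "mut_cases": a,
                "mut_controls": c,
                "odds_ratio": _sample_odds_ratio(a, b, c, d),
                "statistic": statistic,
                "test": test,
                "p": p,
                "direction": int(np.sign(a / n_cases - c / n_controls)),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mut_cases",
            "mut_controls",
            "odds_ratio",
            "statistic",
            "test",
            "p",
            "direction",
        ],
    )
    report["q"] = bh_q(report["p"].to_numpy()) if len(report) else []
    return report


def _mean_burden_til_r(
    burden_values: np.ndarray, scores_centered: np.ndarray, scores_norm: np.ndarray
) -> float:
    """Mean across cell types of Pearson r(burden, TIL score)."""
    b = burden_values.astype(float)
    bc = b - b.mean()
    bnorm = np.sqrt((bc**2).sum())
    if bnorm == 0:
        return 0.0
    denom = bnorm * scores_norm
    denom = np.where(denom == 0, np.inf, denom)
    return float((bc @ scores_centered / denom).mean())


def randomization_test(
    matrix: pd.DataFrame,
    profile: pd.DataFrame,
    clinical: pd.DataFrame | None,
    candidate_set: list[str],
    universe: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "til_correlation",
) -> dict:
    """Can a gene set this predictive arise by chance?

    The observed statistic for ``candidate_set`` is compared with the same
    statistic for ``n_perm`` random gene sets of identical size drawn
    without replacement from ``universe``.  The default statistic is the
    mean burden-TIL Pearson correlation across cell types (more negative =
    stronger); ``statistic="logrank"`` uses the top/bottom-30% log-rank
    chi2 instead (larger = stronger).  The empirical p uses the +1
    convention, so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stray = sorted(set(candidate_set) - set(universe))
    if stray:
        raise ValueError(f"candidate genes outside the universe: {stray[:5]}")
    if statistic not in ("til_correlation", "logrank"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "logrank" and clinical is None:
        raise ValueError("clinical table required for the log-rank statistic")
    row_of = {g: i for i, g in enumerate(matrix.index)}
    missing = sorted(g for g in universe if g not in row_of)
    if missing:
        raise ValueError(f"universe genes absent from matrix: {missing[:5]}")
    profile = profile.loc[matrix.columns]
    matrix_values = matrix.to_numpy()
    scores = profile.to_numpy(dtype=float)
    scores_centered = scores - scores.mean(axis=0)
    scores_norm = np.sqrt((scores_centered**2).sum(axis=0))

    def evaluate(gene_rows: np.ndarray) -> float:
        b = matrix_values[gene_rows].sum(axis=0)
        if statistic == "til_correlation":
            return _mean_burden_til_r(b, scores_centered, scores_norm)
        groups = split_quantile_groups(pd.Series(b, index=matrix.columns))
        return logrank_test(clinical, groups).chi2

    observed = evaluate(np.array([row_of[g] for g in candidate_set]))
    rng = np.random.default_rng(seed)
    universe_rows = np.array([row_of[g] for g in universe])
    null = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-burden ties in null draws
        for i in range(n_perm):
            pick = rng.choice(universe_rows, size=len(candidate_set), replace=False)
            null[i] = evaluate(pick)
    if statistic == "til_correlation":
        p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    else:
        p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return {"observed": observed, "null": null, "p": p, "statistic": statistic}


def hypergeom_enrichment(
    gene_list: list[str],
    pathway_sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Over-representation of each pathway in a gene list (upper-tail
    hypergeometric p, BH q across pathways)."""
    if not universe:
        raise ValueError("empty universe")
    pool = set(universe)
    stray = sorted(set(gene_list) - pool)
    if stray:
        raise ValueError(f"gene list outside the universe: {stray[:5]}")
    listed = set(gene_list)
    m = len(pool)
    rows = []
    for term in pathway_sets.names():
        members = pool & set(pathway_sets[term])
        k = len(listed & members)
        p = float(sps.hypergeom.sf(k - 1, m, len(members), len(listed)))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": len(members),
                "list_size": len(listed),
                "universe_size": m,
                "p": p,
            }
        )
    report = pd.DataFrame(rows)
    report["q"] = bh_q(report["p"].to_numpy()) if len(report) else []
    return report
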