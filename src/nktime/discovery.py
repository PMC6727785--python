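"""Candidate NK-deficiency (NKD) gene discovery.

Per gene, a 2x2 table (functionally mutated vs not x TIME-rich vs
intermediate+poor) is tested with a chi-squared test (no continuity
correction), switching to Fisher's exact test when any expected count
falls below 5; q-values are Benjamini-Hochberg over the tested family.
Candidates enriched in the non-rich subtypes are then passed through the
expression filter, which removes genes expressed significantly higher in
TIME-rich tumors (one-sided Welch t, BH within the candidate family).
The surviving NK-specific genes are the potential NKD genes; defective
ITAM-signaling genes passing the same mutation test can be merged in,
with per-gene provenance recorded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_q
from .subtypes import SubtypeAssignment

__all__ = [
    "differential_mutation_test",
    "expression_filter",
    "identify_potential_nkd",
    "combine_with_itam",
]


def _strata(assignment: SubtypeAssignment) -> tuple[list[str], list[str]]:
    rich = assignment.samples_with("rich")
    other = [s for s in assignment.labels.index if s not in set(rich)]
    if not rich or not other:
        raise ValueError("both strata (rich and intermediate/poor) must be non-empty")
    return rich, other


def _test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, str]:
    """Test [[a, b], [c, d]]; returns (statistic, p, test name).

    a/b: mutated/non-mutated in the first stratum, c/d in the second.
    Degenerate margins (no mutations at all, or everything mutated) get
    the p = 1 convention.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=1).min() == 0 or (a + c == 0) or (b + d == 0):
        return 0.0, 1.0, "degenerate"
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if expected.min() < 5:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float("nan"), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2"


def differential_mutation_test(
    matrix: pd.DataFrame,
    assignment: SubtypeAssignment,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene mutation-frequency test, rich vs intermediate+poor.

    Returns a report with the 2x2 counts, the statistic, the test used
    (chi2 / fisher / degenerate), p, BH q over the tested family, and the
    enrichment direction (+1 when the non-rich strata carry more
    mutations, -1 when rich does, 0 for no signal).
    """
    rich, other = _strata(assignment)
    rich = [s for s in rich if s in matrix.columns]
    other = [s for s in other if s in matrix.columns]
    if not rich or not other:
        raise ValueError("assignment samples not found in the mutation matrix")
    rows = []
    for gene in genes:
        if gene not in matrix.index:
            warnings.warn(f"gene {gene!r} absent from mutation matrix; skipped", stacklevel=2)
            continue
        mut_other = int(matrix.loc[gene, other].sum())
        mut_rich = int(matrix.loc[gene, rich].sum())
        a, b = mut_other, len(other) - mut_other
        c, d = mut_rich, len(rich) - mut_rich
        statistic, p, test = _test_2x2(a, b, c, d)
        rate_other = mut_other / len(other)
        rate_rich = mut_rich / len(rich)
        direction = int(np.sign(rate_other - rate_rich))
        rows.append(
            {
                "gene": gene,
                "mut_other": a,
                "nonmut_other": b,
                "mut_rich": c,
                "nonmut_rich": d,
                "statistic": statistic,
                "test": test,
                "p": p,
                "direction": direction,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mut_other",
            "nonmut_other",
            "mut_rich",
            "nonmut_rich",
            "statistic",
            "test",
            "p",
            "direction",
        ],
    )
    if len(report):
        report["q"] = bh_q(report["p"].to_numpy())
    else:
        report["q"] = []
    return report


def expression_filter(
    candidates: list[str],
    expr: pd.DataFrame,
    assignment: SubtypeAssignment,
    q_max: float = 0.05,
) -> list[str]:
    """Drop candidates expressed significantly higher in TIME-rich tumors.

    One-sided Welch t (rich > intermediate+poor) on log10(x+1); BH within
    the candidate family; a gene is dropped iff q <= q_max.  Genes absent
    from the matrix pass through with a warning.
    """
    if not candidates:
        return []
    rich, other = _strata(assignment)
    present = [g for g in candidates if g in expr.index]
    absent = [g for g in candidates if g not in expr.index]
    if absent:
        warnings.warn(
            f"{len(absent)} candidate(s) absent from expression matrix kept: {absent[:5]}",
            stacklevel=2,
        )
    if not present:
        return list(candidates)
    x = np.log10(expr.loc[present, rich].to_numpy() + 1.0)
    y = np.log10(expr.loc[present, other].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False, alternative="greater")
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_q(p)
    dropped = {g for g, qg in zip(present, q) if qg <= q_max}
    return [g for g in candidates if g not in dropped]


def identify_potential_nkd(
    matrix: pd.DataFrame,
    expr: pd.DataFrame,
    assignment: SubtypeAssignment,
    nk_specific: list[str],
    q_max: float = 0.05,
) -> list[str]:
    """NK-specific genes enriched for functional mutations outside TIME-rich
    tumors and not preferentially expressed in TIME-rich tumors.

    Output order is deterministic: ascending q, then gene id.
    """
    report = differential_mutation_test(matrix, assignment, nk_specific)
    hits = report[(report["direction"] > 0) & (report["q"] <= q_max)]
    hits = hits.sort_values(["q", "gene"], kind="stable")
    kept = expression_filter(list(hits["gene"]), expr, assignment, q_max=q_max)
    return kept


def combine_with_itam(
    nkd: list[str],
    itam: list[str],
    matrix: pd.DataFrame,
    assignment: SubtypeAssignment,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Union of potential NKD genes with significantly defective ITAM genes.

    Returns a two-column frame (gene, source); a gene found in both sets is
    reported once with source ``nk_specific``.
    """
    rows = [{"gene": g, "source": "nk_specific"} for g in nkd]
    seen = set(nkd)
    if itam:
        report = differential_mutation_test(matrix, assignment, list(itam))
        passing = report[(report["direction"] > 0) & (report["q"] <= q_max)]
        for gene in passing.sort_values(["q", "gene"], kind="stable")["gene"]:
            if gene not in seen:
                seen.add(gene)
                rows.append({"gene": gene, "source": "itam"})
    return pd.DataFrame(rows, columns=["gene", "source"])
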