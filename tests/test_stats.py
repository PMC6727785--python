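"""Association statistics: log-rank/KM oracles, Fisher enumeration, BH,
randomization null, hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats as sps

from nktime._utils import bh_q
from nktime.gene_sets import GeneSetCollection
from nktime.stats import (
    burden_til_correlation,
    case_control_test,
    fisher_subtype_enrichment,
    hypergeom_enrichment,
    kaplan_meier,
    ligand_stratification,
    logrank_test,
    randomization_test,
    split_quantile_groups,
)
from nktime.subtypes import SubtypeAssignment


def clinical_frame(times, events, prefix="s"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"time": list(map(float, times)), "event": list(events)},
        index=pd.Index(idx, name="sample"),
    )


class TestSplitQuantileGroups:
    def test_distinct_burdens_split_exactly(self):
        burden = pd.Series(range(10), index=[f"s{i}" for i in range(10)])
        groups = split_quantile_groups(burden)
        assert {int(burden[s]) for s in groups["high"]} == {7, 8, 9}
        assert {int(burden[s]) for s in groups["low"]} == {0, 1, 2}

    def test_all_equal_burdens_warn_and_split_by_id(self):
        burden = pd.Series(1, index=[f"s{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="id order"):
            groups = split_quantile_groups(burden)
        assert len(groups["high"]) == 3 and len(groups["low"]) == 3
        assert not set(groups["high"]) & set(groups["low"])

    def test_overlapping_fractions_rejected(self):
        burden = pd.Series(range(10), index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="fractions"):
            split_quantile_groups(burden, top_frac=0.6, bottom_frac=0.6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4"):
            split_quantile_groups(pd.Series([1, 2, 3], index=list("abc")))


class TestLogrank:
    def test_identical_groups_are_null(self):
        clin = clinical_frame([5, 10, 15, 5, 10, 15], [1, 0, 1, 1, 0, 1])
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        res = logrank_test(clin, groups)
        assert res.chi2 == 0.0
        assert res.p == 1.0
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_six_subject_worked_case_matches_hand_enumeration(self):
        """Risk tables enumerated by hand: A events at 2,4,6; B at 3,5,7.

        t=2: (rA,rB)=(3,3) E_A+=1/2 V+=1/4;  t=3: (2,3) E_A+=2/5 V+=6/25;
        t=4: (2,2) E_A+=1/2 V+=1/4;          t=5: (1,2) E_A+=1/3 V+=2/9;
        t=6: (1,1) E_A+=1/2 V+=1/4;          t=7: (0,1) E_A+=0 V+=0.
        """
        e1 = Fraction(1, 2) + Fraction(2, 5) + Fraction(1, 2) + Fraction(1, 3) + Fraction(1, 2)
        var = (
            Fraction(1, 4) + Fraction(6, 25) + Fraction(1, 4) + Fraction(2, 9) + Fraction(1, 4)
        )
        chi2 = (3 - e1) ** 2 / var
        assert e1 == Fraction(67, 30) and var == Fraction(1091, 900)

        clin = clinical_frame([2, 4, 6, 3, 5, 7], [1] * 6)
        res = logrank_test(clin, {"A": ["s0", "s1", "s2"], "B": ["s3", "s4", "s5"]})
        assert res.observed1 == 3
        assert res.expected1 == pytest.approx(float(e1), abs=1e-10)
        assert res.variance == pytest.approx(float(var), abs=1e-10)
        assert res.chi2 == pytest.approx(float(chi2), abs=1e-10)
        hr = (3 / float(e1)) / (3 / float(6 - e1))
        assert res.hazard_ratio == pytest.approx(hr, abs=1e-10)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            n = 60
            times = rng.exponential(100, n).round(1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            clin = clinical_frame(times, events)
            ids = list(clin.index)
            res = logrank_test(clin, {"a": ids[:30], "b": ids[30:]})
            ref = ll_logrank(
                times[:30], times[30:], event_observed_A=events[:30],
                event_observed_B=events[30:],
            )
            assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert res.p == pytest.approx(ref.p_value, abs=1e-10)

    def test_oe_conservation_property(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            times = rng.integers(1, 20, n).astype(float)  # heavy ties
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            clin = clinical_frame(times, events)
            ids = list(clin.index)
            k = int(rng.integers(1, n))
            res = logrank_test(clin, {"a": ids[:k], "b": ids[k:]})
            total = res.observed1 + res.observed2
            assert res.expected1 + res.expected2 == pytest.approx(total, abs=1e-10)
            assert res.chi2 >= 0

    def test_error_cases(self):
        clin = clinical_frame([1, 2], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            logrank_test(clin, {"a": ["s0"], "b": ["s1"]})
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test(clin, {"a": [], "b": ["s1"]})


class TestKaplanMeier:
    def test_no_events_is_constant_one(self):
        km = kaplan_meier(np.array([3.0, 5.0]), np.array([0, 0]))
        assert len(km) == 0  # no drops: survival stays 1

    def test_all_events_distinct_times_steps_to_zero(self):
        km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert km["survival"].iloc[-1] == pytest.approx(0.0)
        assert list(km["survival"]) == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_matches_lifelines(self):
        rng = np.random.default_rng(12)
        times = rng.integers(1, 15, 40).astype(float)
        events = rng.integers(0, 2, 40)
        km = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.survival_function_at_times(row["time"]).iloc[0]), abs=1e-10
            )


class TestBenjaminiHochberg:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=100)
    )
    def test_matches_reference_step_up(self, p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        ref = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, p[i] * m / rank)
            ref[i] = running_min
        assert bh_q(p) == pytest.approx(ref, abs=1e-12)

    def test_single_p_is_its_own_q(self):
        assert bh_q([0.03]) == pytest.approx([0.03])


def two_sided_fisher_enumeration(a, b, c, d):
    """Full enumeration: sum point probabilities <= that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pt(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    obs = pt(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(pt(x) for x in range(lo, hi + 1) if pt(x) <= obs))


class TestFisher:
    def test_balanced_table_is_null(self):
        assignment = _assignment_from_counts(10, 10)
        matrix = _matrix_from_counts(assignment, mut_rich=5, mut_other=5)
        res = fisher_subtype_enrichment(matrix, assignment, "G")
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_enumeration_oracle_on_fixed_table(self):
        want = two_sided_fisher_enumeration(8, 2, 1, 9)
        _, got = sps.fisher_exact([[8, 2], [1, 9]])
        assert got == pytest.approx(want, abs=1e-12)
        assignment = _assignment_from_counts(10, 10)
        matrix = _matrix_from_counts(assignment, mut_rich=1, mut_other=8)
        res = fisher_subtype_enrichment(matrix, assignment, "G")
        assert res["p"] == pytest.approx(want, abs=1e-12)

    def test_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n1, n2 = rng.integers(2, 21, 2)
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            want = two_sided_fisher_enumeration(a, int(n1) - a, c, int(n2) - c)
            _, got = sps.fisher_exact([[a, n1 - a], [c, n2 - c]])
            assert got == pytest.approx(want, abs=1e-11)

    def test_zero_mutation_gene_uses_corrected_or(self):
        assignment = _assignment_from_counts(10, 10)
        matrix = _matrix_from_counts(assignment, mut_rich=0, mut_other=0)
        res = fisher_subtype_enrichment(matrix, assignment, "G")
        assert res["p"] == 1.0
        assert res["odds_ratio"] == pytest.approx(1.0)  # (0.5*10.5)/(10.5*0.5)


def _assignment_from_counts(n_rich, n_other):
    samples = [f"r{i}" for i in range(n_rich)] + [f"o{i}" for i in range(n_other)]
    labels = pd.Series(["rich"] * n_rich + ["poor"] * n_other, index=samples)
    return SubtypeAssignment(labels=labels, cluster_ids=pd.Series(1, index=samples))


def _matrix_from_counts(assignment, mut_rich, mut_other):
    rich = assignment.samples_with("rich")
    other = [s for s in assignment.labels.index if s not in set(rich)]
    m = pd.DataFrame(0, index=pd.Index(["G"], name="gene"), columns=assignment.labels.index)
    m.loc["G", rich[:mut_rich]] = 1
    m.loc["G", other[:mut_other]] = 1
    return m


class TestCaseControl:
    def test_identical_matrices_are_null(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(5, 40)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(40)],
        )
        rep = case_control_test(m, m, list(m.index))
        assert np.allclose(rep["p"], 1.0)
        assert np.allclose(rep["odds_ratio"], 1.0)

    def test_single_gene_q_equals_p(self):
        rng = np.random.default_rng(15)
        cases = pd.DataFrame(
            rng.integers(0, 2, size=(1, 100)), index=["g"], columns=[f"c{i}" for i in range(100)]
        )
        controls = pd.DataFrame(
            rng.integers(0, 2, size=(1, 100)), index=["g"], columns=[f"n{i}" for i in range(100)]
        )
        rep = case_control_test(cases, controls, ["g"])
        assert rep.loc[0, "q"] == pytest.approx(rep.loc[0, "p"])


class TestBurdenTILCorrelation:
    def test_perfect_correlation_when_burden_equals_score(self):
        idx = [f"s{i}" for i in range(20)]
        b = pd.Series(np.arange(20), index=idx)
        prof = pd.DataFrame({"NK": np.arange(20, dtype=float)}, index=idx)
        out = burden_til_correlation(b, prof)
        assert out.loc[out.cell_type == "NK", "r"].iloc[0] == pytest.approx(1.0)

    def test_constant_burden_rejected(self):
        idx = [f"s{i}" for i in range(10)]
        b = pd.Series(1, index=idx)
        prof = pd.DataFrame({"NK": np.arange(10, dtype=float)}, index=idx)
        with pytest.raises(ValueError, match="constant"):
            burden_til_correlation(b, prof)


class TestLigandStratification:
    def test_median_split_sizes_differ_by_at_most_one(self, cohort, universe_sets, profile, mutation_matrix):
        sets, _ = universe_sets
        from nktime.germline import burden

        b = burden(mutation_matrix, cohort.truth.nkd_genes)
        out = ligand_stratification(b, cohort.expression, sets["ligand"], profile)
        assert (abs(out["n_high"] - out["n_low"]) <= 1).all()

    def test_tiny_tail_rejected(self, cohort, universe_sets, profile, mutation_matrix):
        sets, _ = universe_sets
        from nktime.germline import burden

        b = burden(mutation_matrix, cohort.truth.nkd_genes)
        with pytest.raises(ValueError, match="fewer than 4"):
            ligand_stratification(
                b, cohort.expression, sets["ligand"], profile, bottom_frac=0.001,
                top_frac=0.001,
            )


class TestRandomization:
    @pytest.fixture()
    def toy_data(self):
        rng = np.random.default_rng(16)
        samples = [f"s{i}" for i in range(30)]
        genes = [f"g{i}" for i in range(40)]
        matrix = pd.DataFrame(
            rng.integers(0, 2, size=(40, 30)), index=genes, columns=samples
        )
        profile = pd.DataFrame(
            rng.normal(size=(30, 3)), index=samples, columns=["NK", "CD8T", "gdT"]
        )
        return matrix, profile, genes

    def test_fixed_seed_reproduces_null(self, toy_data):
        matrix, profile, genes = toy_data
        a = randomization_test(matrix, profile, None, genes[:5], genes, n_perm=50, seed=3)
        b = randomization_test(matrix, profile, None, genes[:5], genes, n_perm=50, seed=3)
        assert np.array_equal(a["null"], b["null"])
        assert a["p"] == b["p"]

    def test_extreme_observed_gets_minimal_p(self, toy_data):
        matrix, profile, genes = toy_data
        # make the candidate burden perfectly anti-correlated with all scores
        b = matrix.loc[genes[:5]].sum(axis=0).astype(float)
        profile = pd.DataFrame(
            {ct: -b + 1e-9 * np.arange(len(b)) for ct in ["NK", "CD8T"]},
            index=matrix.columns,
        )
        out = randomization_test(
            matrix, profile, None, genes[:5], genes, n_perm=99, seed=4
        )
        assert out["p"] == pytest.approx(1 / 100)

    def test_p_never_zero_and_bounded(self, toy_data):
        matrix, profile, genes = toy_data
        out = randomization_test(matrix, profile, None, genes[:5], genes, n_perm=19, seed=5)
        assert 0 < out["p"] <= 1

    def test_candidates_outside_universe_rejected(self, toy_data):
        matrix, profile, genes = toy_data
        with pytest.raises(ValueError, match="outside"):
            randomization_test(matrix, profile, None, ["nope"], genes, n_perm=5, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            randomization_test(matrix, profile, None, genes[:2], genes, n_perm=0, seed=0)


class TestHypergeomEnrichment:
    def test_full_overlap_tail_matches_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection(name="p", sets={"path": universe[:5]})
        rep = hypergeom_enrichment(universe[:5], sets, universe)
        want = comb(5, 5) * comb(15, 0) / comb(20, 5)
        assert rep.loc[0, "p"] == pytest.approx(want, abs=1e-12)

    def test_disjoint_pathway_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection(name="p", sets={"path": universe[10:15]})
        rep = hypergeom_enrichment(universe[:5], sets, universe)
        assert rep.loc[0, "p"] == 1.0

    def test_pathway_equal_to_universe_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection(name="p", sets={"path": universe})
        rep = hypergeom_enrichment(universe[:3], sets, universe)
        assert rep.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        sets = GeneSetCollection(name="p", sets={"path": ["a"]})
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment([], sets, [])
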