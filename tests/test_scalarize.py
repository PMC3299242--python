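"""Weighted-sum selection and the Pareto max-efficiency certificate."""

import math

import numpy as np
import pandas as pd
import pytest

from mei.cohort import CohortTable, WeightScheme
from mei.criteria import CriterionMatrix, build_criterion_matrix
from mei.scalarize import (
    AssignmentProblem,
    expand_lambda,
    pareto_efficient,
    select_treatment,
    synthesis_value,
)

from conftest import STUDY_WEIGHTS, make_cell, random_full_cells


def matrix_from_array(scores: np.ndarray) -> CriterionMatrix:
    """Wrap an (m treatments × n criteria) array as a criterion matrix."""
    m, n = scores.shape
    rows = [
        {
            "treatment_id": f"T{t + 1}",
            "age_group": "g",
            "phototype": "p",
            "family": f"F{k}",
            "k_index": None,
            "score": float(scores[t, k]),
        }
        for t in range(m)
        for k in range(n)
    ]
    return CriterionMatrix(pd.DataFrame(rows), "mei_eq5", 1.0)


def brute_force_pareto(scores: np.ndarray) -> set[str]:
    """Independent dominance oracle on the raw score array."""
    m = scores.shape[0]
    efficient = set()
    for a in range(m):
        dominated = any(
            (scores[b] >= scores[a]).all() and (scores[b] > scores[a]).any()
            for b in range(m)
            if b != a
        )
        if not dominated:
            efficient.add(f"T{a + 1}")
    return efficient


class TestLambdaExpansion:
    def test_family_weight_fills_its_six_slots(self):
        lam = expand_lambda(STUDY_WEIGHTS)
        assert all(lam[k] == 0.125 for k in range(1, 7))  # t_E
        assert all(lam[k] == 0.5 for k in range(31, 37))  # t_F
        assert all(lam[k] == 0.25 for k in range(55, 61))  # t_C
        assert all(lam[k] == 0.0 for k in range(13, 19))  # t_L unset
        assert len(lam) == 60


class TestSynthesisValue:
    def test_case_study_values(self, two_arm_table):
        problem = AssignmentProblem(
            build_criterion_matrix(two_arm_table), STUDY_WEIGHTS
        )
        assert math.isclose(
            synthesis_value(problem, "P63"), 0.812726, abs_tol=1e-6
        )
        assert math.isclose(
            synthesis_value(problem, "placebo"), 0.756981, abs_tol=1e-6
        )

    def test_zero_weight_zero_cost_gives_zero(self):
        cell = make_cell(cost=0.0)
        problem = AssignmentProblem(
            build_criterion_matrix(CohortTable((cell,), 400)),
            WeightScheme(t_C=1.0),
        )
        assert synthesis_value(problem, "T1") == 0.0

    def test_unknown_treatment_raises(self, two_arm_table):
        problem = AssignmentProblem(
            build_criterion_matrix(two_arm_table), STUDY_WEIGHTS
        )
        with pytest.raises(KeyError):
            synthesis_value(problem, "nope")


class TestSelectTreatment:
    def test_case_study_selection(self, two_arm_table):
        result = select_treatment(
            AssignmentProblem(build_criterion_matrix(two_arm_table), STUDY_WEIGHTS)
        )
        assert result.chosen == "P63"
        assert not result.tie
        # placebo is cheaper, so both arms sit on the efficacy/cost frontier
        assert result.pareto == {"P63", "placebo"}

    def test_identical_treatments_tie(self, p63_cell):
        import dataclasses

        twin = dataclasses.replace(p63_cell, treatment_id="P63b")
        table = CohortTable((p63_cell, twin), 400)
        result = select_treatment(
            AssignmentProblem(build_criterion_matrix(table), STUDY_WEIGHTS)
        )
        assert result.tie
        assert set(result.maximizers) == {"P63", "P63b"}
        assert result.chosen == "P63"  # lowest identifier

    def test_argmax_of_three(self):
        matrix = matrix_from_array(np.array([[0.5], [0.9], [0.7]]))
        weights = WeightScheme(t_C=1.0)  # any valid scheme; scores are direct
        # weight lookup uses family names; rename to C so t_C applies
        matrix.scores["family"] = "C"
        result = select_treatment(AssignmentProblem(matrix, weights))
        assert result.chosen == "T2"

    def test_single_treatment_rejected(self, p63_cell):
        table = CohortTable((p63_cell,), 400)
        with pytest.raises(ValueError, match="at least 2"):
            select_treatment(
                AssignmentProblem(build_criterion_matrix(table), STUDY_WEIGHTS)
            )

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        weights = WeightScheme(t_E=0.3, t_D=0.2, t_F=0.3, t_C=0.2)
        for m in range(2, 7):
            cells = random_full_cells(rng, m)
            problem = AssignmentProblem(
                build_criterion_matrix(CohortTable(tuple(cells), 400)), weights
            )
            result = select_treatment(problem)
            # brute force over all one-hot assignments
            values = {t: synthesis_value(problem, t) for t in problem.treatments}
            best = max(values, key=lambda t: (values[t], t))
            assert math.isclose(result.values[result.chosen], values[best])

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=(3, 8))
        weights = WeightScheme(t_C=1.0)
        m1 = matrix_from_array(scores)
        m1.scores["family"] = "C"
        first = select_treatment(AssignmentProblem(m1, weights)).chosen
        shifted = scores.copy()
        shifted[:, 3] += 5.0  # same constant for every treatment
        m2 = matrix_from_array(shifted)
        m2.scores["family"] = "C"
        assert select_treatment(AssignmentProblem(m2, weights)).chosen == first


class TestParetoEfficiency:
    def test_strict_domination(self):
        scores = np.array([[2.0, 2.0], [1.0, 1.0]])
        assert pareto_efficient(matrix_from_array(scores)) == {"T1"}

    def test_single_treatment_is_efficient(self):
        assert pareto_efficient(matrix_from_array(np.array([[1.0, 2.0]]))) == {"T1"}

    def test_tradeoff_keeps_both(self):
        scores = np.zeros((2, 60))
        scores[0, :6] = 1.0  # A better on the E block
        scores[1, 54:] = 1.0  # B better on the C block
        result = pareto_efficient(matrix_from_array(scores))
        assert result == brute_force_pareto(scores) == {"T1", "T2"}

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            m = rng.integers(2, 5)
            # coarse scores force frequent domination and ties
            scores = rng.integers(0, 3, size=(m, 5)).astype(float)
            assert pareto_efficient(matrix_from_array(scores)) == brute_force_pareto(
                scores
            )

    def test_every_positive_weight_maximizer_is_pareto(self):
        """Weighted-sum consistency over 1000 random problems, m <= 4.

        Each problem is a random cohort with every criterion family
        present and a strictly positive random weight scheme; every
        maximizer returned by select_treatment must pass the exhaustive
        pairwise dominance oracle on the raw score array.
        """
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = int(rng.integers(2, 5))
            cells = tuple(
                c
                for c in random_full_cells(rng, m)
                if (c.age_group, c.phototype) == ("40-49", "2")
            )
            table = CohortTable(cells, 400)
            raw = rng.uniform(0.05, 1.0, size=10)
            raw /= raw.sum()
            weights = WeightScheme(
                **{f"t_{s}": float(v) for s, v in zip("EDLMHFRQSC", raw)}
            )
            problem = AssignmentProblem(build_criterion_matrix(table), weights)
            result = select_treatment(problem)
            scores = np.array(
                [
                    problem.matrix.vector(t).sort_index().to_numpy()
                    for t in problem.treatments
                ]
            )
            assert set(result.maximizers) <= brute_force_pareto(scores)
            assert set(result.maximizers) <= result.pareto
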