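"""Weighted-sum scalarization over discrete treatment assignments.

Choosing one of m treatments is a 0/1 multicriteria problem: the feasible
set is the one-hot assignment vectors x ∈ {0,1}^m with Σx = 1, and each of
the criteria is linear in x with the normalized subgroup scores as
coefficients.  The weight method collapses the vector objective into one
synthesis function Λ(x) = Σ_k λ_k f_k(x), where λ is constant within each
criterion family (all six cells of family E share t_E, and so on).  With
one-hot feasibility, maximizing Λ is an argmax over the m per-treatment
sums, and any maximizer under strictly positive weights is a max-efficient
(Pareto) point — certified here by exhaustive pairwise dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import WeightScheme
from .criteria import FAMILIES, CriterionMatrix

__all__ = [
    "AssignmentProblem",
    "SelectionResult",
    "expand_lambda",
    "synthesis_value",
    "select_treatment",
    "pareto_efficient",
]


def expand_lambda(weights: WeightScheme) -> dict[int, float]:
    """Expand family weights to the per-criterion λ_1..λ_60 (λ_1..λ_6 = t_E …)."""
    lam: dict[int, float] = {}
    for fam in FAMILIES.values():
        w = weights.weight(fam.code)
        for k in range(fam.base_offset + 1, fam.base_offset + 7):
            lam[k] = w
    return lam


@dataclass(frozen=True)
class AssignmentProblem:
    """A criterion matrix over m treatments plus the family weights."""

    matrix: CriterionMatrix
    weights: WeightScheme

    @property
    def treatments(self) -> list[str]:
        return self.matrix.treatments

    @property
    def lambda_weights(self) -> dict[int, float]:
        return expand_lambda(self.weights)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the assignment optimization.

    ``chosen`` is the deterministic primary pick (lowest identifier among
    the maximizers); ``maximizers`` lists every treatment attaining the
    maximal Λ; ``tie`` flags |maximizers| > 1; ``pareto`` certifies which
    treatments are max-efficient under exhaustive dominance.
    """

    chosen: str
    maximizers: tuple[str, ...]
    values: dict[str, float]
    tie: bool
    pareto: frozenset[str]


def synthesis_value(problem: AssignmentProblem, treatment: str) -> float:
    """Λ evaluated at the one-hot vector selecting *treatment*.

    Criteria with missing data for the treatment contribute 0 (they were
    dropped from the matrix with a diagnostic at build time).
    """
    vec = problem.matrix.vector(treatment)  # KeyError for unknown treatment
    total = 0.0
    for (_age, _ph, family), score in vec.items():
        total += problem.weights.weight(family) * score
    return total


def select_treatment(problem: AssignmentProblem) -> SelectionResult:
    """Enumerate all one-hot assignments and return the argmax of Λ.

    Ties are reported explicitly; the primary choice among maximizers is
    the lowest treatment identifier, a deterministic convention rather
    than a preference.
    """
    tids = problem.treatments
    if len(tids) < 2:
        raise ValueError(f"need at least 2 treatments to select, got {len(tids)}")
    values = {t: synthesis_value(problem, t) for t in tids}
    best = max(values.values())
    maximizers = tuple(t for t in tids if values[t] == best)
    return SelectionResult(
        chosen=min(maximizers),
        maximizers=maximizers,
        values=values,
        tie=len(maximizers) > 1,
        pareto=frozenset(pareto_efficient(problem.matrix)),
    )


def pareto_efficient(matrix: CriterionMatrix) -> set[str]:
    """Treatments not strictly dominated on the shared criteria.

    Treatment b dominates a if, on every criterion with data for both,
    b scores ≥ a with strict inequality somewhere.  Criteria missing for
    either treatment are excluded pairwise from the comparison.
    """
    tids = matrix.treatments
    vectors = {t: matrix.vector(t) for t in tids}
    efficient: set[str] = set()
    for a in tids:
        dominated = False
        for b in tids:
            if b == a:
                continue
            common = vectors[a].index.intersection(vectors[b].index)
            if common.empty:
                continue
            va = vectors[a].loc[common]
            vb = vectors[b].loc[common]
            if (vb >= va).all() and (vb > va).any():
                dominated = True
                break
        if not dominated:
            efficient.add(a)
    return efficient
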