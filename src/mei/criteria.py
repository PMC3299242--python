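"""Normalized per-criterion scores — the coefficients of the 60 objectives.

Each of the ten criterion families (E epidermis, D dermis, L low-, M medium-,
H high-echogenity pixels, F LEPs/LEPi ratio, R no-adverse-effect fraction,
Q convenience mark, S satisfaction mark, C cost) contributes six criteria,
one per (age group j ∈ {1,2,3}, phototype h ∈ {2,3}) cell, for a total of
60.  Benefit families score the post/pre ratio of the subgroup mean (times
the cell's population fraction); the cost family scores −P·C/K; the
adverse-effect family scores −P·R as printed in the source model (see the
``r_as_benefit`` switch).

Two explicit scoring modes exist because the source model's general
criterion list and its closed-form index disagree on two families:

* ``paper_eq2`` — L scores P·pre/post (a *reduction* of low-echogenity
  pixels is the benefit); Q and S score P·mark/10.
* ``mei_eq5``  — L scores P·post/pre, mirroring the closed-form index; Q
  and S would need pre/post marks that the summary schema does not carry,
  so they fall back to mark/10 with a diagnostic.

Neither mode is silently preferred; callers choose.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import RATIO_FAMILIES, CohortTable, Diagnostic, SubgroupCell

__all__ = [
    "CriterionFamily",
    "FAMILIES",
    "CriterionMatrix",
    "benefit_ratio",
    "reduction_ratio",
    "criterion_index",
    "cell_family_score",
    "build_criterion_matrix",
]

MODES = ("paper_eq2", "mei_eq5")


@dataclass(frozen=True)
class CriterionFamily:
    """One of the ten families, with its direction and f_k block offset."""

    code: str
    direction: str  # "benefit" or "burden"
    base_offset: int


FAMILIES: dict[str, CriterionFamily] = {
    code: CriterionFamily(code, direction, offset)
    for code, direction, offset in [
        ("E", "benefit", 0),
        ("D", "benefit", 6),
        ("L", "benefit", 12),
        ("M", "benefit", 18),
        ("H", "benefit", 24),
        ("F", "benefit", 30),
        ("R", "burden", 36),
        ("Q", "benefit", 42),
        ("S", "benefit", 48),
        ("C", "burden", 54),
    ]
}

_STEM = {sym: stem for stem, sym in RATIO_FAMILIES}


def benefit_ratio(pre: float, post: float) -> float:
    """post/pre score for parameters whose increase is the benefit."""
    if not pre > 0:
        raise ValueError(f"pre-treatment mean must be > 0, got {pre}")
    return post / pre


def reduction_ratio(pre: float, post: float) -> float:
    """pre/post score for parameters whose decrease is the benefit."""
    if not post > 0:
        raise ValueError(f"post-treatment mean must be > 0, got {post}")
    return pre / post


def criterion_index(family: CriterionFamily | str, j: int, h: int) -> int:
    """Map (family, age index j, phototype index h) to k ∈ 1..60.

    k = base_offset + 2(j−1) + (h−1); the map is a bijection onto 1..60
    over the 10 families × 3 age groups × 2 phototypes.
    """
    fam = FAMILIES[family] if isinstance(family, str) else family
    if j not in (1, 2, 3):
        raise ValueError(f"age index j must be in {{1,2,3}}, got {j}")
    if h not in (2, 3):
        raise ValueError(f"phototype index h must be in {{2,3}}, got {h}")
    return fam.base_offset + 2 * (j - 1) + (h - 1)


def cell_family_score(
    cell: SubgroupCell,
    family: CriterionFamily | str,
    mode: str = "mei_eq5",
    cost_ceiling: float = 1.0,
    pop_frac: float = 1.0,
    r_as_benefit: bool = False,
) -> float | None:
    """The normalized score of one family in one cell, or None if data absent.

    ``pop_frac`` is the multiplier P (1 for the small/homogenous-sample
    convention); ``cost_ceiling`` is K.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    fam = FAMILIES[family] if isinstance(family, str) else family
    code = fam.code
    if not cell.has_family(code):
        return None
    if code in _STEM:
        pre = getattr(cell, f"{_STEM[code]}_pre")
        post = getattr(cell, f"{_STEM[code]}_post")
        if code == "L" and mode == "paper_eq2":
            return pop_frac * reduction_ratio(pre, post)
        return pop_frac * benefit_ratio(pre, post)
    if code == "R":
        sign = 1.0 if r_as_benefit else -1.0
        return sign * pop_frac * cell.no_adverse_frac
    if code == "Q":
        return pop_frac * cell.q_mean / 10.0
    if code == "S":
        return pop_frac * cell.s_mean / 10.0
    if code == "C":
        return -pop_frac * cell.cost / cost_ceiling
    raise KeyError(code)  # pragma: no cover


@dataclass(frozen=True)
class CriterionMatrix:
    """Per (treatment, cell, family) normalized criterion scores.

    ``scores`` has columns treatment_id, age_group, phototype, family,
    k_index (the f_k enumeration slot where the cell grid matches the
    3-age × 2-phototype layout, else <NA>) and score.  ``diagnostics``
    records dropped families and fallback behaviour.
    """

    scores: pd.DataFrame
    mode: str
    cost_ceiling: float
    diagnostics: tuple[Diagnostic, ...] = ()

    @property
    def treatments(self) -> list[str]:
        out: list[str] = []
        for t in self.scores["treatment_id"]:
            if t not in out:
                out.append(t)
        return out

    def vector(self, treatment_id: str) -> pd.Series:
        """Scores of one treatment indexed by (age_group, phototype, family)."""
        sub = self.scores[self.scores["treatment_id"] == treatment_id]
        if sub.empty:
            raise KeyError(f"unknown treatment {treatment_id!r}")
        return sub.set_index(["age_group", "phototype", "family"])["score"]

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


def _paper_indices(table: CohortTable) -> dict[tuple[str, str], tuple[int, int] | None]:
    """Assign (j, h) slots when the cell grid matches the canonical layout."""
    ages = sorted({c.age_group for c in table.cells})
    photos = sorted({c.phototype for c in table.cells})
    if len(ages) > 3 or len(photos) > 2:
        return {(a, p): None for a in ages for p in photos}
    jmap = {a: i + 1 for i, a in enumerate(ages)}
    hmap = {p: i + 2 for i, p in enumerate(photos)}
    return {(a, p): (jmap[a], hmap[p]) for a in ages for p in photos}


def build_criterion_matrix(
    table: CohortTable,
    mode: str = "mei_eq5",
    r_as_benefit: bool = False,
    use_pop_frac: bool = False,
) -> CriterionMatrix:
    """Score every present (treatment, cell, family) combination.

    Families with missing data are dropped per cell with a diagnostic.
    When ``use_pop_frac`` is False (the small/homogenous-sample
    convention) every P multiplier is 1; when True, each cell's pop_frac
    multiplies its scores and must be present.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    diags: list[Diagnostic] = []
    slots = _paper_indices(table)
    rows = []
    for cell in table.cells:
        if use_pop_frac:
            if cell.pop_frac is None:
                raise ValueError(f"cell {cell.key}: pop_frac required but absent")
            p = cell.pop_frac
        else:
            p = 1.0
        for code, fam in FAMILIES.items():
            score = cell_family_score(
                cell,
                fam,
                mode=mode,
                cost_ceiling=table.cost_ceiling,
                pop_frac=p,
                r_as_benefit=r_as_benefit,
            )
            if score is None:
                diags.append(
                    Diagnostic(
                        "warning",
                        f"cell {cell.key}: family {code} has no data; dropped",
                    )
                )
                continue
            slot = slots.get((cell.age_group, cell.phototype))
            k = criterion_index(fam, slot[0], slot[1]) if slot else None
            rows.append(
                {
                    "treatment_id": cell.treatment_id,
                    "age_group": cell.age_group,
                    "phototype": cell.phototype,
                    "family": code,
                    "k_index": k,
                    "score": score,
                }
            )
    if mode == "mei_eq5":
        if any(c.q_mean is not None for c in table.cells) or any(
            c.s_mean is not None for c in table.cells
        ):
            diags.append(
                Diagnostic(
                    "warning",
                    "mei_eq5 mode: no pre/post questionnaire marks in the "
                    "summary schema; Q and S scored as mark/10",
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "treatment_id",
            "age_group",
            "phototype",
            "family",
            "k_index",
            "score",
        ],
    )
    df["k_index"] = df["k_index"].astype("Int64")
    return CriterionMatrix(df, mode, table.cost_ceiling, tuple(diags))
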