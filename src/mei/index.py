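"""The medicoeconomic index (MEI) and its subgroup variants.

For one treatment arm the index is a weighted sum, over the arm's subgroup
cells, of the normalized criterion scores:

    MEI = Σ_cells [ t_E·E2/E1 + t_D·D2/D1 + t_L·(L ratio) + t_M·M2/M1
                    + t_H·H2/H1 + t_F·F2/F1 + t_Q·Q/10 + t_S·S/10
                    − t_R·R − t_C·C/K ]

in the *simplified* variant (appropriate for small or homogenous samples),
or with each cell's block multiplied by its population fraction P in the
*weighted* variant.  Restricting the sum to the cells of one age group, one
phototype, or a single (age group, phototype) cell yields the subgroup
indices used to rank responses across strata.

Larger is better: an inert, cost-free treatment under ratio-family weights
summing to w scores exactly w (every ratio is 1), and any post-mean
improvement in a positively weighted benefit family raises the index while
cost lowers it through −t_C·C/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import CohortTable, SubgroupCell, WeightScheme
from .criteria import FAMILIES, MODES, cell_family_score

__all__ = [
    "MEIReport",
    "mei_cell",
    "mei_treatment",
    "mei_by_age_group",
    "mei_by_phototype",
    "mei_by_cell",
    "rank_treatments",
]

VARIANTS = ("weighted", "simplified")


@dataclass(frozen=True)
class MEIReport:
    """Index values keyed by scope, with full provenance.

    ``values`` maps scope keys — "overall", "age_group:<label>",
    "phototype:<label>" or "cell:<age>|<phototype>" — to index values.
    ``cells_used`` records exactly which cell keys entered each sum.
    """

    treatment_id: str
    values: dict[str, float]
    variant: str
    mode: str
    weights: WeightScheme
    cost_ceiling: float
    cells_used: dict[str, tuple[tuple[str, str, str], ...]] = field(
        default_factory=dict
    )
    notes: tuple[str, ...] = ()


def _check_variant_mode(variant: str, mode: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def mei_cell(
    cell: SubgroupCell,
    weights: WeightScheme,
    cost_ceiling: float,
    mode: str = "mei_eq5",
    pop_frac: float = 1.0,
    r_as_benefit: bool = False,
) -> float:
    """One cell's contribution to the index (P = 1 unless given).

    Every family carrying positive weight must have data; zero-weight
    families with missing data contribute nothing and raise nothing.
    """
    _check_variant_mode("simplified", mode)
    total = 0.0
    for code, fam in FAMILIES.items():
        w = weights.weight(code)
        if w == 0.0:
            continue
        score = cell_family_score(
            cell,
            fam,
            mode=mode,
            cost_ceiling=cost_ceiling,
            pop_frac=pop_frac,
            r_as_benefit=r_as_benefit,
        )
        if score is None:
            raise ValueError(
                f"cell {cell.key}: family {code} carries weight {w} but has "
                "no data"
            )
        total += w * score
    return total


def _cell_pop(cell: SubgroupCell, variant: str) -> float:
    if variant == "simplified":
        return 1.0
    if cell.pop_frac is None:
        raise ValueError(
            f"cell {cell.key}: weighted variant requires pop_frac"
        )
    return cell.pop_frac


def mei_treatment(
    table: CohortTable,
    treatment: str,
    weights: WeightScheme,
    variant: str = "simplified",
    mode: str = "mei_eq5",
    r_as_benefit: bool = False,
) -> float:
    """Overall index of one treatment arm, summed over its present cells."""
    _check_variant_mode(variant, mode)
    cells = table.cells_for(treatment)
    if not cells:
        raise KeyError(f"unknown treatment {treatment!r}")
    return sum(
        mei_cell(
            c,
            weights,
            table.cost_ceiling,
            mode=mode,
            pop_frac=_cell_pop(c, variant),
            r_as_benefit=r_as_benefit,
        )
        for c in cells
    )


def _grouped_report(
    table: CohortTable,
    treatment: str,
    weights: WeightScheme,
    variant: str,
    mode: str,
    r_as_benefit: bool,
    group_attr: str,
    scope_prefix: str,
) -> MEIReport:
    _check_variant_mode(variant, mode)
    cells = table.cells_for(treatment)
    if not cells:
        raise KeyError(f"unknown treatment {treatment!r}")
    labels: list[str] = []
    for c in cells:
        lab = getattr(c, group_attr)
        if lab not in labels:
            labels.append(lab)
    values: dict[str, float] = {}
    used: dict[str, tuple[tuple[str, str, str], ...]] = {}
    notes: list[str] = []
    for lab in labels:
        members = [c for c in cells if getattr(c, group_attr) == lab]
        if not members:  # pragma: no cover - labels derive from cells
            notes.append(f"{scope_prefix}:{lab}: empty group omitted")
            continue
        key = f"{scope_prefix}:{lab}"
        values[key] = sum(
            mei_cell(
                c,
                weights,
                table.cost_ceiling,
                mode=mode,
                pop_frac=_cell_pop(c, variant),
                r_as_benefit=r_as_benefit,
            )
            for c in members
        )
        used[key] = tuple(c.key for c in members)
    return MEIReport(
        treatment_id=treatment,
        values=values,
        variant=variant,
        mode=mode,
        weights=weights,
        cost_ceiling=table.cost_ceiling,
        cells_used=used,
        notes=tuple(notes),
    )


def mei_by_age_group(
    table: CohortTable,
    treatment: str,
    weights: WeightScheme,
    variant: str = "simplified",
    mode: str = "mei_eq5",
    r_as_benefit: bool = False,
) -> MEIReport:
    """One index value per age-group label of the treatment's cells."""
    return _grouped_report(
        table, treatment, weights, variant, mode, r_as_benefit,
        "age_group", "age_group",
    )


def mei_by_phototype(
    table: CohortTable,
    treatment: str,
    weights: WeightScheme,
    variant: str = "simplified",
    mode: str = "mei_eq5",
    r_as_benefit: bool = False,
) -> MEIReport:
    """One index value per phototype label of the treatment's cells."""
    return _grouped_report(
        table, treatment, weights, variant, mode, r_as_benefit,
        "phototype", "phototype",
    )


def mei_by_cell(
    table: CohortTable,
    treatment: str,
    weights: WeightScheme,
    variant: str = "simplified",
    mode: str = "mei_eq5",
    r_as_benefit: bool = False,
) -> MEIReport:
    """One index value per (age group, phototype) cell."""
    _check_variant_mode(variant, mode)
    cells = table.cells_for(treatment)
    if not cells:
        raise KeyError(f"unknown treatment {treatment!r}")
    values: dict[str, float] = {}
    used: dict[str, tuple[tuple[str, str, str], ...]] = {}
    for c in cells:
        key = f"cell:{c.age_group}|{c.phototype}"
        values[key] = mei_cell(
            c,
            weights,
            table.cost_ceiling,
            mode=mode,
            pop_frac=_cell_pop(c, variant),
            r_as_benefit=r_as_benefit,
        )
        used[key] = (c.key,)
    return MEIReport(
        treatment_id=treatment,
        values=values,
        variant=variant,
        mode=mode,
        weights=weights,
        cost_ceiling=table.cost_ceiling,
        cells_used=used,
    )


def rank_treatments(
    table: CohortTable,
    weights: WeightScheme,
    variant: str = "simplified",
    mode: str = "mei_eq5",
    r_as_benefit: bool = False,
) -> list[tuple[str, float, bool]]:
    """All treatments ordered by descending index.

    Returns (treatment, MEI, tied) triples; ``tied`` marks a value shared
    with another treatment.  Requires at least two treatments.
    """
    tids = table.treatments
    if len(tids) < 2:
        raise ValueError(f"need at least 2 treatments to rank, got {len(tids)}")
    scored = [
        (
            t,
            mei_treatment(
                table, t, weights, variant=variant, mode=mode,
                r_as_benefit=r_as_benefit,
            ),
        )
        for t in tids
    ]
    scored.sort(key=lambda tv: (-tv[1], tv[0]))
    counts: dict[float, int] = {}
    for _, v in scored:
        counts[v] = counts.get(v, 0) + 1
    return [(t, v, counts[v] > 1) for t, v in scored]
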