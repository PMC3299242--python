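"""Domain types and delimited-text I/O for cohort summary tables.

The medicoeconomic index operates on *summary* data: one row per
(treatment, age group, phototype) subgroup cell, carrying pre/post means of
the high-frequency-ultrasound skin parameters (epidermis and dermis
thickness, low/medium/high-echogenity pixel counts, the LEPs/LEPi ratio),
the fraction of the cell with no adverse effects, the mean treatment cost,
mean questionnaire marks, and the cell's population fraction within its
treatment arm.  Patient-level records never enter the index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "SubgroupCell",
    "CohortTable",
    "WeightScheme",
    "Diagnostic",
    "SchemaError",
    "ValidationError",
    "read_cohort_table",
    "write_cohort_table",
    "read_weights",
    "validate_cohort",
]

#: absolute tolerance for all sum constraints (hand-entered decimal weights)
SUM_TOL = 1e-9


class SchemaError(ValueError):
    """A required column or key is missing or malformed."""


class ValidationError(ValueError):
    """A domain invariant is violated; the message names cell and field."""


# pre/post ratio families: (field stem, paper symbol)
RATIO_FAMILIES = [
    ("epidermis", "E"),
    ("dermis", "D"),
    ("lep", "L"),
    ("mep", "M"),
    ("hep", "H"),
    ("leps_lepi", "F"),
]

MANDATORY_COLUMNS = [
    "treatment_id",
    "age_group",
    "phototype",
    "epidermis_pre",
    "epidermis_post",
    "dermis_pre",
    "dermis_post",
    "leps_lepi_pre",
    "leps_lepi_post",
    "cost",
]

OPTIONAL_COLUMNS = [
    "lep_pre",
    "lep_post",
    "mep_pre",
    "mep_post",
    "hep_pre",
    "hep_post",
    "no_adverse_frac",
    "q_mean",
    "s_mean",
    "pop_frac",
]

# columns that may arrive percent-encoded under a *_pct alias
PCT_ALIASES = {"no_adverse_pct": "no_adverse_frac", "pop_pct": "pop_frac"}


@dataclass(frozen=True)
class SubgroupCell:
    """One (treatment, age-group, phototype) cell of summary means.

    Pre/post means must be strictly positive where present so that the
    post/pre (or pre/post) efficacy ratios are defined.  ``no_adverse_frac``
    and ``pop_frac`` are stored as fractions in [0, 1] regardless of whether
    the source file encoded them as percents.
    """

    treatment_id: str
    age_group: str
    phototype: str
    epidermis_pre: float
    epidermis_post: float
    dermis_pre: float
    dermis_post: float
    leps_lepi_pre: float
    leps_lepi_post: float
    cost: float
    lep_pre: float | None = None
    lep_post: float | None = None
    mep_pre: float | None = None
    mep_post: float | None = None
    hep_pre: float | None = None
    hep_post: float | None = None
    no_adverse_frac: float | None = None
    q_mean: float | None = None
    s_mean: float | None = None
    pop_frac: float | None = None

    def __post_init__(self) -> None:
        label = f"cell ({self.treatment_id}, {self.age_group}, {self.phototype})"
        for stem, _sym in RATIO_FAMILIES:
            for suffix in ("pre", "post"):
                v = getattr(self, f"{stem}_{suffix}")
                if v is not None and not v > 0:
                    raise ValidationError(
                        f"{label}: {stem}_{suffix} must be strictly positive, got {v}"
                    )
        if self.cost < 0:
            raise ValidationError(f"{label}: cost must be >= 0, got {self.cost}")
        for name, lo, hi in [
            ("no_adverse_frac", 0.0, 1.0),
            ("pop_frac", 0.0, 1.0),
            ("q_mean", 1.0, 10.0),
            ("s_mean", 1.0, 10.0),
        ]:
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValidationError(
                    f"{label}: {name} must lie in [{lo}, {hi}], got {v}"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.treatment_id, self.age_group, self.phototype)

    def has_family(self, symbol: str) -> bool:
        """Whether the data needed by criterion family *symbol* is present."""
        if symbol in {"E", "D", "L", "M", "H", "F"}:
            stem = {s: st for st, s in ((a, b) for a, b in RATIO_FAMILIES)}[symbol]
            return (
                getattr(self, f"{stem}_pre") is not None
                and getattr(self, f"{stem}_post") is not None
            )
        if symbol == "R":
            return self.no_adverse_frac is not None
        if symbol == "Q":
            return self.q_mean is not None
        if symbol == "S":
            return self.s_mean is not None
        if symbol == "C":
            return True
        raise KeyError(symbol)


@dataclass(frozen=True)
class CohortTable:
    """A collection of subgroup cells plus the cost ceiling K.

    (treatment, age_group, phototype) triples must be unique.  Within each
    treatment the population fractions, where present, may not sum above 1.
    A cell whose cost exceeds the ceiling only triggers a warning — the
    ceiling normalizes the cost criterion, it is not a hard budget.
    """

    cells: tuple[SubgroupCell, ...]
    cost_ceiling: float

    def __post_init__(self) -> None:
        if not self.cost_ceiling > 0:
            raise ValidationError(
                f"cost_ceiling must be > 0, got {self.cost_ceiling}"
            )
        object.__setattr__(self, "cells", tuple(self.cells))
        seen: set[tuple[str, str, str]] = set()
        for c in self.cells:
            if c.key in seen:
                raise ValidationError(f"duplicate cell key {c.key}")
            seen.add(c.key)
        for tid in self.treatments:
            fracs = [c.pop_frac for c in self.cells_for(tid) if c.pop_frac is not None]
            if fracs and sum(fracs) > 1 + SUM_TOL:
                raise ValidationError(
                    f"treatment {tid}: pop_frac sums to {sum(fracs)} > 1"
                )
        for c in self.cells:
            if c.cost > self.cost_ceiling:
                warnings.warn(
                    f"cell {c.key}: cost {c.cost} exceeds ceiling {self.cost_ceiling}",
                    stacklevel=2,
                )

    @property
    def treatments(self) -> list[str]:
        out: list[str] = []
        for c in self.cells:
            if c.treatment_id not in out:
                out.append(c.treatment_id)
        return out

    def cells_for(self, treatment_id: str) -> list[SubgroupCell]:
        return [c for c in self.cells if c.treatment_id == treatment_id]

    def merge(self, other: "CohortTable") -> "CohortTable":
        if not math.isclose(self.cost_ceiling, other.cost_ceiling):
            raise ValidationError("cannot merge tables with different cost ceilings")
        return CohortTable(self.cells + other.cells, self.cost_ceiling)


@dataclass(frozen=True)
class WeightScheme:
    """The ten nonnegative criterion-family weights t_E … t_C.

    The hierarchical decomposition requires the three purpose weights to sum
    to one: t_1 = t_E+t_D+t_L+t_M+t_H+t_F+t_R (medical), t_2 = t_Q+t_S
    (patient-reported), t_3 = t_C (economic), with t_1 + t_2 + t_3 = 1.
    """

    t_E: float = 0.0
    t_D: float = 0.0
    t_L: float = 0.0
    t_M: float = 0.0
    t_H: float = 0.0
    t_F: float = 0.0
    t_R: float = 0.0
    t_Q: float = 0.0
    t_S: float = 0.0
    t_C: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValidationError(f"weight {f.name} must be >= 0, got {v}")
        t1, t2, t3 = self.purpose_weights
        if abs(t1 + t2 + t3 - 1.0) > SUM_TOL:
            raise ValidationError(
                "weights must satisfy t_1 + t_2 + t_3 = 1; got "
                f"t_1={t1}, t_2={t2}, t_3={t3} (sum {t1 + t2 + t3})"
            )

    @property
    def purpose_weights(self) -> tuple[float, float, float]:
        t1 = self.t_E + self.t_D + self.t_L + self.t_M + self.t_H + self.t_F + self.t_R
        return (t1, self.t_Q + self.t_S, self.t_C)

    def weight(self, symbol: str) -> float:
        return getattr(self, f"t_{symbol}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.message}"


def _cell_from_row(row: pd.Series) -> SubgroupCell:
    kwargs: dict[str, object] = {}
    for col in MANDATORY_COLUMNS + OPTIONAL_COLUMNS:
        if col not in row.index:
            continue
        v = row[col]
        if pd.isna(v):
            continue
        if col in ("treatment_id", "age_group", "phototype"):
            kwargs[col] = str(v)
        else:
            kwargs[col] = float(v)
    return SubgroupCell(**kwargs)  # type: ignore[arg-type]


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve *_pct aliases into fractional columns (divide by 100)."""
    df = df.copy()
    for pct, frac in PCT_ALIASES.items():
        if pct in df.columns:
            if frac in df.columns:
                raise SchemaError(
                    f"both '{pct}' and '{frac}' present; supply exactly one"
                )
            df[frac] = df[pct] / 100.0
            df = df.drop(columns=[pct])
    return df


def cells_from_frame(df: pd.DataFrame) -> list[SubgroupCell]:
    """Build validated cells from a DataFrame with schema column names."""
    df = _normalize_columns(df)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return [_cell_from_row(row) for _, row in df.iterrows()]


def read_cohort_table(
    path: str | Path, ceiling: float, sep: str = ","
) -> CohortTable:
    """Read a delimiter-separated cohort summary table.

    Parameters
    ----------
    path
        UTF-8 text file, one row per (treatment, age_group, phototype) cell.
    ceiling
        The cost ceiling K used to normalize the cost criterion.
    sep
        Field delimiter, comma by default.
    """
    df = pd.read_csv(path, sep=sep)
    return CohortTable(tuple(cells_from_frame(df)), ceiling)


def table_to_frame(table: CohortTable) -> pd.DataFrame:
    rows = []
    for c in table.cells:
        row = {f.name: getattr(c, f.name) for f in fields(c)}
        rows.append(row)
    df = pd.DataFrame(rows)
    # drop entirely-absent optional columns for a clean export
    return df.dropna(axis=1, how="all")


def write_cohort_table(table: CohortTable, path: str | Path, sep: str = ",") -> None:
    """Export the table; exact inverse of :func:`read_cohort_table`."""
    table_to_frame(table).to_csv(path, sep=sep, index=False)


_WEIGHT_KEYS = [f"t_{s}" for s in "EDLMHFRQSC"]


def read_weights(path: str | Path) -> WeightScheme:
    """Read a key-value weights file; absent keys default to zero."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"weights file {path} is not a key-value mapping")
    unknown = set(raw) - set(_WEIGHT_KEYS) - {"cost_ceiling"}
    if unknown:
        raise SchemaError(f"unknown weight key(s): {', '.join(sorted(unknown))}")
    kwargs = {k: float(raw[k]) for k in _WEIGHT_KEYS if k in raw}
    return WeightScheme(**kwargs)


def read_config(path: str | Path) -> tuple[WeightScheme, float | None]:
    """Read weights plus an optional cost_ceiling from one file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    ceiling = raw.get("cost_ceiling")
    return read_weights(path), (float(ceiling) if ceiling is not None else None)


def validate_cohort(
    table: CohortTable | Iterable[SubgroupCell],
    cost_ceiling: float | None = None,
) -> list[Diagnostic]:
    """Collect diagnostics; the list is empty iff the table is fully valid.

    Hard invariant breaches (duplicate keys, pop_frac overrun) surface as
    ``error`` diagnostics, soft findings (cost above the ceiling,
    population fractions summing below one, optional criterion families
    missing) as ``warning``.  Accepts either a constructed
    :class:`CohortTable` (whose constructor already enforces the hard
    invariants) or a raw cell iterable plus ``cost_ceiling``.
    """
    out: list[Diagnostic] = []
    if not isinstance(table, CohortTable):
        cells = tuple(table)
        if cost_ceiling is None:
            raise TypeError("cost_ceiling is required when passing raw cells")
        seen: set[tuple[str, str, str]] = set()
        for c in cells:
            if c.key in seen:
                out.append(Diagnostic("error", f"duplicate cell key {c.key}"))
            seen.add(c.key)
        by_tid: dict[str, float] = {}
        for c in cells:
            if c.pop_frac is not None:
                by_tid[c.treatment_id] = by_tid.get(c.treatment_id, 0.0) + c.pop_frac
        for tid, s in by_tid.items():
            if s > 1 + SUM_TOL:
                out.append(
                    Diagnostic("error", f"treatment {tid}: pop_frac sums to {s} > 1")
                )
        if any(d.severity == "error" for d in out):
            return out
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = CohortTable(cells, cost_ceiling)
    for c in table.cells:
        if c.cost > table.cost_ceiling:
            out.append(
                Diagnostic(
                    "warning",
                    f"cell {c.key}: cost {c.cost} exceeds ceiling "
                    f"{table.cost_ceiling}",
                )
            )
    for tid in table.treatments:
        fracs = [c.pop_frac for c in table.cells_for(tid) if c.pop_frac is not None]
        if fracs and sum(fracs) < 1 - SUM_TOL:
            out.append(
                Diagnostic(
                    "warning",
                    f"treatment {tid}: pop_frac sums to {sum(fracs):g} < 1",
                )
            )
    for sym in ("L", "M", "H", "R", "Q", "S"):
        absent = [c.key for c in table.cells if not c.has_family(sym)]
        if absent and len(absent) == len(table.cells):
            out.append(
                Diagnostic("warning", f"family {sym}: data absent from all cells")
            )
        elif absent:
            out.append(
                Diagnostic(
                    "warning",
                    f"family {sym}: data absent from cells {absent}",
                )
            )
    return out
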