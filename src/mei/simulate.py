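"""Seeded patient-level cohort simulator.

Emulates a two-arm (or m-arm) skin antiaging study: per subgroup cell, each
patient's baseline skin parameters are drawn from log-normal distributions
moment-matched to a given mean and coefficient of variation (positivity is
required for the ratio criteria), post-treatment values are the baseline
times a multiplicative treatment-effect factor times multiplicative
measurement noise, questionnaire marks come from a discrete distribution on
1..10, and adverse events are Bernoulli.  Aggregating patients to cell
means yields a table in exactly the summary schema the index consumes, so
every downstream module can be exercised without external data.

Determinism contract: one root seed drives a per-arm, per-cell
``SeedSequence`` split, so identical specs and seeds reproduce the emitted
table bitwise and adding a cell never perturbs other cells' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, SubgroupCell, WeightScheme, cells_from_frame
from .index import rank_treatments

__all__ = [
    "CellSpec",
    "ArmSpec",
    "SimulationSpec",
    "simulate_cohort",
    "ranking_recovery_experiment",
]

#: parameter stems simulated per patient (pixel counts rounded to integers)
PARAMS = ("epidermis", "dermis", "lep", "mep", "hep", "leps_lepi")
INTEGER_PARAMS = frozenset({"lep", "mep", "hep"})

#: default within-cell coefficient of variation (no dispersions are
#: published for such cohorts; configurable per spec)
DEFAULT_CV = 0.15


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with the requested mean and CV (CV=0 → constant)."""
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


@dataclass(frozen=True)
class CellSpec:
    """Simulation parameters for one (age_group, phototype) cell of one arm."""

    age_group: str
    phototype: str
    n_patients: int
    baseline_means: dict[str, float]  # stem -> mean (subset of PARAMS)
    baseline_cv: float = DEFAULT_CV
    effect_factors: dict[str, float] = field(default_factory=dict)  # default 1.0
    noise_cv: float = DEFAULT_CV
    adverse_prob: float = 0.0
    q_probs: tuple[float, ...] | None = None  # distribution over marks 1..10
    s_probs: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(
                f"cell ({self.age_group}, {self.phototype}): n_patients must "
                f"be >= 1, got {self.n_patients}"
            )
        for stem, m in self.baseline_means.items():
            if stem not in PARAMS:
                raise ValueError(f"unknown parameter {stem!r}")
            if not m > 0:
                raise ValueError(f"baseline mean for {stem} must be > 0, got {m}")
        for stem, f in self.effect_factors.items():
            if stem not in PARAMS:
                raise ValueError(f"unknown parameter {stem!r}")
            if not f > 0:
                raise ValueError(f"effect factor for {stem} must be > 0, got {f}")
        if self.baseline_cv < 0 or self.noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if not 0 <= self.adverse_prob <= 1:
            raise ValueError(
                f"adverse_prob must be in [0,1], got {self.adverse_prob}"
            )
        for name, probs in (("q_probs", self.q_probs), ("s_probs", self.s_probs)):
            if probs is None:
                continue
            if len(probs) != 10 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be 10 nonnegative probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: its cells and per-patient cost."""

    treatment_id: str
    cells: tuple[CellSpec, ...]
    cost: float = 0.0

    def validate(self) -> None:
        if self.cost < 0:
            raise ValueError(f"arm {self.treatment_id}: cost must be >= 0")
        if not self.cells:
            raise ValueError(f"arm {self.treatment_id}: needs at least one cell")
        seen = set()
        for c in self.cells:
            key = (c.age_group, c.phototype)
            if key in seen:
                raise ValueError(f"arm {self.treatment_id}: duplicate cell {key}")
            seen.add(key)
            c.validate()


@dataclass(frozen=True)
class SimulationSpec:
    """Full study design: arms, cost ceiling and root seed."""

    arms: tuple[ArmSpec, ...]
    cost_ceiling: float
    seed: int = 0

    def validate(self) -> None:
        if not self.cost_ceiling > 0:
            raise ValueError("cost_ceiling must be > 0")
        if not self.arms:
            raise ValueError("at least one arm required")
        ids = [a.treatment_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate treatment_id across arms")
        for a in self.arms:
            a.validate()

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)


def _cell_rng(spec: SimulationSpec, arm_idx: int, cell_idx: int) -> np.random.Generator:
    # stable split: the (arm, cell) pair addresses its own stream
    ss = np.random.SeedSequence(spec.seed, spawn_key=(arm_idx, cell_idx))
    return np.random.default_rng(ss)


def _simulate_cell(
    rng: np.random.Generator, cell: CellSpec
) -> tuple[dict[str, float], pd.DataFrame]:
    n = cell.n_patients
    patients: dict[str, np.ndarray] = {}
    for stem in PARAMS:
        if stem not in cell.baseline_means:
            continue
        base = _lognormal(rng, cell.baseline_means[stem], cell.baseline_cv, n)
        factor = cell.effect_factors.get(stem, 1.0)
        noise = _lognormal(rng, 1.0, cell.noise_cv, n)
        post = base * factor * noise
        if stem in INTEGER_PARAMS:
            base = np.maximum(np.rint(base), 1.0)
            post = np.maximum(np.rint(post), 1.0)
        patients[f"{stem}_pre"] = base
        patients[f"{stem}_post"] = post
    summary: dict[str, float] = {
        k: float(np.mean(v)) for k, v in patients.items()
    }
    adverse = rng.random(n) < cell.adverse_prob
    patients["adverse_event"] = adverse.astype(int)
    summary["no_adverse_frac"] = float(1.0 - adverse.mean())
    marks = np.arange(1, 11)
    for name, probs in (("q_mean", cell.q_probs), ("s_mean", cell.s_probs)):
        if probs is None:
            continue
        draws = rng.choice(marks, size=n, p=np.asarray(probs))
        patients[name.replace("_mean", "_mark")] = draws
        summary[name] = float(np.clip(draws, 1, 10).mean())
    return summary, pd.DataFrame(patients)


def simulate_cohort(
    spec: SimulationSpec, return_patients: bool = False
) -> CohortTable | tuple[CohortTable, pd.DataFrame]:
    """Simulate the study and aggregate to a validated summary table.

    Population fractions are the realized per-cell patient shares within
    each arm, so they sum to one per treatment by construction.
    """
    spec.validate()
    rows: list[dict[str, object]] = []
    patient_frames: list[pd.DataFrame] = []
    for ai, arm in enumerate(spec.arms):
        total_n = sum(c.n_patients for c in arm.cells)
        for ci, cell in enumerate(arm.cells):
            rng = _cell_rng(spec, ai, ci)
            summary, patients = _simulate_cell(rng, cell)
            row: dict[str, object] = {
                "treatment_id": arm.treatment_id,
                "age_group": cell.age_group,
                "phototype": cell.phototype,
                "cost": arm.cost,
                "pop_frac": cell.n_patients / total_n,
            }
            row.update(summary)
            rows.append(row)
            if return_patients:
                patients.insert(0, "treatment_id", arm.treatment_id)
                patients.insert(1, "age_group", cell.age_group)
                patients.insert(2, "phototype", cell.phototype)
                patient_frames.append(patients)
    df = pd.DataFrame(rows)
    table = CohortTable(tuple(cells_from_frame(df)), spec.cost_ceiling)
    if return_patients:
        return table, pd.concat(patient_frames, ignore_index=True)
    return table


def ranking_recovery_experiment(
    spec_better: SimulationSpec,
    spec_worse: SimulationSpec,
    weights: WeightScheme,
    replicates: int,
    seed: int,
    mode: str = "mei_eq5",
) -> float:
    """Fraction of replicates in which the truly better arm ranks first.

    ``spec_better`` and ``spec_worse`` are single-arm designs that differ
    only by effect factors (the first at least as good on every positively
    weighted family, strictly on one, at equal cost).  Each replicate
    reseeds both arms from a common stream, merges the two simulated
    tables and ranks by the index; recovery should approach one as the
    per-cell sample size grows.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if len(spec_better.arms) != 1 or len(spec_worse.arms) != 1:
        raise ValueError("each spec must contain exactly one arm")
    better_id = spec_better.arms[0].treatment_id
    root = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in root.spawn(replicates):
        s1, s2 = rep_ss.generate_state(2) >> np.uint32(1)  # keep below 2**31
        t1 = simulate_cohort(spec_better.with_seed(int(s1)))
        t2 = simulate_cohort(spec_worse.with_seed(int(s2)))
        ranking = rank_treatments(t1.merge(t2), weights, mode=mode)
        if ranking[0][0] == better_id and not ranking[0][2]:
            hits += 1
    return hits / replicates
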