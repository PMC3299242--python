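import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mei.cohort import CohortTable, SubgroupCell, WeightScheme, cells_from_frame

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# §-style case-study weight scheme used throughout: medical ratio families
# 1/8 + 1/8 + 1/2, cost 1/4
STUDY_WEIGHTS = WeightScheme(t_E=0.125, t_D=0.125, t_F=0.5, t_C=0.25)


@pytest.fixture
def study_weights() -> WeightScheme:
    return STUDY_WEIGHTS


def make_cell(**overrides) -> SubgroupCell:
    base = dict(
        treatment_id="T1",
        age_group="40-49",
        phototype="2",
        epidermis_pre=0.117,
        epidermis_post=0.135,
        dermis_pre=1.537,
        dermis_post=1.719,
        leps_lepi_pre=1.149,
        leps_lepi_post=1.574,
        cost=250.0,
    )
    base.update(overrides)
    return SubgroupCell(**base)


@pytest.fixture
def p63_cell() -> SubgroupCell:
    """The aggregate treated-arm cell of the case study."""
    return make_cell(treatment_id="P63", age_group="40-75", phototype="II-III")


@pytest.fixture
def placebo_cell() -> SubgroupCell:
    return make_cell(
        treatment_id="placebo",
        age_group="40-75",
        phototype="II-III",
        epidermis_pre=0.1358,
        epidermis_post=0.13505,
        dermis_pre=1.49635,
        dermis_post=1.57155,
        leps_lepi_pre=0.924757,
        leps_lepi_post=1.042922,
        cost=100.0,
    )


@pytest.fixture
def two_arm_table(p63_cell, placebo_cell) -> CohortTable:
    return CohortTable((p63_cell, placebo_cell), cost_ceiling=400.0)


def random_full_cells(
    rng: np.random.Generator, n_treatments: int, complete_grid: bool = True
) -> list[SubgroupCell]:
    """Random cells with every criterion family present, full 3×2 grid."""
    cells = []
    for t in range(n_treatments):
        fracs = rng.dirichlet(np.ones(6))
        for idx, (age, photo) in enumerate(
            (a, p) for a in ("40-49", "50-59", "60-75") for p in ("2", "3")
        ):
            cells.append(
                SubgroupCell(
                    treatment_id=f"T{t + 1}",
                    age_group=age,
                    phototype=photo,
                    epidermis_pre=rng.uniform(0.08, 0.2),
                    epidermis_post=rng.uniform(0.08, 0.2),
                    dermis_pre=rng.uniform(1.0, 2.0),
                    dermis_post=rng.uniform(1.0, 2.0),
                    lep_pre=rng.uniform(50, 400),
                    lep_post=rng.uniform(50, 400),
                    mep_pre=rng.uniform(50, 400),
                    mep_post=rng.uniform(50, 400),
                    hep_pre=rng.uniform(50, 400),
                    hep_post=rng.uniform(50, 400),
                    leps_lepi_pre=rng.uniform(0.5, 2.0),
                    leps_lepi_post=rng.uniform(0.5, 2.0),
                    no_adverse_frac=rng.uniform(0, 1),
                    q_mean=rng.uniform(1, 10),
                    s_mean=rng.uniform(1, 10),
                    cost=rng.uniform(0, 400),
                    pop_frac=float(fracs[idx]),
                )
            )
    return cells


def frame_to_cells(df: pd.DataFrame):
    return cells_from_frame(df)
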