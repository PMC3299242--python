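"""Select among three treatments by weighted-sum scalarization.

Builds the criterion matrix for a three-arm table, maximizes the synthesis
function Λ over the one-hot assignments, and prints each arm's Λ together
with its Pareto (max-efficiency) status.  The chosen arm maximizes the
weighted composite; an arm can be Pareto-efficient yet not chosen when its
strengths sit on criteria with low weight.
"""

from mei import (
    AssignmentProblem,
    CohortTable,
    SubgroupCell,
    WeightScheme,
    build_criterion_matrix,
    select_treatment,
)


def cell(tid, e_post, cost):
    return SubgroupCell(
        treatment_id=tid,
        age_group="40-75",
        phototype="II-III",
        epidermis_pre=0.117,
        epidermis_post=e_post,
        dermis_pre=1.537,
        dermis_post=1.70,
        leps_lepi_pre=1.149,
        leps_lepi_post=1.50,
        cost=cost,
    )


table = CohortTable(
    (cell("A", 0.140, 300), cell("B", 0.130, 150), cell("C", 0.125, 350)),
    cost_ceiling=400,
)
weights = WeightScheme(t_E=0.25, t_D=0.125, t_F=0.375, t_C=0.25)
result = select_treatment(
    AssignmentProblem(build_criterion_matrix(table), weights)
)
for tid, value in result.values.items():
    status = "max-efficient" if tid in result.pareto else "dominated"
    print(f"{tid}: Lambda = {value:.6f} ({status})")
print(f"chosen: {result.chosen}  (tie: {result.tie})")
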