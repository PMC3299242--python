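# mei — a medicoeconomic index for multicriteria treatment evaluation

`mei` quantifies and compares the efficacy of skin antiaging treatments
from subgroup summary data. It is written for dermatology and
health-economics researchers who have, per treatment arm and per
(age group, phototype) stratum, the before/after means of high-frequency
ultrasound skin parameters — epidermis and dermis thickness, low/medium/
high-echogenity pixel counts (LEP/MEP/HEP), the LEPs/LEPi ratio — plus
adverse-effect rates, patient questionnaire marks, and treatment cost,
and who want a single defensible composite to rank treatments or strata.

## The index

Choosing one of *m* treatments is modelled as a 0/1 multicriteria
assignment problem: each criterion family *X* contributes, per subgroup
cell *(j, h)*, a normalized score — the post/pre ratio
*X₂/X₁* for benefit parameters, *Q/10* and *S/10* for the 1–10
questionnaire marks, *−R* for the no-adverse-effect fraction (sign as in
the source model; a `r_as_benefit` switch flips it), and *−C/K* for cost
normalized by a ceiling *K*. The weight method collapses the 60-criterion
objective into a synthesis function Λ(x) = Σₖ λₖ fₖ(x) with λ constant
within each family (t_E, t_D, t_L, t_M, t_H, t_F, t_R, t_Q, t_S, t_C ≥ 0,
hierarchical sums t₁+t₂+t₃ = 1). Any maximizer of Λ under positive
weights is a max-efficient (Pareto) point. Restricting Λ to one
treatment's coefficients gives the **medicoeconomic index**

    MEI(T) = Σ_cells [ t_E·E₂/E₁ + t_D·D₂/D₁ + t_L·(L ratio) + t_M·M₂/M₁
                       + t_H·H₂/H₁ + t_F·F₂/F₁ + t_Q·Q/10 + t_S·S/10
                       − t_R·R − t_C·C/K ]

in the *simplified* variant; the *weighted* variant multiplies each
cell's block by its population fraction P. Summing over one age group,
one phototype, or a single cell gives the subgroup indices. Classical
ICER (Δc/Δe) and incremental net benefit (INB = λ·Δe − Δc) are included
as two-treatment baselines.

## Worked example

The package ships the summary tables of a 30-patient, two-arm P63
antiaging complex study (phototypes II/III, ages 40–75; treatment cost
250 m.u., placebo 100 m.u., ceiling K = 400; weights
t_E = t_D = 1/8, t_F = 1/2, t_C = 1/4):

```python
>>> from mei import demo_paper
>>> print(demo_paper().format())
P63 antiaging case study — medicoeconomic index

Treatment ranking (simplified variant):
  P63        MEI = 0.812726
  placebo    MEI = 0.756981

Reproduction of published values:
  overall:P63          reported 0.812143  computed 0.812726  [DISCREPANT]
  overall:placebo      reported 0.569481  computed 0.756981  [DISCREPANT]
  age_group:40-49      reported 0.724915  computed 0.724915  [reproduced]
  age_group:50-59      reported 0.897944  computed 0.782455  [DISCREPANT]
  age_group:60-75      reported 0.745013  computed 0.745013  [reproduced]
  phototype:2          reported 0.782524  computed 0.782525  [reproduced]
  phototype:3          reported 0.848880  computed 0.848880  [reproduced]
```

The treated arm's index (0.812726) exceeds the placebo's (0.756981), so
the treatment is worth doing under this weighting; the best subgroup
responses are phototype 3 (0.848880) and — on recomputation — the 50–59
age group. Lines marked DISCREPANT are published values that the
published summary means do not support under any formula variant; the
demo reports the faithful recomputation instead of adjusting inputs.

Further narrative scripts live in `examples/` (index from CSV,
multi-treatment selection with a Pareto certificate, ICER/INB, cohort
simulation and ranking-recovery). A thin CLI mirrors the library:
`mei demo-paper`, `mei mei --table t.csv --weights w.yaml --by age`,
`mei compare`, `mei econ`, `mei simulate`, `mei validate`.

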