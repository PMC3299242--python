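# Weight scheme and scenario constants of the P63 antiaging case study:
# t_E = t_D = 1/8, t_F = 1/2, t_C = 1/4, all other families 0;
# treatment cost 250 m.u., placebo cost 100 m.u., ceiling K = 400 m.u.
t_E: 0.125
t_D: 0.125
t_F: 0.5
t_C: 0.25
cost_ceiling: 400
treatment_cost: 250
placebo_cost: 100
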