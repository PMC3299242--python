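"""Classical pharmacoeconomic baselines on an index difference.

Uses the case-study arm indices as the effect measure: Δe is the index
gap between the treated and placebo arms, Δc the cost gap.  The ICER is
the cost per unit of index gained; the incremental net benefit is positive
exactly when the willingness to pay per effect unit exceeds the ICER.
"""

from mei import (
    EconComparison,
    icer,
    incremental_net_benefit,
    load_study_tables,
    mei_treatment,
    study_weights,
)

weights, _k = study_weights()
table = load_study_tables()["overall"]
delta_e = mei_treatment(table, "P63", weights) - mei_treatment(
    table, "placebo", weights
)
delta_c = 250.0 - 100.0

print(f"effect difference (index units): {delta_e:.6f}")
print(f"ICER: {icer(delta_c, delta_e):.2f} m.u. per index unit")
for wtp in (1000.0, 5000.0):
    inb = incremental_net_benefit(EconComparison(delta_e, delta_c, wtp))
    verdict = "worth paying" if inb > 0 else "not worth paying"
    print(f"willingness to pay {wtp:.0f}: INB = {inb:.2f} m.u. ({verdict})")
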