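"""Classical pharmacoeconomic comparators: ICER and incremental net benefit.

Two-treatment baselines against which the multicriteria index is motivated.
The incremental cost-effectiveness ratio is Δcost/Δeffect; the incremental
net benefit is INB = λ·Δe − Δc with λ the willingness to pay per effect
unit.  Effect units are caller-defined — a QALY difference or a difference
of medicoeconomic index values both fit.  For Δe > 0 the two agree:
INB > 0 ⟺ λ > ICER.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EconComparison", "incremental_net_benefit", "icer"]


@dataclass(frozen=True)
class EconComparison:
    """Effect difference, cost difference and willingness to pay."""

    delta_e: float
    delta_c: float
    willingness_to_pay: float

    def __post_init__(self) -> None:
        if self.willingness_to_pay < 0:
            raise ValueError(
                f"willingness_to_pay must be >= 0, got {self.willingness_to_pay}"
            )


def incremental_net_benefit(comp: EconComparison) -> float:
    """INB = λ·Δe − Δc, in monetary units."""
    return comp.willingness_to_pay * comp.delta_e - comp.delta_c


def icer(delta_c: float, delta_e: float) -> float:
    """Δc/Δe, monetary units per effect unit.

    Undefined at Δe = 0 (dominance must be assessed instead of a ratio).
    """
    if delta_e == 0:
        raise ZeroDivisionError(
            "ICER undefined for zero effect difference; assess dominance instead"
        )
    return delta_c / delta_e
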