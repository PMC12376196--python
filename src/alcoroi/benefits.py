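"""Benefit estimation: monetizing harm reduction and converting it to QALYs.

Two routes produce the monetized benefits of an intervention:

* **direct** — an effectiveness estimate (proportional harm reduction) is
  combined with the current incidence of the harmful behavior and the
  per-person or per-event cost of alcohol-attributable harm, split into a
  resource component and an intangible (health) component;
* **transfer** — benefits already valued in a source jurisdiction (usually
  the United States) are multiplied by the ratio of costs per
  alcohol-attributable harm in the target jurisdiction.

Benefits estimated from demonstration-stage trials are reduced by 25%
because effectiveness generally attenuates when programs are scaled up.
Intangible savings divided by the value of a statistical life year (VSLY)
give the health gain in QALYs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .core import BenefitComponents, Money


class HarmBasis(str, enum.Enum):
    """Whether a harm unit cost applies per affected person or per event."""

    PER_PERSON = "per_person"
    PER_EVENT = "per_event"


class BasisMismatchError(ValueError):
    code = "basis_mismatch"


@dataclass(frozen=True)
class EffectivenessEstimate:
    """Proportional harm reduction and the incidence it applies to.

    ``target_incidence`` is events (or affected persons) per denominator
    unit per year, on the basis named by ``basis``.
    """

    relative_reduction: float
    target_incidence: float
    basis: HarmBasis = HarmBasis.PER_EVENT
    follow_up_years: float = 1.0
    demonstration_stage: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.relative_reduction <= 1:
            raise ValueError("relative_reduction must be in [0, 1]")
        if self.target_incidence < 0:
            raise ValueError("target_incidence must be non-negative")


@dataclass(frozen=True)
class HarmUnitCost:
    """Cost of one unit of alcohol-attributable harm, split by component."""

    resource_cost: Money
    intangible_cost: Money
    basis: HarmBasis = HarmBasis.PER_EVENT

    def __post_init__(self) -> None:
        if self.resource_cost < 0 or self.intangible_cost < 0:
            raise ValueError("harm unit cost components must be non-negative")


def direct_benefit(
    eff: EffectivenessEstimate,
    unit: HarmUnitCost,
    spillover_savings: Money = 0.0,
) -> BenefitComponents:
    """Benefits as reduction × incidence × harm unit cost, per component.

    ``spillover_savings`` (reduced drug use, smoking, violence) are passed
    through as a separate additive component.  Raises
    :class:`BasisMismatchError` if the effectiveness incidence and the unit
    cost are on different bases.
    """
    if eff.basis is not unit.basis:
        raise BasisMismatchError(
            f"basis_mismatch: incidence is {eff.basis.value}, unit cost is {unit.basis.value}"
        )
    events_averted = eff.relative_reduction * eff.target_incidence
    return BenefitComponents(
        resource_savings=events_averted * unit.resource_cost,
        intangible_savings=events_averted * unit.intangible_cost,
        spillover_savings=spillover_savings,
    )


def transfer_benefit(
    source_benefit: BenefitComponents, harm_cost_ratio: float
) -> BenefitComponents:
    """Transfer benefits to another jurisdiction by the harm-cost ratio.

    The ratio of costs per alcohol-attributable harm (per person or per
    event) between target and source jurisdiction absorbs differences in
    both incidence and cost per incident, plus currency conversion.
    """
    if harm_cost_ratio <= 0:
        raise ValueError("harm_cost_ratio must be positive")
    return source_benefit.scaled(harm_cost_ratio)


def apply_demonstration_discount(
    benefit: BenefitComponents, demonstration_stage: bool, discount: float = 0.25
) -> BenefitComponents:
    """Reduce benefits by ``discount`` when estimated at demonstration stage."""
    if not 0 <= discount < 1:
        raise ValueError("discount must be in [0, 1)")
    if not demonstration_stage:
        return benefit
    return benefit.scaled(1.0 - discount)


def discount_stream(values: Sequence[Money], rate: float) -> Money:
    """Present value of a yearly stream, year 0 undiscounted: Σ v_t/(1+r)^t."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return sum(v / (1.0 + rate) ** t for t, v in enumerate(values))


def qalys_from_intangible(intangible_savings: Money, vsly: Money) -> float:
    """QALYs gained: intangible (health) savings divided by the VSLY."""
    if vsly <= 0:
        raise ValueError("vsly must be positive")
    return intangible_savings / vsly


__all__ = [
    "HarmBasis",
    "BasisMismatchError",
    "EffectivenessEstimate",
    "HarmUnitCost",
    "direct_benefit",
    "transfer_benefit",
    "apply_demonstration_discount",
    "discount_stream",
    "qalys_from_intangible",
]
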