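"""Ingredients-based intervention costing.

Intervention costs follow the bottom-up ("ingredients") approach: total cost
is the product of the quantities of all resources consumed and their unit
prices.  Capital items lasting several years are annualized to an
equivalent annual cost; overhead and joint costs are excluded because
delivering one more intervention barely moves them.  Special rules cover
the environmental interventions: foregone alcohol consumption is costed at
half its purchase price (the supply-chain profit margin), volumetric tax
changes at administrative shift cost plus deadweight loss, and licensed
establishment liability as an upper-bound implementation cost.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import JurisdictionProfile, Money

logger = logging.getLogger(__name__)

#: Share of the purchase price of alcohol not consumed that is counted as a
#: societal cost — the profit across the supply chain from manufacture to
#: sale, which embodies the welfare loss of reduced consumption.
SUPPLY_CHAIN_PROFIT_SHARE = 0.5

#: Travel time is valued at 60% of the wage rate, delay time at 90%.
TRAVEL_TIME_WAGE_SHARE = 0.6
DELAY_TIME_WAGE_SHARE = 0.9


class CostKind(str, enum.Enum):
    """Which jurisdiction multiplier applies when converting a cost."""

    LABOR = "labor"
    NONLABOR = "nonlabor"
    ALCOHOL_PRICE = "alcohol_price"


class UnknownOccupationError(KeyError):
    code = "unknown_occupation"


class ZeroLifetimeError(ValueError):
    code = "zero_lifetime"


@dataclass(frozen=True)
class CostIngredient:
    """One quantity × unit-price line item.

    ``lifetime_years`` > 1 marks a capital item whose cost is spread as an
    equivalent annual cost; ``is_overhead`` marks joint costs excluded from
    intervention totals; ``labor_occupation`` tags labor items for
    wage-ratio conversion between jurisdictions.
    """

    label: str
    quantity: float
    unit_price: Money
    lifetime_years: float = 1.0
    is_overhead: bool = False
    labor_occupation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError("quantity must be non-negative")
        if self.unit_price < 0:
            raise ValueError("unit_price must be non-negative")
        if self.lifetime_years < 1:
            raise ValueError("lifetime_years must be >= 1")


@dataclass(frozen=True)
class TaxChangeSpec:
    """Cost components of moving to a volumetric alcohol taxation system.

    The societal cost is the one-off administrative cost of shifting the tax
    system plus the deadweight loss: consumer benefits lost from the
    consumption decrease minus the offsetting increase in tax revenue.  The
    total may be negative when the revenue gain exceeds the welfare loss.
    """

    admin_shift_cost: Money
    consumer_benefit_loss: Money
    tax_revenue_change: Money

    def __post_init__(self) -> None:
        if self.admin_shift_cost < 0:
            raise ValueError("admin_shift_cost must be non-negative")


@dataclass(frozen=True)
class LiabilitySpec:
    """Upper-bound costing of licensed-establishment liability for over-serving.

    Lawsuits mostly transfer incident costs between payers, so only the cost
    of passing and implementing the law counts — assumed at the upper end of
    the estimated range, 7.1% of expected annual lawsuit claims.  Expected
    claims are the annual claims value times the share of late-night
    drink-drivers whose last drink was at a licensed establishment (51%,
    Perth 2012) times the share of eligible victims who would actually sue
    (at most one half).  ``court_costs`` is an aggregate allowance for the
    modest court costs of those suits, default $0.
    """

    annual_claims_value: Money
    share_last_drink_licensed: float = 0.51
    share_who_sue: float = 0.50
    implementation_cost_fraction: float = 0.071
    court_costs: Money = 0.0

    def __post_init__(self) -> None:
        for name in (
            "share_last_drink_licensed",
            "share_who_sue",
            "implementation_cost_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def annualize(capital: Money, lifetime_years: float, rate: float) -> Money:
    """Equivalent annual cost of a capital outlay over its lifetime.

    Uses the annuity factor ``r / (1 - (1+r)^-n)`` so that discounting the
    annual cost back over the lifetime at the same rate recovers the
    capital exactly; at rate 0 this degenerates to straight-line
    ``capital / n``.
    """
    if lifetime_years <= 0:
        raise ZeroLifetimeError("zero_lifetime: lifetime_years must be positive")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return capital / lifetime_years
    factor = rate / (1.0 - (1.0 + rate) ** (-lifetime_years))
    return capital * factor


def ingredient_cost(ing: CostIngredient, rate: float = 0.03) -> Money:
    """Annual cost of one ingredient: quantity × unit price, annualized if capital."""
    base = ing.quantity * ing.unit_price
    if ing.lifetime_years > 1:
        return annualize(base, ing.lifetime_years, rate)
    return base


def total_intervention_cost(
    ingredients: Iterable[CostIngredient], rate: float = 0.03
) -> Money:
    """Sum of annual ingredient costs, excluding overhead/joint items.

    Excluded overheads are logged; an empty ingredient list yields $0 with
    a warning.
    """
    total = 0.0
    seen = False
    for ing in ingredients:
        seen = True
        if ing.is_overhead:
            logger.info("excluding overhead ingredient %r", ing.label)
            continue
        total += ingredient_cost(ing, rate)
    if not seen:
        logger.warning("total_intervention_cost called with no ingredients")
    return total


def value_time(
    travel_hours: float,
    delay_hours: float,
    wage: Money,
    travel_share: float = TRAVEL_TIME_WAGE_SHARE,
    delay_share: float = DELAY_TIME_WAGE_SHARE,
) -> Money:
    """Monetize travel and delay time at 60% / 90% of the wage rate."""
    if min(travel_hours, delay_hours, wage) < 0:
        raise ValueError("inputs must be non-negative")
    return travel_share * wage * travel_hours + delay_share * wage * delay_hours


def consumption_reduction_cost(
    drinks_reduced: float,
    pretax_price_per_drink: Money,
    profit_share: float = SUPPLY_CHAIN_PROFIT_SHARE,
) -> Money:
    """Societal cost of alcohol not consumed: half its purchase price.

    Applies to consumption-reducing environmental interventions
    (advertising bans, outlet density cuts, sales-hour limits, minimum
    pricing); ``profit_share`` is exposed for sensitivity analysis.
    """
    if drinks_reduced < 0:
        raise ValueError("drinks_reduced must be non-negative")
    return profit_share * drinks_reduced * pretax_price_per_drink


def tax_change_cost(spec: TaxChangeSpec) -> Money:
    """Cost of a volumetric tax change: admin shift cost plus deadweight loss."""
    deadweight_loss = spec.consumer_benefit_loss - spec.tax_revenue_change
    return spec.admin_shift_cost + deadweight_loss


def liability_cost(spec: LiabilitySpec) -> Money:
    """Upper-bound annual cost of establishment liability (see :class:`LiabilitySpec`)."""
    expected_claims = (
        spec.annual_claims_value
        * spec.share_last_drink_licensed
        * spec.share_who_sue
    )
    return spec.implementation_cost_fraction * expected_claims + spec.court_costs


def convert_cost(
    cost: Money,
    kind: CostKind | str,
    src: JurisdictionProfile,
    dst: JurisdictionProfile,
    occupation: Optional[str] = None,
) -> Money:
    """Convert a cost between jurisdictions by the matching index ratio.

    Labor costs use the ratio of national average salaries for
    ``occupation``; non-labor costs (interlocks, media buys) the
    purchasing-power-parity index; foregone-consumption costs the pre-tax
    drink price ratio.
    """
    kind = CostKind(kind)
    if kind is CostKind.LABOR:
        if occupation is None:
            raise UnknownOccupationError("unknown_occupation: occupation required for labor costs")
        try:
            ratio = dst.occupation_wage_index[occupation] / src.occupation_wage_index[occupation]
        except KeyError as exc:
            raise UnknownOccupationError(f"unknown_occupation: {exc.args[0]!r}") from None
    elif kind is CostKind.NONLABOR:
        ratio = dst.ppp_index / src.ppp_index
    else:
        ratio = dst.pretax_drink_price / src.pretax_drink_price
    return cost * ratio


__all__ = [
    "SUPPLY_CHAIN_PROFIT_SHARE",
    "TRAVEL_TIME_WAGE_SHARE",
    "DELAY_TIME_WAGE_SHARE",
    "CostKind",
    "CostIngredient",
    "TaxChangeSpec",
    "LiabilitySpec",
    "UnknownOccupationError",
    "ZeroLifetimeError",
    "annualize",
    "ingredient_cost",
    "total_intervention_cost",
    "value_time",
    "consumption_reduction_cost",
    "tax_change_cost",
    "liability_cost",
    "convert_cost",
]
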