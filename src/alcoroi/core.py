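"""Domain types shared by every stage of the evaluation pipeline.

All monetary amounts are Australian dollars in a single (unstated) reference
year; the package carries the currency tag as metadata and performs no
inflation adjustment.  Intervention effects are expressed *per denominator
unit* — per driver, per student, per million population, per 10,000 drinks —
and :func:`rescale_denominator` converts between those bases linearly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: Currency tag attached to every monetary quantity in the package.
CURRENCY = "AUD"

Money = float
"""Monetary amount in :data:`CURRENCY` (reference-year dollars)."""


class Category(str, enum.Enum):
    """Broad intervention categories used for league-table grouping."""

    AVAILABILITY = "availability"
    MARKETING = "marketing"
    PRICING = "pricing"
    DRINK_DRIVING = "drink_driving"
    WORKPLACE = "workplace"
    HEALTH_SECTOR = "health_sector"
    YOUTH_DEVELOPMENT = "youth_development"
    SCHOOL_BASED = "school_based"


class QualityRating(str, enum.Enum):
    """Evidence-quality grade of the underlying effectiveness study.

    ``A`` marks randomized controlled trials without serious attrition, or
    large-scale implementations evaluated with a credible comparison design;
    grades decline with the strength of the design.
    """

    A = "A"
    B = "B"
    C = "C"


class AdjustmentFlag(str, enum.Enum):
    """Standardization adjustments applied to the source study's estimates."""

    UNIFORM_BENEFITS = "uniform_benefits"
    OTHER_MODIFICATIONS = "other_modifications"
    COSTS_COMPUTED = "costs_computed"
    DEMONSTRATION_DISCOUNT = "demonstration_discount"


class Denominator(str, enum.Enum):
    """Unit basis of per-unit costs and savings, with an attached scale.

    ``scale`` is the number of natural units (persons, drinks, drivers)
    represented by one denominator unit, so a per-``PER_1E6_POPULATION``
    dollar amount divided by ``1e6`` is a per-person amount.
    """

    DRIVER = "driver"
    YOUTH = "youth"
    ADULT = "adult"
    DRINKER_YEAR = "drinker_year"
    LICENSE_REVOKED = "license_revoked"
    VEHICLE_EQUIPPED = "vehicle_equipped"
    IMPOUNDMENT = "impoundment"
    HOUSE_ARREST = "house_arrest"
    PROBATION = "probation"
    CLIENT = "client"
    PARTICIPATING_WORKER = "participating_worker"
    PERSON_TREATED = "person_treated"
    STUDENT = "student"
    PER_1E4_DRINKS = "per_1e4_drinks"
    PER_1E3_POPULATION = "per_1e3_population"
    PER_1E4_DRIVERS = "per_1e4_drivers"
    PER_1E6_POPULATION = "per_1e6_population"

    @property
    def scale(self) -> float:
        return _DENOMINATOR_SCALE[self]


_DENOMINATOR_SCALE: dict[Denominator, float] = {
    Denominator.PER_1E4_DRINKS: 1e4,
    Denominator.PER_1E3_POPULATION: 1e3,
    Denominator.PER_1E4_DRIVERS: 1e4,
    Denominator.PER_1E6_POPULATION: 1e6,
}
for _d in Denominator:
    _DENOMINATOR_SCALE.setdefault(_d, 1.0)


class UnknownUnitError(ValueError):
    """Raised when a denominator string does not name a known unit basis."""

    code = "unknown_unit"


class RecordValidationError(ValueError):
    """Raised by :func:`validate_record`; ``violations`` lists the breaches."""

    def __init__(self, record_id: str, violations: list[str]):
        self.record_id = record_id
        self.violations = violations
        super().__init__(f"record {record_id!r} violates: {', '.join(violations)}")


@dataclass(frozen=True)
class InterventionRecord:
    """One intervention with its per-unit cost and per-unit savings.

    ``resource_savings_per_unit`` is the reduction in resource costs
    (medical, property, productivity); ``intangible_savings_per_unit`` is
    the monetized value of the health improvement (pain, suffering, lost
    quality of life), later converted to QALYs via the value of a
    statistical life year.
    """

    id: str
    name: str
    category: Category
    cost_per_unit: Money
    denominator: Denominator
    resource_savings_per_unit: Money
    intangible_savings_per_unit: Money
    quality_rating: QualityRating
    demonstration_stage: bool = False
    adjustment_flags: frozenset[AdjustmentFlag] = field(default_factory=frozenset)

    @property
    def total_savings_per_unit(self) -> Money:
        return self.resource_savings_per_unit + self.intangible_savings_per_unit


@dataclass(frozen=True)
class BenefitComponents:
    """Monetized benefits of an intervention, split by component.

    ``spillover_savings`` holds benefits from reductions in drug use,
    smoking or violence, which are added only when the intervention was
    effective against alcohol-attributable harm itself.
    """

    resource_savings: Money
    intangible_savings: Money
    spillover_savings: Money = 0.0

    def __post_init__(self) -> None:
        for name in ("resource_savings", "intangible_savings", "spillover_savings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> Money:
        return self.resource_savings + self.intangible_savings + self.spillover_savings

    def scaled(self, factor: float) -> "BenefitComponents":
        return BenefitComponents(
            self.resource_savings * factor,
            self.intangible_savings * factor,
            self.spillover_savings * factor,
        )


@dataclass(frozen=True)
class JurisdictionProfile:
    """Multipliers for converting costs and benefits between jurisdictions.

    ``occupation_wage_index`` maps occupation keys (teacher, police_officer,
    physician, ...) to annual salaries; labor-intensive costs move between
    jurisdictions by the salary ratio, non-labor costs by purchasing-power
    parity, and foregone-consumption costs by the pre-tax drink price ratio.
    ``harm_cost_per_person`` / ``harm_cost_per_event`` support benefit
    transfer by the ratio of costs per alcohol-attributable harm.
    """

    name: str
    occupation_wage_index: dict[str, Money] = field(default_factory=dict)
    ppp_index: float = 1.0
    pretax_drink_price: Money = 1.0
    harm_cost_per_person: Money = 1.0
    harm_cost_per_event: Money = 1.0

    def __post_init__(self) -> None:
        for key, value in {
            "ppp_index": self.ppp_index,
            "pretax_drink_price": self.pretax_drink_price,
            "harm_cost_per_person": self.harm_cost_per_person,
            "harm_cost_per_event": self.harm_cost_per_event,
        }.items():
            if value <= 0:
                raise ValueError(f"{key} must be positive")
        for occ, wage in self.occupation_wage_index.items():
            if wage <= 0:
                raise ValueError(f"wage index for {occ!r} must be positive")


@dataclass(frozen=True)
class EconomicConfig:
    """Evaluation-wide economic parameters.

    ``vsly`` (value of a statistical life year, dollars per QALY) has no
    package default: it is either supplied explicitly or calibrated from a
    fixture table (see :func:`alcoroi.evaluation.calibrate_vsly`).
    """

    discount_rate: float = 0.03
    vsly: Optional[Money] = None
    wtp_threshold: Money = 50_000.0
    demonstration_discount: float = 0.25
    price_year: Optional[int] = None  # metadata only; no inflation adjustment

    def __post_init__(self) -> None:
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount_rate must be in [0, 1)")
        if self.vsly is not None and self.vsly <= 0:
            raise ValueError("vsly must be positive")
        if not 0 <= self.demonstration_discount < 1:
            raise ValueError("demonstration_discount must be in [0, 1)")


def record_violations(record: InterventionRecord) -> list[str]:
    """Return named invariant violations for ``record`` (empty if valid).

    Violation codes:

    ``negative_savings``
        a savings component is negative;
    ``negative_cost_category``
        a negative per-unit cost on a category other than pricing — only
        tax-change interventions may carry a negative (revenue-dominated)
        cost.
    """
    violations: list[str] = []
    if record.resource_savings_per_unit < 0 or record.intangible_savings_per_unit < 0:
        violations.append("negative_savings")
    if record.cost_per_unit < 0 and record.category is not Category.PRICING:
        violations.append("negative_cost_category")
    return violations


def validate_record(record: InterventionRecord) -> InterventionRecord:
    """Return ``record`` unchanged if valid, else raise :class:`RecordValidationError`."""
    violations = record_violations(record)
    if violations:
        raise RecordValidationError(record.id, violations)
    return record


def rescale_denominator(
    value: Money,
    denominator: Denominator | str,
    target_scale: float = 1.0,
) -> Money:
    """Rescale a per-denominator dollar amount onto a different per-capita basis.

    ``target_scale`` is the number of natural units in the target basis
    (1 = per person/drink/driver, 1e3 = per thousand, ...).  E.g. $16,036
    per million population → $0.016036 per person.

    Raises :class:`UnknownUnitError` for an unrecognized denominator.
    """
    if not isinstance(denominator, Denominator):
        try:
            denominator = Denominator(denominator)
        except ValueError:
            raise UnknownUnitError(f"unknown_unit: {denominator!r}") from None
    if target_scale <= 0:
        raise ValueError("target_scale must be positive")
    return value * (target_scale / denominator.scale)


__all__ = [
    "CURRENCY",
    "Money",
    "Category",
    "QualityRating",
    "AdjustmentFlag",
    "Denominator",
    "UnknownUnitError",
    "RecordValidationError",
    "InterventionRecord",
    "BenefitComponents",
    "JurisdictionProfile",
    "EconomicConfig",
    "record_violations",
    "validate_record",
    "rescale_denominator",
]
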