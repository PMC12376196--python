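"""Synthetic intervention portfolios with known ground-truth BCR/ICER.

The generator emulates the statistical structure of the evaluation inputs:
ingredient-level costs (log-normal unit prices, occasional capital items
and overheads), effectiveness estimates, per-event harm unit costs split
into resource and intangible components (the intangible share defaults to
0.8, matching the roughly 80–85% intangible share of the printed rows),
and a demonstration-stage flag that attenuates benefits by 25%.

Ground truth is computed here from the closed-form definitions,
**deliberately duplicating rather than importing** the pipeline code, so it
serves as an independent oracle for parameter-recovery tests: running the
full pipeline on the emitted CSVs must reproduce the truth table exactly
(pre-rounding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_OCCUPATIONS = ["teacher", "police_officer", "physician", "bartender", "all_employees"]
_CATEGORIES = [
    "availability", "marketing", "pricing", "drink_driving",
    "workplace", "health_sector", "youth_development", "school_based",
]
_PERSON_DENOMINATORS = ["driver", "adult", "client", "person_treated", "student"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic portfolio generator.

    ``unit_price_median`` / ``unit_price_dispersion`` parameterize the
    log-normal ingredient price distribution (dispersion is the sigma of
    log price); ``intangible_share`` is the mean share of total harm cost
    that is intangible; ``harm_cost_median`` scales per-event harm costs so
    that typical BCRs land in the printed tables' range.
    """

    n_interventions: int = 20
    seed: int = 0
    ingredient_count_range: tuple[int, int] = (2, 6)
    unit_price_median: float = 40.0
    unit_price_dispersion: float = 0.8
    effectiveness_range: tuple[float, float] = (0.02, 0.30)
    incidence_mean: float = 25.0
    harm_cost_median: float = 2_000.0
    harm_cost_dispersion: float = 0.6
    intangible_share: float = 0.8
    intangible_share_concentration: float = 150.0
    demonstration_probability: float = 0.25
    demonstration_discount: float = 0.25
    capital_probability: float = 0.2
    overhead_probability: float = 0.15
    discount_rate: float = 0.03
    vsly: float = 182_000.0
    wtp_threshold: float = 50_000.0

    def __post_init__(self) -> None:
        lo, hi = self.ingredient_count_range
        if not (1 <= lo <= hi):
            raise ValueError("ingredient_count_range must be well-ordered and >= 1")
        e0, e1 = self.effectiveness_range
        if not (0 <= e0 <= e1 <= 1):
            raise ValueError("effectiveness_range must be within [0, 1]")
        if not 0 <= self.intangible_share <= 1:
            raise ValueError("intangible_share must be in [0, 1]")
        if self.vsly <= 0:
            raise ValueError("vsly must be positive")


@dataclass
class PortfolioBundle:
    """Generated portfolio: pipeline inputs plus the ground-truth table."""

    interventions: pd.DataFrame
    ingredients: pd.DataFrame
    harm_costs: pd.DataFrame
    effectiveness: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.interventions.to_csv(out / "interventions.csv", index=False)
        self.ingredients.to_csv(out / "ingredients.csv", index=False)
        self.harm_costs.to_csv(out / "harm_costs.csv", index=False)
        self.effectiveness.to_csv(out / "effectiveness.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _oracle_annuity_cost(quantity, price, lifetime, rate):
    # independent restatement of equivalent-annual-cost; do not import costing
    base = quantity * price
    if lifetime <= 1:
        return base
    if rate == 0:
        return base / lifetime
    return base * rate / (1.0 - (1.0 + rate) ** (-lifetime))


def generate_portfolio(cfg: GeneratorConfig) -> PortfolioBundle:
    """Draw a portfolio; same config (incl. seed) gives bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_interventions == 0:
        logger.warning("generate_portfolio called with n_interventions=0")
    interventions, ingredients, harm_costs, effectiveness, truth = [], [], [], [], []

    for i in range(cfg.n_interventions):
        iid = f"syn_{i:04d}"
        n_ing = int(rng.integers(cfg.ingredient_count_range[0],
                                 cfg.ingredient_count_range[1] + 1))
        cost = 0.0
        for j in range(n_ing):
            quantity = float(rng.integers(1, 20))
            price = float(cfg.unit_price_median * np.exp(
                cfg.unit_price_dispersion * rng.standard_normal()))
            lifetime = 1.0
            if rng.random() < cfg.capital_probability:
                lifetime = float(rng.integers(2, 11))
            overhead = bool(rng.random() < cfg.overhead_probability)
            occupation = (
                str(rng.choice(_OCCUPATIONS)) if rng.random() < 0.5 else ""
            )
            ingredients.append({
                "intervention_id": iid,
                "label": f"{iid}_item{j}",
                "quantity": quantity,
                "unit_price": price,
                "lifetime_years": lifetime,
                "is_overhead": overhead,
                "labor_occupation": occupation,
            })
            if not overhead:
                cost += _oracle_annuity_cost(quantity, price, lifetime, cfg.discount_rate)

        reduction = float(rng.uniform(*cfg.effectiveness_range))
        incidence = float(rng.poisson(cfg.incidence_mean))
        total_harm = float(cfg.harm_cost_median * np.exp(
            cfg.harm_cost_dispersion * rng.standard_normal()))
        if cfg.intangible_share in (0.0, 1.0):
            share = cfg.intangible_share
        else:
            kappa = cfg.intangible_share_concentration
            share = float(rng.beta(kappa * cfg.intangible_share,
                                   kappa * (1.0 - cfg.intangible_share)))
        resource_unit = (1.0 - share) * total_harm
        intangible_unit = share * total_harm
        demo = bool(rng.random() < cfg.demonstration_probability)

        scale = (1.0 - cfg.demonstration_discount) if demo else 1.0
        resource_savings = reduction * incidence * resource_unit * scale
        intangible_savings = reduction * incidence * intangible_unit * scale
        total_savings = resource_savings + intangible_savings

        # --- independent closed-form ground truth -------------------------
        if cost > 0:
            truth_bcr: object = total_savings / cost
        else:
            truth_bcr = "NO_COST"
        qalys = intangible_savings / cfg.vsly
        if cost <= 0:
            truth_icer: object = ""
            truth_class = "no_cost_dominant"
        elif resource_savings >= cost:
            truth_icer = "NET_SAVING"
            truth_class = "cost_saving"
        elif qalys <= 0:
            truth_icer = "no_health_gain"
            truth_class = "not_cost_effective"
        else:
            truth_icer = (cost - resource_savings) / qalys
            truth_class = (
                "cost_effective"
                if truth_icer <= cfg.wtp_threshold
                else "not_cost_effective"
            )

        interventions.append({
            "id": iid,
            "name": f"Synthetic intervention {i}",
            "category": str(rng.choice(_CATEGORIES)),
            "cost_per_unit": cost,
            "denominator": str(rng.choice(_PERSON_DENOMINATORS)),
            "resource_savings": resource_savings,
            "intangible_savings": intangible_savings,
            "quality_rating": str(rng.choice(["A", "B", "C"])),
            "demonstration_stage": demo,
            "flags": "demonstration_discount" if demo else "",
        })
        harm_costs.append({
            "harm_type": f"harm_{iid}",
            "basis": "per_event",
            "resource_cost": resource_unit,
            "intangible_cost": intangible_unit,
        })
        effectiveness.append({
            "id": iid,
            "relative_reduction": reduction,
            "target_incidence": incidence,
            "basis": "per_event",
            "demonstration_stage": demo,
        })
        truth.append({
            "id": iid,
            "cost": cost,
            "resource_savings": resource_savings,
            "intangible_savings": intangible_savings,
            "total_savings": total_savings,
            "bcr": truth_bcr,
            "qalys": qalys,
            "icer": truth_icer,
            "classification": truth_class,
        })

    cols = dict(
        interventions=["id", "name", "category", "cost_per_unit", "denominator",
                       "resource_savings", "intangible_savings", "quality_rating",
                       "demonstration_stage", "flags"],
        ingredients=["intervention_id", "label", "quantity", "unit_price",
                     "lifetime_years", "is_overhead", "labor_occupation"],
        harm_costs=["harm_type", "basis", "resource_cost", "intangible_cost"],
        effectiveness=["id", "relative_reduction", "target_incidence", "basis",
                       "demonstration_stage"],
        truth=["id", "cost", "resource_savings", "intangible_savings",
               "total_savings", "bcr", "qalys", "icer", "classification"],
    )
    return PortfolioBundle(
        interventions=pd.DataFrame(interventions, columns=cols["interventions"]),
        ingredients=pd.DataFrame(ingredients, columns=cols["ingredients"]),
        harm_costs=pd.DataFrame(harm_costs, columns=cols["harm_costs"]),
        effectiveness=pd.DataFrame(effectiveness, columns=cols["effectiveness"]),
        truth=pd.DataFrame(truth, columns=cols["truth"]),
        config=cfg,
    )


def _round_to_unit(values: pd.Series, unit: float) -> pd.Series:
    return (values / unit).round() * unit


def perturb_rounding(bundle: PortfolioBundle, dollars: float) -> PortfolioBundle:
    """Round monetary components to ``dollars`` units, printed-table style.

    Only the interventions table is rounded; the truth table keeps full
    precision, so downstream comparisons measure pure rounding error.
    ``dollars = 0`` is the identity.
    """
    if dollars < 0:
        raise ValueError("rounding unit must be non-negative")
    if dollars == 0:
        return bundle
    interventions = bundle.interventions.copy()
    for col in ("cost_per_unit", "resource_savings", "intangible_savings"):
        interventions[col] = _round_to_unit(interventions[col], dollars)
    return replace(bundle, interventions=interventions)


def bcr_rounding_bound(total_savings: float, cost: float, dollars: float) -> float:
    """Worst-case BCR shift from rounding both components and the cost.

    Each savings component moves by at most half the rounding unit (so the
    numerator by at most one unit) and the cost by at most half a unit; the
    bound is the exact worst case over those intervals, infinite when the
    cost can cross zero.
    """
    h = dollars / 2.0
    if cost - h <= 0:
        return float("inf")
    return (total_savings + 2 * h) / (cost - h) - total_savings / cost


__all__ = [
    "GeneratorConfig",
    "PortfolioBundle",
    "generate_portfolio",
    "perturb_rounding",
    "bcr_rounding_bound",
]
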