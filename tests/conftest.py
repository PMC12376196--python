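import pytest
from hypothesis import HealthCheck, settings

from alcoroi.io import fixture_records, load_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def recompute_bundle(bundle):
    """Run the real pipeline over a synthetic bundle's ingredient/effect CSVs.

    Returns a list of (id, EvaluationResult) computed from first principles:
    ingredients -> total cost, effectiveness x harm unit cost -> benefits,
    demonstration discount, then BCR/ICER evaluation.  Deliberately uses
    only public pipeline functions so it exercises the same code path as a
    user run, independent of the generator's internal closed forms.
    """
    from alcoroi.benefits import (
        EffectivenessEstimate,
        HarmBasis,
        HarmUnitCost,
        apply_demonstration_discount,
        direct_benefit,
    )
    from alcoroi.costing import CostIngredient, total_intervention_cost
    from alcoroi.evaluation import evaluate_components

    cfg = bundle.config
    harm = bundle.harm_costs.set_index("harm_type")
    eff = bundle.effectiveness.set_index("id")
    ingredients = {
        iid: [
            CostIngredient(
                label=row.label,
                quantity=row.quantity,
                unit_price=row.unit_price,
                lifetime_years=row.lifetime_years,
                is_overhead=bool(row.is_overhead),
                labor_occupation=row.labor_occupation or None,
            )
            for row in grp.itertuples()
        ]
        for iid, grp in bundle.ingredients.groupby("intervention_id", sort=False)
    }
    out = []
    for iid in bundle.interventions["id"]:
        cost = total_intervention_cost(ingredients[iid], rate=cfg.discount_rate)
        e = eff.loc[iid]
        h = harm.loc[f"harm_{iid}"]
        benefit = direct_benefit(
            EffectivenessEstimate(
                relative_reduction=float(e["relative_reduction"]),
                target_incidence=float(e["target_incidence"]),
                basis=HarmBasis(e["basis"]),
                demonstration_stage=bool(e["demonstration_stage"]),
            ),
            HarmUnitCost(
                resource_cost=float(h["resource_cost"]),
                intangible_cost=float(h["intangible_cost"]),
                basis=HarmBasis(h["basis"]),
            ),
        )
        benefit = apply_demonstration_discount(
            benefit, bool(e["demonstration_stage"]), cfg.demonstration_discount
        )
        result = evaluate_components(
            cost,
            benefit.resource_savings,
            benefit.intangible_savings,
            vsly=cfg.vsly,
            threshold=cfg.wtp_threshold,
        )
        out.append((iid, cost, benefit, result))
    return out


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4_rows")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5_rows")


@pytest.fixture(scope="session")
def table4_records():
    return fixture_records("table4_rows")


@pytest.fixture(scope="session")
def table5_records():
    return fixture_records("table5_rows")
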