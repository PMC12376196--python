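"""Return-on-investment metrics, classification and league tables.

Two ratios summarize each intervention:

* **BCR** — total monetized benefits (resource savings + intangible health
  savings) divided by intervention cost.  Interventions with non-positive
  cost get the ``NO_COST`` sentinel instead of a ratio.
* **ICER** — net cost (intervention cost minus resource savings) per QALY
  gained, where QALYs are intangible savings divided by the value of a
  statistical life year (VSLY).  When resource savings alone cover the
  cost the intervention is dominant and gets the ``NET_SAVING`` sentinel.

Against a willingness-to-pay threshold (A$50,000/QALY by default) each
intervention classifies as cost-saving, cost-effective, not cost-effective,
or dominant-at-no-cost.  Because the source tables print per-unit dollar
components but not the VSLY used, :func:`implied_vsly` inverts the ICER
formula row by row and :func:`calibrate_vsly` summarizes the implied
constant per table; :func:`consistency_report` then checks every printed
row against its own components.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .benefits import qalys_from_intangible
from .core import EconomicConfig, InterventionRecord, Money

#: Recomputed-vs-printed BCR deviations beyond this are flagged as rounding
#: casualties (small printed denominators) rather than accepted agreement.
BCR_FLAG_TOLERANCE = 0.15

#: Rows whose printed net cost is below this are too rounding-sensitive for
#: a meaningful implied-VSLY reading.
VSLY_MIN_NET_COST = 50.0


class Sentinel(enum.Enum):
    """Non-numeric cells of the ratio columns."""

    NO_COST = "NO_COST"  # intervention cost <= 0: BCR undefined, dominant
    NET_SAVING = "NET_SAVING"  # resource savings >= cost: ICER undefined, dominant

    def __str__(self) -> str:  # CSV round-trip token
        return self.value


NO_COST = Sentinel.NO_COST
NET_SAVING = Sentinel.NET_SAVING

BcrValue = Union[float, Sentinel]
IcerValue = Union[float, Sentinel, None]


class Classification(str, enum.Enum):
    COST_SAVING = "cost_saving"
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    NO_COST_DOMINANT = "no_cost_dominant"


class NoHealthGainError(ValueError):
    code = "no_health_gain"


class NetSavingRowError(ValueError):
    code = "net_saving_row"


@dataclass(frozen=True)
class EvaluationResult:
    """Computed ratios and classification for one intervention.

    ``icer`` is ``NET_SAVING`` exactly when resource savings cover a
    positive cost; for non-positive cost the BCR sentinel ``NO_COST``
    takes precedence and ``icer`` is ``None``.
    """

    bcr: BcrValue
    icer: IcerValue
    qalys_gained: Optional[float]
    classification: Classification


def bcr(total_savings: Money, cost: Money) -> BcrValue:
    """Benefit–cost ratio, or ``NO_COST`` when the cost is non-positive."""
    if cost <= 0:
        return NO_COST
    return total_savings / cost


def icer(cost: Money, resource_savings: Money, qalys: float) -> IcerValue:
    """Net cost per QALY, or ``NET_SAVING`` when resource savings cover cost.

    Raises :class:`NoHealthGainError` for a positive net cost with zero
    QALY gain (the ratio would be unbounded).
    """
    if resource_savings >= cost:
        return NET_SAVING
    if qalys <= 0:
        raise NoHealthGainError("no_health_gain: positive net cost with no QALY gain")
    return (cost - resource_savings) / qalys


def classify(result: EvaluationResult, threshold: Money = 50_000.0) -> Classification:
    """Threshold classification of an evaluated intervention.

    ``NET_SAVING`` → cost-saving; ``NO_COST`` → dominant at no cost; a
    finite ICER at or below the willingness-to-pay threshold →
    cost-effective; above it → not cost-effective.
    """
    if result.icer is NET_SAVING:
        return Classification.COST_SAVING
    if result.bcr is NO_COST:
        return Classification.NO_COST_DOMINANT
    if result.icer is None:
        raise ValueError("finite classification requires a computed ICER")
    return (
        Classification.COST_EFFECTIVE
        if result.icer <= threshold
        else Classification.NOT_COST_EFFECTIVE
    )


def evaluate_components(
    cost: Money,
    resource_savings: Money,
    intangible_savings: Money,
    vsly: Optional[Money] = None,
    threshold: Money = 50_000.0,
) -> EvaluationResult:
    """Full evaluation of one intervention from its dollar components.

    ``vsly`` may be omitted for dominant rows (sentinel outcomes need no
    QALY conversion) but is required whenever a finite ICER must be
    computed.
    """
    total = resource_savings + intangible_savings
    bcr_val = bcr(total, cost)
    qalys = qalys_from_intangible(intangible_savings, vsly) if vsly else None
    if cost <= 0:
        icer_val: IcerValue = None
        cls = Classification.NO_COST_DOMINANT
    elif resource_savings >= cost:
        icer_val = NET_SAVING
        cls = Classification.COST_SAVING
    else:
        if vsly is None:
            raise ValueError("vsly required to compute a finite ICER")
        icer_val = icer(cost, resource_savings, qalys)
        cls = (
            Classification.COST_EFFECTIVE
            if icer_val <= threshold
            else Classification.NOT_COST_EFFECTIVE
        )
    return EvaluationResult(bcr=bcr_val, icer=icer_val, qalys_gained=qalys, classification=cls)


def evaluate_record(
    record: InterventionRecord, config: EconomicConfig
) -> EvaluationResult:
    """Evaluate an :class:`InterventionRecord` under an economic config."""
    return evaluate_components(
        cost=record.cost_per_unit,
        resource_savings=record.resource_savings_per_unit,
        intangible_savings=record.intangible_savings_per_unit,
        vsly=config.vsly,
        threshold=config.wtp_threshold,
    )


def implied_vsly(
    cost: Money, resource_savings: Money, intangible_savings: Money, printed_icer: Money
) -> Money:
    """VSLY implied by a printed ICER: intangible × ICER / net cost.

    Inverts ICER = (cost − resource) / (intangible / VSLY).  Raises
    :class:`NetSavingRowError` for dominant rows (net cost ≤ 0), where the
    inversion is undefined.
    """
    net_cost = cost - resource_savings
    if net_cost <= 0:
        raise NetSavingRowError("net_saving_row: implied VSLY undefined for dominant rows")
    if printed_icer <= 0:
        raise ValueError("printed_icer must be positive")
    return intangible_savings * printed_icer / net_cost


@dataclass(frozen=True)
class VslyCalibration:
    """Summary of the implied-VSLY constant across one table's rows."""

    n_rows: int
    median: Money
    mean: Money
    cv: float  # coefficient of variation (population sd / mean)
    minimum: Money
    maximum: Money
    values: tuple[float, ...]


def _printed_number(x) -> Optional[float]:
    """Numeric value of a printed ratio cell, None for sentinel tokens/NaN."""
    if isinstance(x, Sentinel):
        return None
    if isinstance(x, str):
        if x.strip().upper().replace(" ", "_") in {"NO_COST", "NET_SAVING"}:
            return None
        return float(x)
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def calibrate_vsly(
    table: pd.DataFrame, min_net_cost: Money = VSLY_MIN_NET_COST
) -> VslyCalibration:
    """Calibrate the implied VSLY from a fixture table's printed rows.

    Uses every row with a numeric printed cost/QALY and net cost at least
    ``min_net_cost`` (smaller denominators amplify whole-dollar rounding).
    """
    values: list[float] = []
    for _, row in table.iterrows():
        printed = _printed_number(row["cost_per_qaly_printed"])
        if printed is None or printed <= 0:
            continue
        net = row["cost_per_unit"] - row["resource_savings"]
        if net < min_net_cost:
            continue
        values.append(
            implied_vsly(
                row["cost_per_unit"],
                row["resource_savings"],
                row["intangible_savings"],
                printed,
            )
        )
    if not values:
        raise ValueError("no rows usable for VSLY calibration")
    arr = np.asarray(values)
    return VslyCalibration(
        n_rows=len(values),
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        cv=float(arr.std() / arr.mean()),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        values=tuple(float(v) for v in arr),
    )


_CATEGORY_ORDER = [
    "availability",
    "marketing",
    "pricing",
    "drink_driving",
    "workplace",
    "health_sector",
    "youth_development",
    "school_based",
]


def league_table(
    results: Sequence[tuple[InterventionRecord, EvaluationResult]],
    sort_key: str = "bcr",
    group_by_category: bool = True,
) -> pd.DataFrame:
    """Rank evaluated interventions for priority setting.

    Dominant rows (cost-saving / no-cost) sort first; remaining rows by
    descending BCR or ascending ICER; ties break on intervention id.  With
    ``group_by_category`` the ranking is applied within each category, in
    the canonical category order used by the source tables.
    """
    if sort_key not in {"bcr", "icer"}:
        raise ValueError("sort_key must be 'bcr' or 'icer'")
    rows = []
    for record, result in results:
        dominant = result.classification in (
            Classification.COST_SAVING,
            Classification.NO_COST_DOMINANT,
        )
        if sort_key == "bcr":
            metric = -result.bcr if isinstance(result.bcr, float) else -math.inf
        else:
            metric = result.icer if isinstance(result.icer, float) else -math.inf
        rows.append(
            {
                "id": record.id,
                "name": record.name,
                "category": record.category.value,
                "cost": record.cost_per_unit,
                "resource": record.resource_savings_per_unit,
                "intangible": record.intangible_savings_per_unit,
                "total": record.total_savings_per_unit,
                "bcr": str(result.bcr) if isinstance(result.bcr, Sentinel) else result.bcr,
                "icer": str(result.icer) if isinstance(result.icer, Sentinel) else result.icer,
                "classification": result.classification.value,
                "_dominant": 0 if dominant else 1,
                "_metric": metric,
                "_cat_rank": _CATEGORY_ORDER.index(record.category.value),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "id", "name", "category", "cost", "resource", "intangible",
                "total", "bcr", "icer", "classification",
            ]
        )
    sort_cols = (["_cat_rank"] if group_by_category else []) + ["_dominant", "_metric", "id"]
    df = df.sort_values(sort_cols, kind="stable").drop(
        columns=["_dominant", "_metric", "_cat_rank"]
    )
    return df.reset_index(drop=True)


def consistency_report(
    table: pd.DataFrame,
    vsly: Optional[Money] = None,
    *,
    bcr_tolerance: float = BCR_FLAG_TOLERANCE,
    icer_rel_tol: float = 0.01,
    icer_min_net_cost: Money = 250.0,
    vsly_band: Optional[tuple[Money, Money]] = None,
    vsly_min_net_cost: Money = VSLY_MIN_NET_COST,
    sum_tolerance: Money = 1.0,
) -> pd.DataFrame:
    """Check every printed row of a fixture table against its own components.

    Per-row flags:

    ``sum_ok``
        resource + intangible equals the printed total within
        ``sum_tolerance`` (whole-dollar printing);
    ``bcr_ok``
        recomputed total/cost within ``bcr_tolerance`` of the printed BCR
        (sentinel cells check the cost sign instead) — rows failing this
        are casualties of printed-input rounding, e.g. a $19 printed cost;
    ``icer_ok``
        for rows with printed net cost ≥ ``icer_min_net_cost``, the ICER
        recomputed at ``vsly`` matches the printed cost/QALY within
        ``icer_rel_tol`` relative; ``False`` also marks rows whose printed
        number contradicts their components (a "$0" cell on a row whose
        resource savings exceed its cost); ``None`` where not checkable;
    ``vsly_band``
        the row's implied VSLY lies inside ``vsly_band`` (``None`` when no
        band given or the row's net cost is below ``vsly_min_net_cost``).

    ``vsly=None`` calibrates the median implied VSLY from the table itself.
    """
    if vsly is None:
        vsly = calibrate_vsly(table, min_net_cost=vsly_min_net_cost).median
    out = []
    for _, row in table.iterrows():
        cost = row["cost_per_unit"]
        resource = row["resource_savings"]
        intangible = row["intangible_savings"]
        total = row["total_savings"]
        printed_bcr = row["bcr_printed"]
        printed_icer = row["cost_per_qaly_printed"]
        net = cost - resource

        sum_ok = abs((resource + intangible) - total) <= sum_tolerance

        bcr_num = _printed_number(printed_bcr)
        if bcr_num is None:  # printed "No cost"
            recomputed_bcr = None
            bcr_ok = cost <= 0
        elif cost <= 0:
            recomputed_bcr = None
            bcr_ok = False
        else:
            recomputed_bcr = total / cost
            bcr_ok = abs(recomputed_bcr - bcr_num) <= bcr_tolerance

        icer_num = _printed_number(printed_icer)
        recomputed_icer = None
        if icer_num is None:  # printed "Net saving"
            icer_ok: Optional[bool] = resource >= cost
        elif net <= 0:
            # printed a number although the components imply a net saving
            icer_ok = False
        elif net < icer_min_net_cost or icer_num <= 0:
            icer_ok = None
        else:
            recomputed_icer = net * vsly / intangible
            icer_ok = abs(recomputed_icer - icer_num) / icer_num <= icer_rel_tol

        row_vsly = None
        vsly_flag: Optional[bool] = None
        if icer_num is not None and icer_num > 0 and net >= vsly_min_net_cost:
            row_vsly = implied_vsly(cost, resource, intangible, icer_num)
            if vsly_band is not None:
                vsly_flag = vsly_band[0] <= row_vsly <= vsly_band[1]

        out.append(
            {
                "id": row["id"],
                "sum_ok": sum_ok,
                "recomputed_bcr": recomputed_bcr,
                "bcr_ok": bcr_ok,
                "recomputed_icer": recomputed_icer,
                "icer_ok": icer_ok,
                "implied_vsly": row_vsly,
                "vsly_band": vsly_flag,
            }
        )
    return pd.DataFrame(out)


__all__ = [
    "BCR_FLAG_TOLERANCE",
    "VSLY_MIN_NET_COST",
    "Sentinel",
    "NO_COST",
    "NET_SAVING",
    "Classification",
    "NoHealthGainError",
    "NetSavingRowError",
    "EvaluationResult",
    "bcr",
    "icer",
    "classify",
    "evaluate_components",
    "evaluate_record",
    "implied_vsly",
    "VslyCalibration",
    "calibrate_vsly",
    "league_table",
    "consistency_report",
]
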