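"""Fixture packaging, CSV I/O, configuration files and the pipeline driver.

The package ships the printed cost-effectiveness tables as CSV fixtures:

* ``table1_counts`` — intervention counts per category;
* ``table2_ratings`` — evidence-quality grades per intervention;
* ``table3_flags`` — standardization adjustments per intervention;
* ``table4_rows`` — environmental, workplace and health-sector rows (33);
* ``table5_rows`` — youth-development and school-based rows (17).

Printed sentinel cells are preserved verbatim as the literal tokens
``NO_COST`` / ``NET_SAVING`` (and the one printed ``$0`` cost/QALY cell as
the number 0), so round-trips are unambiguous.  Table 4 and 5 rows dedupe
to 49 distinct interventions: Positive Action is evaluated twice (grades
3–8 and 3–5) but is one program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .core import (
    AdjustmentFlag,
    Category,
    Denominator,
    EconomicConfig,
    InterventionRecord,
    JurisdictionProfile,
    QualityRating,
    record_violations,
)
from .evaluation import (
    EvaluationResult,
    VslyCalibration,
    calibrate_vsly,
    consistency_report,
    evaluate_record,
    league_table,
)

logger = logging.getLogger(__name__)

FIXTURE_NAMES = (
    "table1_counts",
    "table2_ratings",
    "table3_flags",
    "table4_rows",
    "table5_rows",
)

#: Implied-VSLY plausibility bands per fixture table (AUD per QALY).  The
#: two tables imply different constants; the gap is reported, not
#: reconciled (see docs/methods.md).
VSLY_BANDS = {
    "table4_rows": (178_000.0, 186_000.0),
    "table5_rows": (225_000.0, 245_000.0),
}

INTERVENTIONS_COLUMNS = [
    "id",
    "name",
    "category",
    "cost_per_unit",
    "denominator",
    "resource_savings",
    "intangible_savings",
    "quality_rating",
    "demonstration_stage",
    "flags",
]


class SchemaError(ValueError):
    code = "schema_violation"


def _fixture_path(name: str):
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    return resources.files("alcoroi.data").joinpath(f"{name}.csv")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table, preserving printed values verbatim.

    For the row tables the ratio columns (``bcr_printed``,
    ``cost_per_qaly_printed``) stay as objects: floats where a number was
    printed, the tokens ``"NO_COST"`` / ``"NET_SAVING"`` where a sentinel
    was.
    """
    path = _fixture_path(name)
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    if name == "table1_counts":
        df["count"] = df["count"].astype(int)
        return df
    if name == "table3_flags":
        for col in df.columns[1:]:
            df[col] = df[col].map({"True": True, "False": False})
        return df
    if name in ("table4_rows", "table5_rows"):
        for col in ("cost_per_unit", "resource_savings", "intangible_savings", "total_savings"):
            df[col] = df[col].astype(float)
        for col in ("bcr_printed", "cost_per_qaly_printed"):
            df[col] = df[col].map(
                lambda x: x if x in ("NO_COST", "NET_SAVING") else float(x)
            )
        df["demonstration_stage"] = df["demonstration_stage"].map(
            {"True": True, "False": False}
        )
        return df
    return df  # table2_ratings: all-string

def _parse_flags(cell: str) -> frozenset[AdjustmentFlag]:
    if not cell or not str(cell).strip():
        return frozenset()
    return frozenset(AdjustmentFlag(tok) for tok in str(cell).split("|"))


def _row_to_record(row: pd.Series) -> InterventionRecord:
    demo = row["demonstration_stage"]
    if isinstance(demo, str):
        demo = demo.strip() == "True"
    return InterventionRecord(
        id=str(row["id"]),
        name=str(row["name"]),
        category=Category(row["category"]),
        cost_per_unit=float(row["cost_per_unit"]),
        denominator=Denominator(row["denominator"]),
        resource_savings_per_unit=float(row["resource_savings"]),
        intangible_savings_per_unit=float(row["intangible_savings"]),
        quality_rating=QualityRating(row["quality_rating"]),
        demonstration_stage=bool(demo),
        adjustment_flags=_parse_flags(row.get("flags", "")),
    )


def fixture_records(name: str) -> list[InterventionRecord]:
    """Parse a row fixture (``table4_rows`` / ``table5_rows``) into records."""
    df = load_fixture(name)
    return [_row_to_record(row) for _, row in df.iterrows()]


def intervention_registry() -> pd.DataFrame:
    """Map evaluated table rows to distinct intervention identities.

    Positive Action has two evaluated variants (grades 3–8 and 3–5) that
    share one identity, so 50 rows map to 49 interventions — the total the
    overview table reports.
    """
    rows = []
    for table in ("table4_rows", "table5_rows"):
        df = load_fixture(table)
        for row_id, category in zip(df["id"], df["category"]):
            key = row_id
            if row_id.startswith("sb_positive_action"):
                key = "sb_positive_action"
            rows.append({"row_id": row_id, "intervention_key": key,
                         "category": category, "table": table})
    return pd.DataFrame(rows)


def read_interventions(path: Union[str, Path]) -> list[InterventionRecord]:
    """Read an interventions CSV into validated records.

    Raises :class:`SchemaError` for a missing column and :class:`ValueError`
    naming the offending line for unparseable cells.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in INTERVENTIONS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"schema_violation: missing column(s) {missing} in {path}")
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            record = _row_to_record(row)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {line_no}: {exc}") from exc
        violations = record_violations(record)
        if violations:
            raise ValueError(
                f"{path}, line {line_no}: record {record.id!r} violates {violations}"
            )
        records.append(record)
    return records


def write_interventions(path: Union[str, Path], records: Sequence[InterventionRecord]) -> None:
    """Write records to the interventions CSV schema (round-trips with reader)."""
    rows = [
        {
            "id": r.id,
            "name": r.name,
            "category": r.category.value,
            "cost_per_unit": r.cost_per_unit,
            "denominator": r.denominator.value,
            "resource_savings": r.resource_savings_per_unit,
            "intangible_savings": r.intangible_savings_per_unit,
            "quality_rating": r.quality_rating.value,
            "demonstration_stage": r.demonstration_stage,
            "flags": "|".join(sorted(f.value for f in r.adjustment_flags)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=INTERVENTIONS_COLUMNS).to_csv(path, index=False)


def write_league(path: Union[str, Path], report: pd.DataFrame) -> None:
    """Write a league table to CSV (sentinels as literal tokens)."""
    report.to_csv(path, index=False)


def load_economic_config(path: Union[str, Path]) -> EconomicConfig:
    """Load an :class:`EconomicConfig` from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return EconomicConfig(**data)


def load_jurisdiction_profile(path: Union[str, Path]) -> JurisdictionProfile:
    """Load a :class:`JurisdictionProfile` (nested map for occupation wages)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return JurisdictionProfile(**data)


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    league: pd.DataFrame
    consistency: Optional[pd.DataFrame]
    calibration: Optional[VslyCalibration]
    results: list[tuple[InterventionRecord, EvaluationResult]] = field(default_factory=list)


def run_pipeline(
    records: Optional[Sequence[InterventionRecord]] = None,
    fixture: Optional[str] = None,
    config: Optional[EconomicConfig] = None,
    sort_key: str = "bcr",
) -> PipelineResult:
    """Evaluate a set of interventions end to end.

    Input is either explicit ``records`` or a fixture table name.  When the
    config carries no VSLY and a fixture is named, the VSLY is calibrated
    from that fixture's printed rows (median implied value); the
    consistency report is produced for fixture runs only.  Deterministic:
    identical inputs and config give byte-identical outputs.
    """
    config = config or EconomicConfig()
    calibration = None
    consistency = None
    if fixture is not None:
        if records is not None:
            raise ValueError("pass either records or fixture, not both")
        table = load_fixture(fixture)
        records = fixture_records(fixture)
        if config.vsly is None:
            calibration = calibrate_vsly(table)
            config = EconomicConfig(
                discount_rate=config.discount_rate,
                vsly=calibration.median,
                wtp_threshold=config.wtp_threshold,
                demonstration_discount=config.demonstration_discount,
                price_year=config.price_year,
            )
            logger.info("stage=calibrate event=vsly_calibrated fixture=%s vsly=%.0f",
                        fixture, config.vsly)
        consistency = consistency_report(
            table, vsly=config.vsly, vsly_band=VSLY_BANDS.get(fixture)
        )
    if records is None:
        records = []
    if not records:
        logger.warning("stage=evaluate event=empty_input")
        return PipelineResult(league=league_table([], sort_key=sort_key),
                              consistency=consistency, calibration=calibration)
    results = []
    for record in records:
        result = evaluate_record(record, config)
        logger.debug("stage=evaluate event=row_evaluated id=%s class=%s",
                     record.id, result.classification.value)
        results.append((record, result))
    league = league_table(results, sort_key=sort_key)
    return PipelineResult(league=league, consistency=consistency,
                          calibration=calibration, results=results)


__all__ = [
    "FIXTURE_NAMES",
    "VSLY_BANDS",
    "INTERVENTIONS_COLUMNS",
    "SchemaError",
    "load_fixture",
    "fixture_records",
    "intervention_registry",
    "read_interventions",
    "write_interventions",
    "write_league",
    "load_economic_config",
    "load_jurisdiction_profile",
    "PipelineResult",
    "run_pipeline",
]
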