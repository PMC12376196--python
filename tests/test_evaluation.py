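"""BCR/ICER computation, classification, VSLY inversion and consistency checks."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from alcoroi.core import EconomicConfig
from alcoroi.evaluation import (
    NET_SAVING,
    NO_COST,
    Classification,
    EvaluationResult,
    NetSavingRowError,
    NoHealthGainError,
    bcr,
    calibrate_vsly,
    classify,
    consistency_report,
    evaluate_components,
    icer,
    implied_vsly,
    league_table,
)
from alcoroi.io import fixture_records


class TestBcr:
    def test_underage_enforcement_ratio(self):
        assert bcr(184.0, 4.0) == 46.0

    def test_break_even(self):
        assert bcr(50.0, 50.0) == 1.0

    def test_negative_cost_is_no_cost_sentinel(self):
        assert bcr(7.0, -10.0) is NO_COST
        assert bcr(7.0, 0.0) is NO_COST

    @given(
        cost=st.tuples(st.floats(1, 1e5), st.floats(1, 1e5)),
        savings=st.floats(0, 1e6),
    )
    def test_strictly_decreasing_in_cost(self, cost, savings):
        lo, hi = sorted(cost)
        if hi > lo and savings > 0:
            assert bcr(savings, hi) < bcr(savings, lo)

    @given(cost=st.floats(1, 1e5), savings=st.tuples(st.floats(0, 1e6), st.floats(0, 1e6)))
    def test_strictly_increasing_in_savings(self, cost, savings):
        lo, hi = sorted(savings)
        if hi > lo:
            assert bcr(hi, cost) > bcr(lo, cost)


class TestIcer:
    def test_resource_savings_covering_cost_is_net_saving(self):
        assert icer(1.0, 8.0, qalys=0.001) is NET_SAVING

    def test_minimum_drinking_age_net_cost_per_qaly(self):
        # 0.0037335 QALYs from $679 intangible at the implied VSLY
        value = icer(401.0, 142.0, 0.0037335)
        assert value == pytest.approx(69_355, rel=1e-3)

    def test_plain_ratio(self):
        assert icer(100.0, 0.0, 1.0) == 100.0

    def test_no_health_gain(self):
        with pytest.raises(NoHealthGainError):
            icer(100.0, 0.0, 0.0)

    @given(
        costs=st.tuples(st.floats(100, 1e5), st.floats(100, 1e5)),
        resource=st.floats(0, 99),
        qalys=st.floats(0.01, 10),
    )
    def test_monotone_in_cost_and_resource(self, costs, resource, qalys):
        lo, hi = sorted(costs)
        if hi > lo:
            assert icer(hi, resource, qalys) > icer(lo, resource, qalys)
        assert icer(hi, resource, qalys) >= icer(hi, resource + 0.5, qalys)


class TestClassify:
    def test_sentinels(self):
        saving = EvaluationResult(bcr=35.0, icer=NET_SAVING, qalys_gained=None,
                                  classification=Classification.COST_SAVING)
        assert classify(saving) is Classification.COST_SAVING
        no_cost = EvaluationResult(bcr=NO_COST, icer=None, qalys_gained=None,
                                   classification=Classification.NO_COST_DOMINANT)
        assert classify(no_cost) is Classification.NO_COST_DOMINANT

    @pytest.mark.parametrize(
        "icer_value,expected",
        [
            (9_151.0, Classification.COST_EFFECTIVE),       # outlet density row
            (102_161.0, Classification.NOT_COST_EFFECTIVE), # electronic house arrest
            (50_000.0, Classification.COST_EFFECTIVE),      # boundary is inclusive
        ],
    )
    def test_threshold_rule(self, icer_value, expected):
        result = EvaluationResult(bcr=2.0, icer=icer_value, qalys_gained=0.1,
                                  classification=expected)
        assert classify(result, threshold=50_000.0) is expected

    @given(
        icer_value=st.floats(1, 2e5),
        thresholds=st.tuples(st.floats(1e3, 2e5), st.floats(1e3, 2e5)),
    )
    def test_monotone_in_threshold(self, icer_value, thresholds):
        lo, hi = sorted(thresholds)
        result = EvaluationResult(bcr=2.0, icer=icer_value, qalys_gained=0.1,
                                  classification=Classification.COST_EFFECTIVE)
        if classify(result, lo) is Classification.COST_EFFECTIVE:
            assert classify(result, hi) is Classification.COST_EFFECTIVE


class TestEvaluateComponents:
    def test_dominant_row(self):
        result = evaluate_components(1.0, 8.0, 27.0)
        assert result.icer is NET_SAVING
        assert result.classification is Classification.COST_SAVING

    def test_no_cost_row(self):
        result = evaluate_components(-10.0, 1.0, 6.0)
        assert result.bcr is NO_COST
        assert result.icer is None
        assert result.classification is Classification.NO_COST_DOMINANT

    def test_finite_icer_requires_vsly(self):
        with pytest.raises(ValueError):
            evaluate_components(401.0, 142.0, 679.0)
        result = evaluate_components(401.0, 142.0, 679.0, vsly=182_000.0)
        assert result.icer == pytest.approx(259 * 182_000 / 679)
        assert result.classification is Classification.NOT_COST_EFFECTIVE


class TestImpliedVsly:
    @pytest.mark.parametrize(
        "cost,resource,intangible,printed,expected",
        [
            (401.0, 142.0, 679.0, 69_355.0, 181_822.0),      # minimum drinking age
            (51_406.0, 40_487.0, 167_137.0, 11_890.0, 182_000.0),  # saturation patrols
            (102.0, 46.0, 3_157.0, 4_064.0, 229_100.0),      # Good Behavior Game
        ],
    )
    def test_inversion_of_printed_icers(self, cost, resource, intangible, printed, expected):
        assert implied_vsly(cost, resource, intangible, printed) == pytest.approx(
            expected, rel=1e-3
        )

    def test_dominant_rows_rejected(self):
        with pytest.raises(NetSavingRowError):
            implied_vsly(1.0, 8.0, 27.0, 1000.0)


class TestCalibration:
    def test_table4_implied_vsly_near_182k(self, table4):
        cal = calibrate_vsly(table4)
        assert cal.median == pytest.approx(182_000, rel=0.01)
        assert cal.cv < 0.015

    def test_table5_implied_vsly_near_232k(self, table5):
        cal = calibrate_vsly(table5)
        assert cal.median == pytest.approx(232_000, rel=0.01)


class TestLeagueTable:
    def test_availability_ranked_by_bcr(self):
        records = [
            r for r in fixture_records("table4_rows") if r.category.value == "availability"
        ]
        config = EconomicConfig(vsly=182_000.0)
        from alcoroi.evaluation import evaluate_record

        results = [(r, evaluate_record(r, config)) for r in records]
        table = league_table(results, sort_key="bcr")
        ids = list(table["id"])
        assert ids.index("avail_underage_enforce") < ids.index("avail_serving_enforce")
        # dominant rows come before all finite-ICER rows
        dominant = table["classification"].isin(["cost_saving", "no_cost_dominant"])
        assert dominant.tolist() == sorted(dominant.tolist(), reverse=True)

    def test_singleton(self, table4_records):
        from alcoroi.evaluation import evaluate_record

        record = table4_records[0]
        result = evaluate_record(record, EconomicConfig(vsly=182_000.0))
        table = league_table([(record, result)])
        assert len(table) == 1

    def test_tie_broken_by_id(self, table4_records):
        from alcoroi.core import InterventionRecord
        from alcoroi.evaluation import evaluate_record
        import dataclasses

        base = table4_records[1]  # minimum drinking age (finite ICER)
        twin = dataclasses.replace(base, id="aaa_twin")
        config = EconomicConfig(vsly=182_000.0)
        results = [(base, evaluate_record(base, config)), (twin, evaluate_record(twin, config))]
        table = league_table(results, group_by_category=False)
        assert list(table["id"]) == ["aaa_twin", base.id]


class TestConsistencyReport:
    def test_clean_row_passes_all_checks(self, table4):
        report = consistency_report(table4, vsly_band=(178_000, 186_000)).set_index("id")
        row = report.loc["avail_underage_enforce"]
        assert row["sum_ok"] and row["bcr_ok"]

    def test_rounding_flagged_rows(self, table4):
        """Small printed denominators make recomputed BCRs drift past 0.15."""
        report = consistency_report(table4).set_index("id")
        flagged = set(report.index[report["bcr_ok"] == False])  # noqa: E712
        assert flagged == {
            "wk_prime_for_life",              # 354/19 = 18.6 vs printed 18.2
            "price_wine_excise_beer_rate",    # 27/3 = 9.0 vs printed 8.8
            "price_volumetric_same_deadweight",  # 61/0.04 = 1525 vs printed 1537
            "price_volumetric_spirits_rate",  # 9564/151 = 63.3 vs printed 63
        }

    def test_contradictory_printed_verdicts_flagged(self, table4, table5):
        """Rows whose printed verdict contradicts their printed components."""
        r4 = consistency_report(table4).set_index("id")
        # printed "Net saving" but resource savings ($1,794) < cost ($1,912)
        assert r4.loc["dd_interlock_mandated", "icer_ok"] == False  # noqa: E712
        r5 = consistency_report(table5, icer_rel_tol=0.05).set_index("id")
        # printed "$0" cost/QALY although resource savings exceed cost
        assert r5.loc["sb_toward_no_drugs", "icer_ok"] == False  # noqa: E712
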