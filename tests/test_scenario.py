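"""Days-to-detect scenario engine: throughput, accrual, pooling, configs."""

from fractions import Fraction
from importlib import resources

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccspool import (
    ThroughputModel,
    days_to_detect,
    deaths_averted,
    events_averted,
    expected_adverse_events,
    expected_events_per_day,
    jurisdiction_throughput,
    parse_probability,
    run_scenario,
)
from sccspool.scenario import (
    SignalNeverAccruesError,
    load_config,
    load_config_multi,
    render_table,
    write_csv,
)

ONTARIO_ANCHOR = ThroughputModel.anchored(50_000, 14_223_942)

TABLE1_DAYS = [94, 158, 268, 314, 997, 1181, 1380, 1725, 2620, 8672, 59, 39, 37]
TABLE2_DAYS = [85, 163, 243, 274, 888, 1086, 1395, 1913, 3024, 8033, 56, 36, 34]
TABLE3_RARE_DAYS = [940, 1573, 2674, 3137, 9964, 11810, 13796, 17242, 26199,
                    86716, 589, 516, 362]
TABLE3_COMMON_DAYS = [10, 16, 27, 32, 100, 119, 138, 173, 262, 868, 6, 6, 4]


def shipped_config(name: str) -> str:
    return str(resources.files("sccspool").joinpath(f"configs/{name}"))


@pytest.fixture(scope="module")
def table1_rows():
    return run_scenario(load_config(shipped_config("myocarditis_table1.json")))


@pytest.fixture(scope="module")
def table2_rows():
    return run_scenario(load_config(shipped_config("vitt_table2.json")))


@pytest.fixture(scope="module")
def table3_rows():
    specs = load_config_multi(shipped_config("hypothetical_table3.json"))
    return [run_scenario(spec) for spec in specs]


class TestParseProbability:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("1/100000", Fraction(1, 100_000)),
            ("1.5/100000", Fraction(3, 200_000)),
            ("0.0035", Fraction(35, 10_000)),
            (0.00001, Fraction(1, 100_000)),
            (Fraction(1, 4), Fraction(1, 4)),
        ],
    )
    def test_notations_normalize(self, raw, expected):
        assert parse_probability(raw) == expected


class TestThroughput:
    def test_anchor_jurisdiction_keeps_its_own_throughput(self):
        assert jurisdiction_throughput(14_223_942, ONTARIO_ANCHOR) == 50_000

    def test_anchored_scaling_floors_to_whole_doses(self):
        assert jurisdiction_throughput(1_342_153, ONTARIO_ANCHOR) == 4_717
        assert jurisdiction_throughput(8_501_833, ONTARIO_ANCHOR) == 29_885

    def test_flat_rate(self):
        assert jurisdiction_throughput(
            4_517_570, ThroughputModel.flat("0.0035")
        ) == 15_811

    def test_explicit_passthrough(self):
        assert jurisdiction_throughput(
            99, ThroughputModel.explicit(7_500)
        ) == 7_500

    def test_rejects_nonpositive_population(self):
        with pytest.raises(ValueError, match="positive"):
            jurisdiction_throughput(0, ONTARIO_ANCHOR)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ThroughputModel("hourly")
        with pytest.raises(ValueError, match="daily_fraction"):
            ThroughputModel.flat("1.5")


class TestAccrualArithmetic:
    def test_expected_events_per_day(self):
        assert expected_events_per_day(50_000, "1/100000") == Fraction(1, 2)
        assert expected_events_per_day(0, "1/100000") == 0
        assert float(
            expected_events_per_day(15_811, "1.5/100000")
        ) == pytest.approx(0.237165)

    @pytest.mark.parametrize(
        "n, rate, expected",
        [(47, "0.5", 94), (20, "0.75", 27), (47, "0.09126", 516)],
    )
    def test_days_to_detect(self, n, rate, expected):
        assert days_to_detect(n, rate) == expected

    def test_zero_rate_never_accrues(self):
        with pytest.raises(SignalNeverAccruesError):
            days_to_detect(47, 0)

    def test_events_averted(self):
        assert events_averted(85, 36, "0.55641") == 28
        # same 49 days saved, priced at the national pooled rate
        assert events_averted(85, 36, "0.59259") == 30
        assert events_averted(85, 34, "0.59259") == 31  # ceil of 30.22
        assert events_averted(40, 40, "0.5") == 0
        with pytest.raises(ValueError):
            events_averted(30, 40, "0.5")

    def test_deaths_averted_floors(self):
        assert deaths_averted(28, 0.23) == 6
        assert deaths_averted(30, 0.23) == 6
        assert deaths_averted(0, 0.23) == 0

    def test_expected_adverse_events(self):
        assert expected_adverse_events(1000, 0.5, 0.01) == pytest.approx(5.0)
        assert expected_adverse_events(
            14_223_942, 0.9, 0.01
        ) == pytest.approx(128_015.478)
        assert expected_adverse_events(12345, 0, 0.5) == 0.0


class TestWholePopulationScenario:
    def test_days_column(self, table1_rows):
        assert [r.days_to_detect for r in table1_rows] == TABLE1_DAYS

    def test_pooled_populations_and_throughputs(self, table1_rows):
        by_label = {r.label: r for r in table1_rows}
        assert by_label["ON + PQ"].population == 22_725_775
        assert by_label["ON + PQ"].throughput == 79_885
        six = by_label["BC + AB + SK + MB + ON + PQ"]
        assert six.population == 34_463_947
        assert six.throughput == 121_145
        # the national row sums all 13 floored jurisdiction throughputs
        assert by_label["Canada"].throughput == 130_028
        assert by_label["Canada"].population == 36_991_981

    def test_summed_and_direct_national_modes_agree_on_days(self):
        import dataclasses

        spec = load_config(shipped_config("myocarditis_table1.json"))
        direct = dataclasses.replace(spec, national_aggregation="direct")
        summed_days = run_scenario(spec)[-1].days_to_detect
        direct_days = run_scenario(direct)[-1].days_to_detect
        assert summed_days == direct_days == 37

    def test_singleton_pool_equals_jurisdiction(self, table1_rows):
        ontario = table1_rows[0]
        assert ontario.label == "Ontario"
        assert ontario.throughput == 50_000
        assert ontario.days_to_detect == 94


class TestAgeRestrictedScenario:
    def test_days_column(self, table2_rows):
        assert [r.days_to_detect for r in table2_rows] == TABLE2_DAYS

    def test_national_direct_row(self, table2_rows):
        canada = table2_rows[-1]
        assert canada.population == 11_287_640
        assert canada.throughput == 39_506
        assert canada.days_to_detect == 34

    def test_women_18_39_explicit_throughput(self, vitt_design):
        from sccspool import required_events

        n = required_events(vitt_design).n_required
        rate = expected_events_per_day(7_500, "1.5/100000")
        assert days_to_detect(n, rate) == 178

    def test_whole_population_variant(self, vitt_design):
        from sccspool import required_events

        n = required_events(vitt_design).n_required
        rate = expected_events_per_day(50_000, "1.5/100000")
        assert days_to_detect(n, rate) == 27


class TestHypotheticalRates:
    def test_rare_event_days(self, table3_rows):
        assert [r.days_to_detect for r in table3_rows[0]] == TABLE3_RARE_DAYS

    def test_common_event_days(self, table3_rows):
        assert [r.days_to_detect for r in table3_rows[1]] == TABLE3_COMMON_DAYS

    def test_rate_scaling_divides_days_tenfold(self, table1_rows, table3_rows):
        # 1/1,000,000 is a tenth of 1/100,000: days stretch ~10x per province
        for base, rare in zip(table1_rows[:10], table3_rows[0][:10]):
            assert rare.days_to_detect / base.days_to_detect == pytest.approx(
                10.0, rel=0.01
            )


class TestScenarioInvariants:
    def test_accrual_bracketing_every_row(
        self, table1_rows, table2_rows, table3_rows
    ):
        from sccspool import required_events

        for rows, n in [
            (table1_rows, 47), (table2_rows, 20),
            (table3_rows[0], 47), (table3_rows[1], 47),
        ]:
            for row in rows:
                days, rate = row.days_to_detect, row.events_per_day
                assert days * rate >= n > (days - 1) * rate

    def test_pool_dominance(self, table1_rows, table2_rows):
        for rows in (table1_rows, table2_rows):
            singles = {r.label: r.days_to_detect for r in rows[:10]}
            assert rows[10].days_to_detect <= min(
                singles["Ontario"], singles["Quebec"]
            )
            assert rows[11].days_to_detect <= min(singles.values())
            assert rows[12].days_to_detect <= rows[11].days_to_detect

    def test_throughput_additivity_anchored(self, table1_rows):
        singles = {r.label: r.throughput for r in table1_rows[:10]}
        assert table1_rows[10].throughput == (
            singles["Ontario"] + singles["Quebec"]
        )


class TestConfigAndOutput:
    def test_multi_rate_config_requires_multi_loader(self):
        with pytest.raises(ValueError, match="load_config_multi"):
            load_config(shipped_config("hypothetical_table3.json"))

    def test_unknown_throughput_mode_rejected(self):
        doc = {
            "design": {"relative_incidence": 3.0, "risk_days": 28,
                       "observation_days": 180},
            "per_dose_risk": "1/100000",
            "throughput": {"mode": "warp"},
            "rows": [["Ontario"]],
        }
        with pytest.raises(ValueError, match="warp"):
            load_config(doc)

    def test_csv_roundtrip_full_precision(self, table1_rows, tmp_path):
        import csv

        path = tmp_path / "table1.csv"
        write_csv(table1_rows, path)
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 13
        assert rows[0]["label"] == "Ontario"
        assert float(rows[1]["events_per_day"]) == pytest.approx(0.29885)
        assert int(rows[-1]["days_to_detect"]) == 37

    def test_render_table_display_rules(self, table2_rows):
        text = render_table(table2_rows)
        assert "<0.01" in text          # sub-0.005 rates
        assert "0.24" in text           # Ontario 18-39 rate to 2 decimals
        assert "Newfoundland and Labrador" in text


@settings(max_examples=100, deadline=None)
@given(
    n=st.integers(1, 500),
    throughput=st.integers(1, 200_000),
    denom=st.sampled_from([10_000, 100_000, 1_000_000]),
)
def test_days_bracketing_property(n, throughput, denom):
    """ceil semantics: the last day crosses the threshold, the prior misses."""
    rate = expected_events_per_day(throughput, Fraction(1, denom))
    days = days_to_detect(n, rate)
    assert days * rate >= n
    assert (days - 1) * rate < n
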