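from dataclasses import replace
from datetime import date

import pytest

from phenofair.model import (
    Event,
    ObservationRecord,
    PhenofairError,
    ValidationFailed,
    canonicalize,
)
from phenofair.synth import generate_fixture
from phenofair.tabular import (
    SECTION_NAMES,
    read_miappe_workbook,
    read_observation_table,
    read_weather_table,
    write_miappe_workbook,
    write_observation_table,
    write_weather_table,
)

from conftest import small_spec


# ---------------------------------------------------------------------------
# workbook


@pytest.mark.parametrize("form", ["dir", "xlsx"])
def test_workbook_round_trip(tiny_investigation, tmp_path, form):
    path = tmp_path / ("wb.xlsx" if form == "xlsx" else "wb")
    write_miappe_workbook(tiny_investigation, path)
    reloaded, report = read_miappe_workbook(path)
    assert report.ok
    assert reloaded == canonicalize(tiny_investigation)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_workbook_round_trip_over_generated_fixtures(tmp_path, seed):
    fx = generate_fixture(small_spec(seed=seed))
    path = tmp_path / "wb"
    write_miappe_workbook(fx.investigation, path)
    reloaded, report = read_miappe_workbook(path)
    assert report.ok
    assert reloaded == fx.investigation  # generator output is canonical


def test_missing_sample_tab_is_a_warning_not_an_error(tiny_investigation,
                                                      tmp_path):
    path = tmp_path / "wb"
    write_miappe_workbook(tiny_investigation, path)
    (path / "sample.tsv").unlink()
    inv, report = read_miappe_workbook(path)
    assert report.ok
    assert ("SECTION_MISSING", "Sample") in {
        (c, o) for c, o, _ in report.warnings}
    assert inv == canonicalize(tiny_investigation)


def test_unknown_tab_is_reported_not_ignored(tiny_investigation, tmp_path):
    path = tmp_path / "wb"
    write_miappe_workbook(tiny_investigation, path)
    (path / "notes.tsv").write_text("whatever\n", encoding="utf-8")
    _, report = read_miappe_workbook(path)
    assert "SECTION_UNKNOWN" in report.warning_codes()


def test_missing_investigation_tab_is_fatal(tiny_investigation, tmp_path):
    path = tmp_path / "wb"
    write_miappe_workbook(tiny_investigation, path)
    (path / "investigation.tsv").unlink()
    with pytest.raises(PhenofairError, match="Investigation"):
        read_miappe_workbook(path)


def test_writer_refuses_invalid_investigation(tiny_investigation, tmp_path):
    s = tiny_investigation.studies[0]
    bad = replace(tiny_investigation, studies=(
        replace(s, events=s.events + (Event("watering", "", None),)),))
    with pytest.raises(ValidationFailed) as exc:
        write_miappe_workbook(bad, tmp_path / "wb")
    assert "EVT_DATE_MISSING" in exc.value.report.error_codes()


def test_all_eleven_sections_written(tiny_investigation, tmp_path):
    path = write_miappe_workbook(tiny_investigation, tmp_path / "wb")
    assert len(list(path.glob("*.tsv"))) == len(SECTION_NAMES) == 11


# ---------------------------------------------------------------------------
# observation tables


def test_empty_cells_yield_no_records(tiny_investigation, tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("observation_unit_id\tdate\ttubw\tflow\n"
                 "pl1\t1999-08-01\t1.5\t\n", encoding="utf-8")
    records = read_observation_table(p, tiny_investigation)
    assert records == [ObservationRecord("pl1", "tubw", 1.5,
                                         date(1999, 8, 1))]


@pytest.mark.parametrize("n,k", [(1, 1), (3, 2), (5, 2)])
def test_dense_table_yields_n_times_k_records(tiny_investigation, tmp_path,
                                              n, k):
    var_ids = ["tubw", "flow"][:k]
    lines = ["\t".join(["observation_unit_id", "date", *var_ids])]
    for i in range(n):
        cells = ["pl1", f"1999-08-{i + 1:02d}"]
        for v in var_ids:
            cells.append("2.5" if v == "tubw" else "4")
        lines.append("\t".join(cells))
    p = tmp_path / "obs.tsv"
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    records = read_observation_table(p, tiny_investigation)
    assert len(records) == n * k  # one record per non-empty cell


def test_observation_round_trip_preserves_sparsity(tiny_investigation,
                                                   tmp_path):
    records = [
        ObservationRecord("pl1", "tubw", 1.5, date(1999, 8, 1)),
        ObservationRecord("pl1", "flow", "3", date(1999, 6, 1)),
        ObservationRecord("p1", "tubw", 9.25, None),
    ]
    p = tmp_path / "obs.tsv"
    write_observation_table(records, p)
    reloaded = read_observation_table(p, tiny_investigation)
    assert sorted(reloaded, key=str) == sorted(records, key=str)


def test_undeclared_header_column_fails_naming_it(tiny_investigation,
                                                  tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("observation_unit_id\tdate\ttottub\npl1\t\t4\n",
                 encoding="utf-8")
    with pytest.raises(PhenofairError, match="tottub"):
        read_observation_table(p, tiny_investigation)


def test_malformed_row_width_reports_line_number(tiny_investigation,
                                                 tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("observation_unit_id\tdate\ttubw\n"
                 "pl1\t1999-08-01\t1.5\n"
                 "pl1\t1999-08-02\n", encoding="utf-8")
    with pytest.raises(PhenofairError, match=":3"):
        read_observation_table(p, tiny_investigation)


def test_configurable_na_tokens(tiny_investigation, tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("observation_unit_id\tdate\ttubw\n"
                 "pl1\t1999-08-01\tNA\n", encoding="utf-8")
    assert len(read_observation_table(p, tiny_investigation)) == 1
    assert read_observation_table(p, tiny_investigation,
                                  na_tokens=("", "NA", "-")) == []


def test_conflicting_duplicate_errors_and_keep_last_override(
        tiny_investigation, tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("observation_unit_id\tdate\ttubw\n"
                 "pl1\t1999-08-01\t1.5\n"
                 "pl1\t1999-08-01\t2.5\n", encoding="utf-8")
    with pytest.raises(PhenofairError, match="duplicate"):
        read_observation_table(p, tiny_investigation)
    kept = read_observation_table(p, tiny_investigation,
                                  on_duplicate="keep_last")
    assert kept == [ObservationRecord("pl1", "tubw", 2.5, date(1999, 8, 1))]


def test_synonyms_resolve_to_canonical_genotype(tiny_investigation, tmp_path):
    p = tmp_path / "obs.tsv"
    p.write_text("observation_unit_id\tdate\ttubw\nalt-g1\t\t3.0\n",
                 encoding="utf-8")
    records = read_observation_table(p, tiny_investigation,
                                     resolve_synonyms=True)
    assert records[0].observation_unit_id == "g1"


# ---------------------------------------------------------------------------
# weather tables


def _weather_lines(rows):
    header = ("station_id\tstation_name\tlatitude\tlongitude\tdate\t"
              "daily_mean_temperature_C\tphotoperiod_hours")
    return "\n".join([header, *rows]) + "\n"


def test_one_station_one_day_two_observations(tmp_path):
    p = tmp_path / "w.tsv"
    p.write_text(_weather_lines(["ws1\tDe Bilt\t52.1\t5.18\t1999-06-01\t17.2\t16.6"]),
                 encoding="utf-8")
    stations, obs = read_weather_table(p)
    assert len(stations) == 1 and stations[0].id == "ws1"
    assert len(obs) == 2
    assert {o.variable for o in obs} == {"daily_mean_temperature_C",
                                         "photoperiod_hours"}


def test_month_of_days_yields_62_observations(tmp_path):
    rows = [f"ws1\t\t52.1\t5.18\t1999-07-{d:02d}\t18.0\t16.0"
            for d in range(1, 32)]
    p = tmp_path / "w.tsv"
    p.write_text(_weather_lines(rows), encoding="utf-8")
    _, obs = read_weather_table(p)
    assert len(obs) == 31 * 2


def test_photoperiod_out_of_bounds_rejected(tmp_path):
    p = tmp_path / "w.tsv"
    p.write_text(_weather_lines(["ws1\t\t52.1\t5.18\t1999-06-01\t17.2\t25.0"]),
                 encoding="utf-8")
    with pytest.raises(PhenofairError, match=r"\[0, 24\]"):
        read_weather_table(p)


def test_conflicting_duplicate_reading_rejected(tmp_path):
    p = tmp_path / "w.tsv"
    p.write_text(_weather_lines([
        "ws1\t\t52.1\t5.18\t1999-06-01\t17.2\t16.0",
        "ws1\t\t52.1\t5.18\t1999-06-01\t18.9\t16.0"]), encoding="utf-8")
    with pytest.raises(PhenofairError, match="conflicting"):
        read_weather_table(p)


def test_weather_round_trip_preserves_gaps(small_fixture, tmp_path):
    p = tmp_path / "w.tsv"
    # drop one variable on one day: the gap must survive the round trip
    obs = [o for o in small_fixture.weather][:-1]
    write_weather_table(small_fixture.stations, obs, p)
    stations, reloaded = read_weather_table(p)
    assert stations == small_fixture.stations
    assert sorted(reloaded, key=str) == sorted(obs, key=str)
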