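import random
from datetime import date

import pytest

from phenofair.milestones import (
    PhenoGraphSource,
    PhenoModelSource,
    StudySummary,
    TraitSummary,
    WeatherGraphSource,
    WeatherModelSource,
    federated_fetch,
    genotype_overlap,
    genotype_trait_means,
    match_weather_stations,
    pbtt_per_study,
    stability_lines,
    station_distance_table,
    summarize_studies,
    weather_stations,
)
from phenofair.model import PhenofairError, WeatherStation
from phenofair.rdf import (
    investigation_to_graph,
    observations_to_graph,
    weather_to_graph,
)
from phenofair.synth import FOCAL_VARIABLE
from phenofair.vocab import UriPolicy


@pytest.fixture(scope="module")
def sources(small_fixture):
    policy = UriPolicy()
    fx = small_fixture
    merged = investigation_to_graph(fx.investigation, policy) \
        + observations_to_graph(fx.all_records, fx.investigation, policy)
    return {
        "pm": PhenoModelSource(fx.investigation, fx.all_records),
        "pg": PhenoGraphSource(merged, policy),
        "wm": WeatherModelSource(fx.stations, fx.weather),
        "wg": WeatherGraphSource(
            weather_to_graph(fx.stations, fx.weather, policy), policy),
    }


# ---------------------------------------------------------------------------
# summaries


def test_summaries_equal_model_fields(small_fixture, sources):
    for key in ("pm", "pg"):
        summaries = summarize_studies(sources[key])
        assert [s.study_id for s in summaries] == \
            [s.id for s in small_fixture.investigation.studies]
        for summary, study in zip(summaries,
                                  small_fixture.investigation.studies):
            assert summary.country_code == study.country_code
            assert summary.location_name == study.location_name
            assert summary.start_date == study.start_date
            assert summary.end_date == study.end_date
            assert summary.latitude == study.latitude
            assert summary.longitude == study.longitude
            assert summary.altitude == study.altitude


# ---------------------------------------------------------------------------
# overlap


def test_overlap_same_over_model_and_graph(small_fixture, sources):
    assert genotype_overlap(sources["pm"]) \
        == genotype_overlap(sources["pg"]) \
        == small_fixture.truth.common_genotypes


def test_overlap_unknown_study_fails_naming_it(sources):
    for key in ("pm", "pg"):
        with pytest.raises(PhenofairError, match="1881XX"):
            genotype_overlap(sources[key], ["1999NL", "1881XX"])


# ---------------------------------------------------------------------------
# station matching


def test_station_at_exact_coordinates_matches_at_zero(sources):
    summaries = summarize_studies(sources["pm"])
    stations = [WeatherStation("exact", "", summaries[0].latitude,
                               summaries[0].longitude),
                WeatherStation("far", "", 0.0, 0.0)]
    matches = match_weather_stations(summaries, stations)
    first = next(m for m in matches if m.study_id == summaries[0].study_id)
    assert first.station_id == "exact"
    assert first.squared_distance == 0.0


def test_matching_agrees_with_exhaustive_pairwise_oracle():
    rng = random.Random(7)
    summaries = [StudySummary(f"S{i}", latitude=rng.uniform(-60, 60),
                              longitude=rng.uniform(-150, 150))
                 for i in range(5)]
    stations = [WeatherStation(f"w{i}", "", rng.uniform(-60, 60),
                               rng.uniform(-150, 150)) for i in range(5)]
    matches = {m.study_id: m for m in match_weather_stations(summaries,
                                                             stations)}
    for su in summaries:
        best = min(((st.id, (su.latitude - st.latitude) ** 2
                     + (su.longitude - st.longitude) ** 2)
                    for st in stations), key=lambda t: (t[1], t[0]))
        assert matches[su.study_id].station_id == best[0]
        assert matches[su.study_id].squared_distance == pytest.approx(best[1])


def test_tie_breaks_lexicographically():
    summaries = [StudySummary("S", latitude=10.0, longitude=10.0)]
    stations = [WeatherStation("wb", "", 10.0, 11.0),
                WeatherStation("wa", "", 10.0, 9.0)]
    assert match_weather_stations(summaries, stations)[0].station_id == "wa"


def test_adding_a_station_never_worsens_a_match(sources):
    summaries = summarize_studies(sources["pm"])
    stations = weather_stations(sources["wm"])
    before = {m.study_id: m.squared_distance
              for m in match_weather_stations(summaries, stations)}
    extra = stations + [WeatherStation("w-extra", "", 30.0, 30.0)]
    after = {m.study_id: m.squared_distance
             for m in match_weather_stations(summaries, extra)}
    for sid in before:
        assert after[sid] <= before[sid]


def test_empty_station_list_fails(sources):
    with pytest.raises(PhenofairError, match="no weather stations"):
        match_weather_stations(summarize_studies(sources["pm"]), [])


def test_distance_table_is_sorted_within_study(sources):
    table = station_distance_table(summarize_studies(sources["pm"]),
                                   weather_stations(sources["wm"]))
    by_study = {}
    for sid, _st, d in table:
        by_study.setdefault(sid, []).append(d)
    for dists in by_study.values():
        assert dists == sorted(dists)


# ---------------------------------------------------------------------------
# trait aggregation


def test_trait_means_match_two_pass_oracle(small_fixture, sources):
    """Independent oracle: collect the last dated record of each plant,
    then a separate two-pass arithmetic mean per (genotype, study)."""
    fx = small_fixture
    summary = genotype_trait_means(sources["pm"], FOCAL_VARIABLE)

    units = {}
    for s in fx.investigation.studies:
        for u in s.observation_units:
            units[u.id] = (s.id, u.biological_material_id, u.level)
    last_per_unit: dict[str, tuple[str, float]] = {}
    passthrough: dict[tuple[str, str], list[float]] = {}
    for r in fx.all_records:
        if r.variable_id != FOCAL_VARIABLE or not isinstance(r.value, float):
            continue
        sid, geno, level = units[r.observation_unit_id]
        if level == "genotype":
            passthrough.setdefault((geno, sid), []).append(r.value)
            continue
        key = r.observation_unit_id
        stamp = r.date.isoformat() if r.date else ""
        if key not in last_per_unit or stamp >= last_per_unit[key][0]:
            last_per_unit[key] = (stamp, r.value)
    cells: dict[tuple[str, str], list[float]] = dict(passthrough)
    for uid, (_, value) in last_per_unit.items():
        sid, geno, _ = units[uid]
        cells.setdefault((geno, sid), []).append(value)

    assert set(summary.cells) == set(cells)
    for cell, values in cells.items():
        total = 0.0          # two-pass mean: sum then divide
        for v in values:
            total += v
        assert summary.cells[cell] == pytest.approx(total / len(values),
                                                    rel=1e-12)


def test_trait_means_permutation_invariant(small_fixture):
    fx = small_fixture
    records = list(fx.all_records)
    random.Random(3).shuffle(records)
    shuffled = genotype_trait_means(
        PhenoModelSource(fx.investigation, records), FOCAL_VARIABLE)
    original = genotype_trait_means(
        PhenoModelSource(fx.investigation, fx.all_records), FOCAL_VARIABLE)
    assert shuffled.cells.keys() == original.cells.keys()
    for k in original.cells:
        assert shuffled.cells[k] == pytest.approx(original.cells[k], rel=1e-12)


def test_genotype_level_records_pass_through(small_fixture, sources):
    fx = small_fixture
    summary = genotype_trait_means(sources["pm"], FOCAL_VARIABLE)
    sid = fx.spec.genotype_level_study
    for (geno, study), count in summary.counts.items():
        if study == sid:
            assert count == 0  # plants-averaged count unknown
            assert summary.cells[(geno, study)] == pytest.approx(
                fx.truth.trait_means[(geno, study)])


def test_undeclared_variable_fails_naming_it(sources):
    for key in ("pm", "pg"):
        with pytest.raises(PhenofairError, match="tottub"):
            genotype_trait_means(sources[key], "tottub")


def test_complete_cases_equal_set_oracle_and_bounded_by_overlap(
        small_fixture, sources):
    summary = genotype_trait_means(sources["pm"], FOCAL_VARIABLE)
    studies = [s.id for s in small_fixture.investigation.studies]
    complete = summary.complete_cases(studies)
    with_values = {s: {g for (g, s2) in summary.cells if s2 == s}
                   for s in studies}
    oracle = set.intersection(*with_values.values())
    assert complete == sorted(oracle)
    assert len(complete) <= len(genotype_overlap(sources["pm"]))


# ---------------------------------------------------------------------------
# stability


def test_stability_against_brute_force_scan(small_fixture, sources):
    fx = small_fixture
    summary = genotype_trait_means(sources["pm"], FOCAL_VARIABLE)
    pbtt = pbtt_per_study(sources["pm"], sources["wm"])
    result = stability_lines(summary, pbtt)
    by_geno = {}
    for (g, s), v in summary.cells.items():
        by_geno.setdefault(g, []).append((s, v))
    assert [l.genotype_id for l in result.lines] == sorted(by_geno)
    for line in result.lines:
        cells = by_geno[line.genotype_id]
        v_min = min(v for _, v in cells)
        v_max = max(v for _, v in cells)
        assert line.value_at_low == v_min
        assert line.value_at_high == v_max
        assert line.value_at_low <= line.value_at_high
        assert line.spread == pytest.approx(v_max - v_min)
        if len(cells) == 1 or v_min == v_max:
            assert line.direction == "flat"
        elif line.pbtt_high > line.pbtt_low:
            assert line.direction == "rising"
        elif line.pbtt_high < line.pbtt_low:
            assert line.direction == "falling"


def test_single_environment_genotype_is_flat_with_zero_spread():
    summary = TraitSummary("v", cells={("g1", "A"): 5.0}, counts={("g1", "A"): 2})
    result = stability_lines(summary, {"A": 10.0})
    assert result.lines[0].direction == "flat"
    assert result.lines[0].spread == 0.0


def test_monotone_trait_in_pbtt_gives_all_rising_lines():
    pbtt = {"A": 10.0, "B": 20.0, "C": 30.0}
    cells = {(g, s): i * 2.0 + k
             for k, g in enumerate(["g1", "g2"])
             for i, s in enumerate(["A", "B", "C"])}
    summary = TraitSummary("v", cells=cells,
                           counts={c: 1 for c in cells})
    result = stability_lines(summary, pbtt)
    assert all(l.direction == "rising" for l in result.lines)


def test_zero_cell_genotypes_are_excluded_and_counted():
    summary = TraitSummary("v", cells={("g1", "A"): 1.0},
                           counts={("g1", "A"): 1})
    result = stability_lines(summary, {"A": 5.0}, genotypes=["g1", "g2", "g3"])
    assert result.excluded == ["g2", "g3"]


# ---------------------------------------------------------------------------
# PBTT per study and federation


def test_pbtt_per_study_matches_ledger(small_fixture, sources):
    got = pbtt_per_study(sources["pm"], sources["wm"])
    for sid, expected in small_fixture.truth.pbtt.items():
        assert got[sid] == pytest.approx(expected, abs=1e-9)


def test_open_ended_study_accumulates_to_last_reading(small_fixture, sources):
    from dataclasses import replace
    fx = small_fixture
    inv = fx.investigation
    open_inv = replace(inv, studies=(
        replace(inv.studies[0], end_date=None), *inv.studies[1:]))
    got = pbtt_per_study(PhenoModelSource(open_inv, fx.all_records),
                         sources["wm"])
    sid = inv.studies[0].id
    station = fx.truth.station_match[sid]
    last = max(o.date for o in fx.weather if o.station_id == station)
    from phenofair.pbtt import cumulative_pbtt
    assert got[sid] == pytest.approx(cumulative_pbtt(
        fx.weather, station, inv.studies[0].start_date, last), abs=1e-12)


def test_degenerate_federation_equals_in_memory_joins(sources):
    rows = federated_fetch(sources["pm"], sources["wm"], "station_matching")
    table = station_distance_table(summarize_studies(sources["pm"]),
                                   weather_stations(sources["wm"]))
    assert [(r["study_id"], r["station_id"], r["squared_distance"])
            for r in rows] == table
    with pytest.raises(PhenofairError, match="unknown federated request"):
        federated_fetch(sources["pm"], sources["wm"], "nonsense")
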