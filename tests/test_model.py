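from dataclasses import replace
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from phenofair.model import (
    BiologicalMaterial,
    Event,
    Investigation,
    ObservationRecord,
    ObservationUnit,
    ObservedVariable,
    Study,
    UnknownIdentifier,
    canonicalize,
    common_genotype_ids,
    genotype_of_unit,
    validate_investigation,
)


def test_consistent_investigation_validates_cleanly(tiny_investigation,
                                                    tiny_records):
    report = validate_investigation(tiny_investigation, tiny_records)
    assert report.ok
    assert report.errors == []


def test_dateless_event_is_reported(tiny_investigation):
    s = tiny_investigation.studies[0]
    bad = replace(tiny_investigation, studies=(
        replace(s, events=s.events + (Event("planting", "spring", None),)),))
    report = validate_investigation(bad)
    assert "EVT_DATE_MISSING" in report.error_codes()


def test_record_with_undeclared_variable_is_reported(tiny_investigation):
    recs = [ObservationRecord("pl1", "tottub", 4.0)]
    report = validate_investigation(tiny_investigation, recs)
    # oracle: set difference of referenced vs declared variable ids
    referenced = {r.variable_id for r in recs}
    undeclared = referenced - tiny_investigation.variable_ids()
    assert undeclared == {"tottub"}
    assert ("REC_VAR_UNKNOWN", "tottub") in {
        (c, o) for c, o, _ in report.errors}


def test_undeclared_categorical_token_error_and_permissive_downgrade(
        tiny_investigation):
    recs = [ObservationRecord("pl1", "flow", "*", date(1999, 6, 2))]
    strict = validate_investigation(tiny_investigation, recs)
    assert "REC_TOKEN_UNDECLARED" in strict.error_codes()
    lax = validate_investigation(tiny_investigation, recs,
                                 strict_categories=False)
    assert lax.ok
    assert "REC_TOKEN_UNDECLARED" in lax.warning_codes()


@pytest.mark.parametrize("mutate, code", [
    (lambda s: replace(s, latitude=95.0), "STUDY_LAT_RANGE"),
    (lambda s: replace(s, longitude=-200.0), "STUDY_LON_RANGE"),
    (lambda s: replace(s, start_date=date(2000, 1, 1),
                       end_date=date(1999, 1, 1)), "STUDY_DATES_ORDER"),
    (lambda s: replace(s, start_date="1999"), "DATE_PARTIAL"),
])
def test_study_field_invariants(tiny_investigation, mutate, code):
    bad = replace(tiny_investigation,
                  studies=(mutate(tiny_investigation.studies[0]),))
    report = validate_investigation(bad)
    assert code in report.error_codes() | report.warning_codes()


def test_reference_resolution_errors(tiny_investigation):
    s = tiny_investigation.studies[0]
    bad = replace(
        tiny_investigation,
        studies=(replace(s, observation_units=s.observation_units + (
            ObservationUnit("pl9", "plant", "ghost", "1999NL", "nowhere"),)),))
    codes = validate_investigation(bad).error_codes()
    assert {"UNIT_MAT_UNKNOWN", "UNIT_PARENT_UNKNOWN"} <= codes


def test_parent_must_be_coarser(tiny_investigation):
    s = tiny_investigation.studies[0]
    # a plot whose declared parent is a plant: nesting inverted
    bad = replace(
        tiny_investigation,
        studies=(replace(s, observation_units=s.observation_units + (
            ObservationUnit("p2", "plot", "g1", "1999NL", "pl1"),)),))
    assert "UNIT_PARENT_LEVEL" in validate_investigation(bad).error_codes()


def test_duplicate_ids_reported(tiny_investigation):
    dup_mat = replace(
        tiny_investigation,
        biological_materials=tiny_investigation.biological_materials * 2)
    assert "MAT_ID_DUP" in validate_investigation(dup_mat).error_codes()
    dup_var = replace(
        tiny_investigation,
        observed_variables=tiny_investigation.observed_variables
        + (tiny_investigation.observed_variables[0],))
    assert "VAR_ID_DUP" in validate_investigation(dup_var).error_codes()


def test_validation_is_deterministic_and_idempotent(tiny_investigation):
    s = tiny_investigation.studies[0]
    bad = replace(tiny_investigation, studies=(
        replace(s, latitude=99.0,
                events=s.events + (Event("x", "", None),)),))
    r1 = validate_investigation(bad)
    r2 = validate_investigation(bad)
    assert str(r1) == str(r2)
    assert r1.errors == sorted(r1.errors)


# ---------------------------------------------------------------------------
# genotype overlap


def _inv_with_genotype_sets(sets: dict[str, set[str]]) -> Investigation:
    all_genos = sorted(set().union(*sets.values())) if sets else []
    studies = tuple(
        Study(id=sid, observation_units=tuple(
            ObservationUnit(f"{sid}_{g}", "plant", g, sid)
            for g in sorted(genos)))
        for sid, genos in sorted(sets.items()))
    return Investigation(
        id="inv", miappe_version="1.1", studies=studies,
        biological_materials=tuple(BiologicalMaterial(g) for g in all_genos),
        observed_variables=(ObservedVariable("v1"),))


def test_single_study_overlap_is_its_own_set():
    inv = _inv_with_genotype_sets({"A": {"g2", "g1"}})
    assert common_genotype_ids(inv, ["A"]) == ["g1", "g2"]


def test_three_studies_with_shared_core():
    shared = {f"g{i}" for i in range(1, 8)}
    inv = _inv_with_genotype_sets({
        "A": shared | {"a1", "a2"},
        "B": shared | {"b1"},
        "C": shared | {"c1", "c2", "c3"},
    })
    assert common_genotype_ids(inv, ["A", "B", "C"]) == sorted(shared)


def test_unknown_study_id_is_named():
    inv = _inv_with_genotype_sets({"A": {"g1"}})
    with pytest.raises(UnknownIdentifier, match="nope"):
        common_genotype_ids(inv, ["A", "nope"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.dictionaries(
    st.sampled_from(["A", "B", "C", "D", "E"]),
    st.sets(st.sampled_from([f"g{i}" for i in range(12)]), min_size=1),
    min_size=1, max_size=5))
def test_overlap_matches_brute_force_and_is_monotone(sets):
    inv = _inv_with_genotype_sets(sets)
    sids = sorted(sets)
    result = common_genotype_ids(inv, sids)
    # brute-force fold of set intersections
    expected = set(sets[sids[0]])
    for sid in sids[1:]:
        expected &= sets[sid]
    assert result == sorted(expected)
    assert len(result) <= min(len(sets[s]) for s in sids)
    # adding a study never grows the overlap
    for k in range(1, len(sids) + 1):
        assert len(common_genotype_ids(inv, sids[:k])) >= len(result)


# ---------------------------------------------------------------------------
# genotype of unit


def test_genotype_of_unit_direct_and_genotype_level(tiny_investigation):
    assert genotype_of_unit(tiny_investigation, "pl1") == "g1"
    inv = _inv_with_genotype_sets({"VE": {"g3"}})
    unit = inv.studies[0].observation_units[0]
    g_level = replace(inv, studies=(replace(
        inv.studies[0],
        observation_units=(replace(unit, level="genotype"),)),))
    assert genotype_of_unit(g_level, "VE_g3") == "g3"
    with pytest.raises(UnknownIdentifier):
        genotype_of_unit(tiny_investigation, "missing")


def test_every_fixture_unit_matches_generator_ledger(small_fixture):
    inv = small_fixture.investigation
    for unit_id, genotype in small_fixture.truth.unit_to_genotype.items():
        assert genotype_of_unit(inv, unit_id) == genotype


def test_canonicalize_is_order_insensitive(tiny_investigation):
    shuffled = replace(
        tiny_investigation,
        observed_variables=tuple(reversed(tiny_investigation.observed_variables)),
        studies=(replace(
            tiny_investigation.studies[0],
            observation_units=tuple(reversed(
                tiny_investigation.studies[0].observation_units))),))
    assert canonicalize(shuffled) == canonicalize(tiny_investigation)
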