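"""Lossless mapping between the MIAPPE model and RDF graphs.

Phenotyping (meta)data is expressed with PPEO-style terms, weather data
with AEMET-style terms (see :mod:`phenofair.vocab`).  Every node gets a
minted URI — no blank nodes — so that FAIR Data Point harvesters can refer
back to any element.  Turtle serialization is deterministic: statements are
emitted in sorted order with a fixed prefix table, so two serializations of
equal graphs are byte-identical and diffs stay readable.

Round-trip contract: ``graph_to_investigation(investigation_to_graph(inv))``
returns the canonical form of ``inv`` (see :func:`phenofair.model.canonicalize`);
for canonical investigations the round trip is the identity.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Union

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import NamespaceManager

from .model import (
    BiologicalMaterial,
    DataFileLink,
    EnvironmentParameter,
    Event,
    Investigation,
    ObservationRecord,
    ObservationUnit,
    ObservedVariable,
    Person,
    ExperimentalFactor,
    PhenofairError,
    Study,
    ValidationFailed,
    WeatherObservation,
    WeatherStation,
    canonicalize,
    validate_investigation,
)
from .vocab import (
    AEMET,
    DCTERMS,
    GEO,
    NAMESPACE_BINDINGS,
    PPEO,
    RDF,
    RDFS,
    UriPolicy,
    WEATHER_PROPERTY_TERMS,
    weather_variable_for_term,
)

__all__ = [
    "investigation_to_graph",
    "graph_to_investigation",
    "observations_to_graph",
    "graph_to_observations",
    "weather_to_graph",
    "graph_to_weather",
    "serialize_turtle",
    "parse_turtle",
]


def _date_literal(d) -> Literal:
    # full dates become xsd:date; partial (year / year-month) stay plain
    return Literal(d) if isinstance(d, date) else Literal(str(d))


def _read_date(lit: Literal):
    value = lit.toPython()
    return value if isinstance(value, (date, str)) else str(value)


def _value_literal(value: Union[float, str]) -> Literal:
    return Literal(float(value)) if isinstance(value, (int, float)) else Literal(value)


def _opt(g: Graph, s: URIRef, p: URIRef):
    return g.value(s, p)


def _str(g: Graph, s: URIRef, p: URIRef) -> str:
    v = g.value(s, p)
    return "" if v is None else str(v)


def _float(g: Graph, s: URIRef, p: URIRef) -> Optional[float]:
    v = g.value(s, p)
    return None if v is None else float(v)


# ---------------------------------------------------------------------------
# investigation metadata


def investigation_to_graph(inv: Investigation, policy: UriPolicy) -> Graph:
    """Map a clean investigation to a PPEO-shaped graph.

    Refuses (raises :class:`ValidationFailed`) if validation reports errors:
    only consistent metadata is ever serialized.
    """
    report = validate_investigation(inv)
    if not report.ok:
        raise ValidationFailed(report)
    inv = canonicalize(inv)

    g = Graph()
    inode = policy.mint("investigation", inv.id)
    g.add((inode, RDF.type, PPEO.Investigation))
    g.add((inode, DCTERMS.identifier, Literal(inv.id)))
    g.add((inode, PPEO.miappeVersion, Literal(inv.miappe_version)))
    if inv.title:
        g.add((inode, DCTERMS.title, Literal(inv.title)))
    if inv.description:
        g.add((inode, DCTERMS.description, Literal(inv.description)))
    if inv.license:
        g.add((inode, DCTERMS.license, Literal(inv.license)))
    for doi in inv.publications:
        g.add((inode, DCTERMS.bibliographicCitation, Literal(doi)))

    for p in inv.persons:
        pnode = policy.mint("person", f"{p.name}|{p.email}|{p.affiliation}|{p.role}")
        g.add((inode, PPEO.hasPerson, pnode))
        g.add((pnode, RDF.type, PPEO.Person))
        g.add((pnode, PPEO.personName, Literal(p.name)))
        if p.email:
            g.add((pnode, PPEO.email, Literal(p.email)))
        if p.affiliation:
            g.add((pnode, PPEO.affiliation, Literal(p.affiliation)))
        if p.role:
            g.add((pnode, PPEO.personRole, Literal(p.role)))

    for m in inv.biological_materials:
        mnode = policy.mint("material", m.id)
        g.add((inode, PPEO.hasBiologicalMaterial, mnode))
        g.add((mnode, RDF.type, PPEO.BiologicalMaterial))
        g.add((mnode, DCTERMS.identifier, Literal(m.id)))
        if m.genus_species:
            g.add((mnode, PPEO.genusSpecies, Literal(m.genus_species)))
        if m.material_source:
            snode = policy.mint("source", m.material_source)
            g.add((mnode, PPEO.hasMaterialSource, snode))
            g.add((snode, RDF.type, PPEO.MaterialSource))
            g.add((snode, RDFS.label, Literal(m.material_source)))
        for syn in m.synonyms:
            g.add((mnode, PPEO.synonym, Literal(syn)))

    for v in inv.observed_variables:
        vnode = policy.mint("variable", v.id)
        g.add((inode, PPEO.hasObservedVariable, vnode))
        g.add((vnode, RDF.type, PPEO.ObservedVariable))
        g.add((vnode, DCTERMS.identifier, Literal(v.id)))
        for pred, text in ((PPEO.variableName, v.name), (PPEO.trait, v.trait),
                           (PPEO.method, v.method), (PPEO.scale, v.scale),
                           (PPEO.unit, v.unit)):
            if text:
                g.add((vnode, pred, Literal(text)))
        for cat in v.categories:
            g.add((vnode, PPEO.scaleCategory, Literal(cat)))

    for f in inv.data_files:
        fnode = policy.mint("datafile", f"{f.study_id}|{f.path_or_url}")
        g.add((inode, PPEO.hasDataFile, fnode))
        g.add((fnode, RDF.type, PPEO.DataFile))
        g.add((fnode, PPEO.filePath, Literal(f.path_or_url)))
        if f.description:
            g.add((fnode, DCTERMS.description, Literal(f.description)))
        if f.study_id:
            g.add((fnode, PPEO.forStudy, policy.mint("study", f.study_id)))

    for s in inv.studies:
        snode = policy.mint("study", s.id)
        g.add((inode, PPEO.hasStudy, snode))
        g.add((snode, RDF.type, PPEO.Study))
        g.add((snode, DCTERMS.identifier, Literal(s.id)))
        if s.title:
            g.add((snode, DCTERMS.title, Literal(s.title)))
        if s.start_date is not None:
            g.add((snode, PPEO.startDate, _date_literal(s.start_date)))
        if s.end_date is not None:
            g.add((snode, PPEO.endDate, _date_literal(s.end_date)))
        for pred, text in ((PPEO.countryCode, s.country_code),
                           (PPEO.locationName, s.location_name),
                           (PPEO.locationAddress, s.location_address),
                           (PPEO.designDescription, s.design_description)):
            if text:
                g.add((snode, pred, Literal(text)))
        if s.latitude is not None:
            g.add((snode, GEO.lat, Literal(float(s.latitude))))
        if s.longitude is not None:
            g.add((snode, GEO.long, Literal(float(s.longitude))))
        if s.altitude is not None:
            g.add((snode, GEO.alt, Literal(float(s.altitude))))

        for ep in s.environment_parameters:
            enode = policy.mint("envparam", f"{s.id}|{ep.name}|{ep.value}|{ep.unit}")
            g.add((snode, PPEO.hasEnvironmentParameter, enode))
            g.add((enode, RDF.type, PPEO.EnvironmentParameter))
            g.add((enode, PPEO.parameterName, Literal(ep.name)))
            if ep.value:
                g.add((enode, PPEO.parameterValue, Literal(ep.value)))
            if ep.unit:
                g.add((enode, PPEO.unit, Literal(ep.unit)))

        for fa in s.experimental_factors:
            fnode = policy.mint("factor", f"{s.id}|{fa.factor_type}|{fa.description}")
            g.add((snode, PPEO.hasExperimentalFactor, fnode))
            g.add((fnode, RDF.type, PPEO.ExperimentalFactor))
            g.add((fnode, PPEO.factorType, Literal(fa.factor_type)))
            if fa.description:
                g.add((fnode, DCTERMS.description, Literal(fa.description)))
            for val in fa.values:
                g.add((fnode, PPEO.factorValue, Literal(val)))

        for ev in s.events:
            enode = policy.mint(
                "event", f"{s.id}|{ev.event_type}|{ev.description}|{ev.date}")
            g.add((snode, PPEO.hasEvent, enode))
            g.add((enode, RDF.type, PPEO.Event))
            g.add((enode, PPEO.eventType, Literal(ev.event_type)))
            if ev.description:
                g.add((enode, DCTERMS.description, Literal(ev.description)))
            g.add((enode, PPEO.date, Literal(ev.date)))

        for u in s.observation_units:
            unode = policy.mint("unit", u.id)
            g.add((snode, PPEO.hasObservationUnit, unode))
            g.add((unode, RDF.type, PPEO.ObservationUnit))
            g.add((unode, DCTERMS.identifier, Literal(u.id)))
            g.add((unode, PPEO.observationLevel, Literal(u.level)))
            g.add((unode, PPEO.hasBiologicalMaterial,
                   policy.mint("material", u.biological_material_id)))
            if u.parent_unit_id:
                g.add((unode, PPEO.hasParentUnit, policy.mint("unit", u.parent_unit_id)))
    return g


def graph_to_investigation(g: Graph, policy: UriPolicy) -> Investigation:
    """Rebuild the (canonical-order) investigation from a PPEO-shaped graph."""
    inodes = sorted(g.subjects(RDF.type, PPEO.Investigation))
    if len(inodes) != 1:
        raise PhenofairError(
            f"expected exactly one ppeo:Investigation node, found {len(inodes)}")
    inode = inodes[0]
    inv_id = _str(g, inode, DCTERMS.identifier)
    version = g.value(inode, PPEO.miappeVersion)
    if version is None:
        raise PhenofairError("investigation node lacks ppeo:miappeVersion")

    persons = sorted(
        (Person(_str(g, p, PPEO.personName), _str(g, p, PPEO.email),
                _str(g, p, PPEO.affiliation), _str(g, p, PPEO.personRole))
         for p in g.objects(inode, PPEO.hasPerson)),
        key=lambda p: (p.name, p.email))

    materials = []
    for m in g.objects(inode, PPEO.hasBiologicalMaterial):
        src = g.value(m, PPEO.hasMaterialSource)
        materials.append(BiologicalMaterial(
            id=_str(g, m, DCTERMS.identifier),
            genus_species=_str(g, m, PPEO.genusSpecies),
            material_source="" if src is None else _str(g, src, RDFS.label),
            synonyms=tuple(sorted(str(x) for x in g.objects(m, PPEO.synonym))),
        ))
    materials.sort(key=lambda m: m.id)

    variables = []
    for v in g.objects(inode, PPEO.hasObservedVariable):
        variables.append(ObservedVariable(
            id=_str(g, v, DCTERMS.identifier),
            name=_str(g, v, PPEO.variableName),
            trait=_str(g, v, PPEO.trait),
            method=_str(g, v, PPEO.method),
            scale=_str(g, v, PPEO.scale),
            unit=_str(g, v, PPEO.unit),
            categories=tuple(sorted(str(x) for x in g.objects(v, PPEO.scaleCategory))),
        ))
    variables.sort(key=lambda v: v.id)

    data_files = []
    for f in g.objects(inode, PPEO.hasDataFile):
        study_ref = g.value(f, PPEO.forStudy)
        study_id = "" if study_ref is None else policy.parse(study_ref)[1]
        data_files.append(DataFileLink(_str(g, f, PPEO.filePath),
                                       _str(g, f, DCTERMS.description), study_id))
    data_files.sort(key=lambda f: (f.study_id, f.path_or_url))

    studies = []
    for s in g.objects(inode, PPEO.hasStudy):
        sid = _str(g, s, DCTERMS.identifier)
        start, end = g.value(s, PPEO.startDate), g.value(s, PPEO.endDate)

        env = sorted(
            (EnvironmentParameter(_str(g, e, PPEO.parameterName),
                                  _str(g, e, PPEO.parameterValue),
                                  _str(g, e, PPEO.unit))
             for e in g.objects(s, PPEO.hasEnvironmentParameter)),
            key=lambda p: (p.name, p.value, p.unit))
        factors = sorted(
            (ExperimentalFactor(_str(g, f, PPEO.factorType),
                                _str(g, f, DCTERMS.description),
                                tuple(sorted(str(x)
                                             for x in g.objects(f, PPEO.factorValue))))
             for f in g.objects(s, PPEO.hasExperimentalFactor)),
            key=lambda f: (f.factor_type, f.description))
        events = sorted(
            (Event(_str(g, e, PPEO.eventType), _str(g, e, DCTERMS.description),
                   g.value(e, PPEO.date).toPython())
             for e in g.objects(s, PPEO.hasEvent)),
            key=lambda e: (e.date.isoformat() if e.date else "",
                           e.event_type, e.description))
        units = []
        for u in g.objects(s, PPEO.hasObservationUnit):
            parent = g.value(u, PPEO.hasParentUnit)
            units.append(ObservationUnit(
                id=_str(g, u, DCTERMS.identifier),
                level=_str(g, u, PPEO.observationLevel),
                biological_material_id=policy.parse(
                    g.value(u, PPEO.hasBiologicalMaterial))[1],
                study_id=sid,
                parent_unit_id="" if parent is None else policy.parse(parent)[1],
            ))
        units.sort(key=lambda u: u.id)

        studies.append(Study(
            id=sid,
            title=_str(g, s, DCTERMS.title),
            start_date=None if start is None else _read_date(start),
            end_date=None if end is None else _read_date(end),
            country_code=_str(g, s, PPEO.countryCode),
            location_name=_str(g, s, PPEO.locationName),
            location_address=_str(g, s, PPEO.locationAddress),
            latitude=_float(g, s, GEO.lat),
            longitude=_float(g, s, GEO.long),
            altitude=_float(g, s, GEO.alt),
            design_description=_str(g, s, PPEO.designDescription),
            environment_parameters=tuple(env),
            events=tuple(events),
            experimental_factors=tuple(factors),
            observation_units=tuple(units),
        ))
    studies.sort(key=lambda s: s.id)

    return Investigation(
        id=inv_id,
        title=_str(g, inode, DCTERMS.title),
        description=_str(g, inode, DCTERMS.description),
        miappe_version=str(version),
        license=_str(g, inode, DCTERMS.license),
        publications=tuple(sorted(
            str(x) for x in g.objects(inode, DCTERMS.bibliographicCitation))),
        studies=tuple(studies),
        persons=tuple(persons),
        data_files=tuple(data_files),
        biological_materials=tuple(materials),
        observed_variables=tuple(variables),
    )


# ---------------------------------------------------------------------------
# observation data


def observations_to_graph(
    records: Iterable[ObservationRecord],
    inv: Investigation,
    policy: UriPolicy,
) -> Graph:
    """One observation node per record, linked to its unit and variable.

    Refuses records referencing units or variables the investigation does
    not declare.
    """
    unit_ids = {u.id for s in inv.studies for u in s.observation_units}
    var_ids = inv.variable_ids()
    g = Graph()
    for r in records:
        if r.observation_unit_id not in unit_ids:
            raise PhenofairError(
                f"record references unknown observation unit "
                f"{r.observation_unit_id!r}")
        if r.variable_id not in var_ids:
            raise PhenofairError(
                f"record references unknown observed variable {r.variable_id!r}")
        dkey = r.date.isoformat() if r.date else ""
        onode = policy.mint(
            "observation", f"{r.observation_unit_id}|{dkey}|{r.variable_id}")
        g.add((onode, RDF.type, PPEO.Observation))
        g.add((onode, PPEO.onObservationUnit,
               policy.mint("unit", r.observation_unit_id)))
        g.add((onode, PPEO.ofVariable, policy.mint("variable", r.variable_id)))
        g.add((onode, PPEO.hasValue, _value_literal(r.value)))
        if r.date is not None:
            g.add((onode, PPEO.observationDate, Literal(r.date)))
    return g


def graph_to_observations(g: Graph, policy: UriPolicy) -> list[ObservationRecord]:
    records = []
    for onode in g.subjects(RDF.type, PPEO.Observation):
        value = g.value(onode, PPEO.hasValue).toPython()
        d = g.value(onode, PPEO.observationDate)
        records.append(ObservationRecord(
            observation_unit_id=policy.parse(g.value(onode, PPEO.onObservationUnit))[1],
            variable_id=policy.parse(g.value(onode, PPEO.ofVariable))[1],
            value=float(value) if isinstance(value, (int, float)) else str(value),
            date=None if d is None else d.toPython(),
        ))
    records.sort(key=lambda r: (r.observation_unit_id,
                                r.date.isoformat() if r.date else "", r.variable_id))
    return records


# ---------------------------------------------------------------------------
# weather data


def weather_to_graph(
    stations: Iterable[WeatherStation],
    observations: Iterable[WeatherObservation],
    policy: UriPolicy,
) -> Graph:
    """AEMET-shaped weather graph: stations with coordinates, dated readings."""
    g = Graph()
    declared = set()
    for s in stations:
        declared.add(s.id)
        snode = policy.mint("station", s.id)
        g.add((snode, RDF.type, AEMET.WeatherStation))
        g.add((snode, DCTERMS.identifier, Literal(s.id)))
        if s.name:
            g.add((snode, RDFS.label, Literal(s.name)))
        if s.latitude is not None:
            g.add((snode, GEO.lat, Literal(float(s.latitude))))
        if s.longitude is not None:
            g.add((snode, GEO.long, Literal(float(s.longitude))))
    for o in observations:
        if o.station_id not in declared:
            raise PhenofairError(
                f"weather observation references undeclared station "
                f"{o.station_id!r}")
        onode = policy.mint(
            "weather", f"{o.station_id}|{o.date.isoformat()}|{o.variable}")
        g.add((onode, RDF.type, AEMET.Observation))
        g.add((onode, AEMET.observedAt, policy.mint("station", o.station_id)))
        g.add((onode, AEMET.observedProperty, WEATHER_PROPERTY_TERMS[o.variable]))
        g.add((onode, AEMET.observationDate, Literal(o.date)))
        g.add((onode, AEMET.value, Literal(float(o.value))))
    return g


def graph_to_weather(
    g: Graph, policy: UriPolicy
) -> tuple[list[WeatherStation], list[WeatherObservation]]:
    stations = sorted(
        (WeatherStation(_str(g, s, DCTERMS.identifier), _str(g, s, RDFS.label),
                        _float(g, s, GEO.lat), _float(g, s, GEO.long))
         for s in g.subjects(RDF.type, AEMET.WeatherStation)),
        key=lambda s: s.id)
    obs = []
    for o in g.subjects(RDF.type, AEMET.Observation):
        obs.append(WeatherObservation(
            station_id=policy.parse(g.value(o, AEMET.observedAt))[1],
            date=g.value(o, AEMET.observationDate).toPython(),
            variable=weather_variable_for_term(g.value(o, AEMET.observedProperty)),
            value=float(g.value(o, AEMET.value)),
        ))
    obs.sort(key=lambda o: (o.station_id, o.date.isoformat(), o.variable))
    return stations, obs


# ---------------------------------------------------------------------------
# Turtle


def serialize_turtle(g: Graph, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize deterministically: fixed sorted prefix table, then one
    statement per line in sorted order.  Equal graphs produce byte-identical
    files."""
    nm = NamespaceManager(Graph(), bind_namespaces="none")
    for prefix, ns in NAMESPACE_BINDINGS.items():
        nm.bind(prefix, ns)
    lines = [f"@prefix {prefix}: <{ns}> ."
             for prefix, ns in sorted(NAMESPACE_BINDINGS.items())]
    lines.append("")
    lines.extend(sorted(f"{s.n3(nm)} {p.n3(nm)} {o.n3(nm)} ." for s, p, o in g))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def parse_turtle(source: Union[str, Path]) -> Graph:
    """Parse a Turtle file (or literal Turtle text) into a graph."""
    from rdflib.plugins.parsers.notation3 import BadSyntax

    g = Graph()
    try:
        p = Path(source) if not str(source).lstrip().startswith("@prefix") else None
        if p is not None and p.is_file():
            g.parse(p, format="turtle")
        else:
            g.parse(data=str(source), format="turtle")
    except BadSyntax as exc:  # surface the line number rdflib reports
        raise PhenofairError(f"malformed Turtle: {exc}") from exc
    return g
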