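"""The six data-reuse milestones over any source form.

A researcher re-enacting a multi-environment potato study needs to:
(a) discover the relevant dataset (see :mod:`phenofair.fdp`),
(b) summarize its studies,
(c) verify the studies share genotypes,
(d) match each study location to a weather station,
(e) aggregate a trait per genotype per study, and
(f) integrate the trait with a photo-thermal environmental covariate
    (cumulative PBTT) to draw per-genotype stability lines.

Every milestone here runs identically over three source forms: in-memory
model objects, serialized RDF graphs, or live SPARQL endpoints.  Model
sources are read directly; graph and endpoint sources are read through the
same SPARQL queries (rdflib locally, the SPARQL protocol remotely), so the
three-way agreement of results is a real property of the serialization and
the queries, not an artifact of shared code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence, Union

from rdflib import Graph

from .endpoint import sparql_select
from .model import (
    Investigation,
    ObservationRecord,
    PhenofairError,
    Study,
    UnknownIdentifier,
    WeatherObservation,
    WeatherStation,
    common_genotype_ids,
)
from .pbtt import PbttParams, cumulative_pbtt
from .vocab import AEMET, DCTERMS, GEO, PPEO, UriPolicy, weather_variable_for_term

__all__ = [
    "PhenoModelSource", "PhenoGraphSource", "PhenoEndpointSource",
    "WeatherModelSource", "WeatherGraphSource", "WeatherEndpointSource",
    "StudySummary", "StationMatch", "TraitSummary", "StabilityLine",
    "StabilityResult",
    "summarize_studies", "genotype_overlap", "weather_stations",
    "weather_series", "match_weather_stations", "station_distance_table",
    "genotype_trait_means", "pbtt_per_study", "stability_lines",
    "federated_fetch",
]

_PREFIXES = """\
PREFIX ppeo: <http://purl.org/ppeo/PPEO.owl#>
PREFIX aemet: <http://aemet.linkeddata.es/ontology#>
PREFIX geo: <http://www.w3.org/2003/01/geo/wgs84_pos#>
PREFIX dct: <http://purl.org/dc/terms/>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
"""


# ---------------------------------------------------------------------------
# source forms


@dataclass
class PhenoModelSource:
    investigation: Investigation
    records: list[ObservationRecord] = field(default_factory=list)


@dataclass
class PhenoGraphSource:
    """Metadata + observation statements merged in one local graph."""
    graph: Graph
    policy: UriPolicy = UriPolicy()


@dataclass
class PhenoEndpointSource:
    url: str
    policy: UriPolicy = UriPolicy()


@dataclass
class WeatherModelSource:
    stations: list[WeatherStation]
    observations: list[WeatherObservation]


@dataclass
class WeatherGraphSource:
    graph: Graph
    policy: UriPolicy = UriPolicy()


@dataclass
class WeatherEndpointSource:
    url: str
    policy: UriPolicy = UriPolicy()


PhenoSource = Union[PhenoModelSource, PhenoGraphSource, PhenoEndpointSource]
WeatherSource = Union[WeatherModelSource, WeatherGraphSource,
                      WeatherEndpointSource]


def _query_target(source) -> Union[Graph, str]:
    return source.graph if hasattr(source, "graph") else source.url


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class StudySummary:
    study_id: str
    country_code: str = ""
    location_name: str = ""
    location_address: str = ""
    start_date: Union[date, str, None] = None
    end_date: Union[date, str, None] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    altitude: Optional[float] = None


@dataclass(frozen=True)
class StationMatch:
    """The station minimizing (Δlat)² + (Δlon)² for a study — squared
    differences of raw decimal degrees, a unitless composite, exactly the
    quantity the discovery queries sort on (not great-circle distance)."""

    study_id: str
    station_id: str
    squared_distance: float


@dataclass
class TraitSummary:
    """Genotype × study table of per-plant-averaged trait values.

    ``cells[(genotype, study)]`` is the arithmetic mean over that
    genotype's contributing units in that study; ``counts`` holds the
    number of contributing units, with 0 meaning "unknown" (a pre-averaged
    genotype-level record passed through as the cell value)."""

    variable_id: str
    cells: dict[tuple[str, str], float] = field(default_factory=dict)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def genotypes(self) -> list[str]:
        """Union of genotypes with at least one cell, sorted."""
        return sorted({g for g, _ in self.cells})

    def studies(self) -> list[str]:
        return sorted({s for _, s in self.cells})

    def complete_cases(self, study_ids: Optional[Sequence[str]] = None) -> list[str]:
        """Genotypes holding a value in *every* listed study (default: every
        study present in the table), sorted."""
        studies = list(study_ids) if study_ids is not None else self.studies()
        return sorted(g for g in self.genotypes()
                      if all((g, s) in self.cells for s in studies))


@dataclass(frozen=True)
class StabilityLine:
    """Best vs worst environment for one genotype: the min and max cell
    value paired with the PBTT of the study they occurred in.  ``direction``
    is "rising" when the best performance happened at higher PBTT (longer,
    warmer days), "falling" when at lower, "flat" on ties or a single
    environment.  ``spread`` (max − min) indicates (in)stability."""

    genotype_id: str
    pbtt_low: float
    value_at_low: float
    pbtt_high: float
    value_at_high: float
    direction: str

    @property
    def spread(self) -> float:
        return self.value_at_high - self.value_at_low


@dataclass
class StabilityResult:
    lines: list[StabilityLine]
    excluded: list[str]  # genotypes with zero cells in the trait table


# ---------------------------------------------------------------------------
# milestone b: study summaries


def summarize_studies(source: PhenoSource) -> list[StudySummary]:
    """One summary per study, sorted by study id, fields identical to the
    underlying Study metadata."""
    if isinstance(source, PhenoModelSource):
        return [_summary_from_study(s)
                for s in sorted(source.investigation.studies, key=lambda s: s.id)]

    q = _PREFIXES + """
    SELECT ?id ?country ?locname ?locaddr ?start ?end ?lat ?lon ?alt WHERE {
      ?s rdf:type ppeo:Study ; dct:identifier ?id .
      OPTIONAL { ?s ppeo:countryCode ?country }
      OPTIONAL { ?s ppeo:locationName ?locname }
      OPTIONAL { ?s ppeo:locationAddress ?locaddr }
      OPTIONAL { ?s ppeo:startDate ?start }
      OPTIONAL { ?s ppeo:endDate ?end }
      OPTIONAL { ?s geo:lat ?lat }
      OPTIONAL { ?s geo:long ?lon }
      OPTIONAL { ?s geo:alt ?alt }
    }"""
    rows = sparql_select(_query_target(source), q)
    out = [StudySummary(
        study_id=str(r["id"]),
        country_code=str(r.get("country", "")),
        location_name=str(r.get("locname", "")),
        location_address=str(r.get("locaddr", "")),
        start_date=r.get("start"),
        end_date=r.get("end"),
        latitude=r.get("lat"),
        longitude=r.get("lon"),
        altitude=r.get("alt"),
    ) for r in rows]
    return sorted(out, key=lambda s: s.study_id)


def _summary_from_study(s: Study) -> StudySummary:
    return StudySummary(
        study_id=s.id, country_code=s.country_code,
        location_name=s.location_name, location_address=s.location_address,
        start_date=s.start_date, end_date=s.end_date,
        latitude=s.latitude, longitude=s.longitude, altitude=s.altitude)


# ---------------------------------------------------------------------------
# milestone c: genotype overlap


def genotype_overlap(source: PhenoSource,
                     study_ids: Optional[Sequence[str]] = None) -> list[str]:
    """Genotype ids present in every named study (default: all studies),
    sorted lexicographically.  Unknown study ids fail naming the id."""
    if isinstance(source, PhenoModelSource):
        inv = source.investigation
        ids = list(study_ids) if study_ids is not None else [s.id for s in inv.studies]
        return common_genotype_ids(inv, ids)

    q = _PREFIXES + """
    SELECT ?sid ?geno WHERE {
      ?s rdf:type ppeo:Study ; dct:identifier ?sid ;
         ppeo:hasObservationUnit ?u .
      ?u ppeo:hasBiologicalMaterial ?m .
      ?m dct:identifier ?geno .
    }"""
    per_study: dict[str, set[str]] = {}
    all_studies: set[str] = set()
    for r in sparql_select(_query_target(source), _PREFIXES + """
        SELECT ?sid WHERE { ?s rdf:type ppeo:Study ; dct:identifier ?sid }"""):
        all_studies.add(str(r["sid"]))
        per_study.setdefault(str(r["sid"]), set())
    for r in sparql_select(_query_target(source), q):
        per_study.setdefault(str(r["sid"]), set()).add(str(r["geno"]))

    wanted = list(study_ids) if study_ids is not None else sorted(all_studies)
    sets = []
    for sid in wanted:
        if sid not in per_study:
            raise UnknownIdentifier(f"unknown study id: {sid!r}")
        sets.append(per_study[sid])
    return sorted(set.intersection(*sets)) if sets else []


# ---------------------------------------------------------------------------
# milestone d: weather stations and matching


def weather_stations(source: WeatherSource) -> list[WeatherStation]:
    if isinstance(source, WeatherModelSource):
        return sorted(source.stations, key=lambda s: s.id)
    q = _PREFIXES + """
    SELECT ?id ?name ?lat ?lon WHERE {
      ?st rdf:type aemet:WeatherStation ; dct:identifier ?id .
      OPTIONAL { ?st <http://www.w3.org/2000/01/rdf-schema#label> ?name }
      OPTIONAL { ?st geo:lat ?lat }
      OPTIONAL { ?st geo:long ?lon }
    }"""
    rows = sparql_select(_query_target(source), q)
    out = [WeatherStation(str(r["id"]), str(r.get("name", "")),
                          r.get("lat"), r.get("lon")) for r in rows]
    return sorted(out, key=lambda s: s.id)


def weather_series(source: WeatherSource,
                   station_id: Optional[str] = None) -> list[WeatherObservation]:
    if isinstance(source, WeatherModelSource):
        obs = [o for o in source.observations
               if station_id is None or o.station_id == station_id]
    else:
        q = _PREFIXES + """
        SELECT ?sid ?d ?prop ?val WHERE {
          ?o rdf:type aemet:Observation ; aemet:observedAt ?st ;
             aemet:observedProperty ?prop ; aemet:observationDate ?d ;
             aemet:value ?val .
          ?st dct:identifier ?sid .
        }"""
        from rdflib import URIRef
        obs = []
        for r in sparql_select(_query_target(source), q):
            sid = str(r["sid"])
            if station_id is not None and sid != station_id:
                continue
            obs.append(WeatherObservation(
                sid, r["d"], weather_variable_for_term(URIRef(r["prop"])),
                float(r["val"])))
    return sorted(obs, key=lambda o: (o.station_id, o.date.isoformat(), o.variable))


def _squared_degree_distance(summary: StudySummary, st: WeatherStation) -> float:
    if summary.latitude is None or summary.longitude is None \
            or st.latitude is None or st.longitude is None:
        return math.inf
    return (summary.latitude - st.latitude) ** 2 + \
        (summary.longitude - st.longitude) ** 2


def _haversine_km(summary: StudySummary, st: WeatherStation) -> float:
    if summary.latitude is None or st.latitude is None:
        return math.inf
    r = 6371.0
    p1, p2 = math.radians(summary.latitude), math.radians(st.latitude)
    dp = p2 - p1
    dl = math.radians(st.longitude - summary.longitude)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def station_distance_table(
    summaries: Sequence[StudySummary],
    stations: Sequence[WeatherStation],
    *,
    metric: str = "squared_degrees",
) -> list[tuple[str, str, float]]:
    """All (study, station, distance) pairs, sorted ascending by distance
    within each study — the full table behind the matching decision."""
    dist = _squared_degree_distance if metric == "squared_degrees" else _haversine_km
    rows = [(su.study_id, st.id, dist(su, st))
            for su in summaries for st in stations]
    rows.sort(key=lambda r: (r[0], r[2], r[1]))
    return rows


def match_weather_stations(
    summaries: Sequence[StudySummary],
    stations: Sequence[WeatherStation],
    *,
    metric: str = "squared_degrees",
) -> list[StationMatch]:
    """Per study, the station minimizing the coordinate distance; ties break
    lexicographically on station id."""
    if not stations:
        raise PhenofairError("no weather stations to match against")
    table = station_distance_table(summaries, stations, metric=metric)
    best: dict[str, tuple[str, float]] = {}
    for study_id, station_id, d in table:  # already sorted: first wins
        best.setdefault(study_id, (station_id, d))
    return [StationMatch(sid, best[sid][0], best[sid][1])
            for sid in sorted(best)]


# ---------------------------------------------------------------------------
# milestone e: trait aggregation


def _aggregate_trait(
    rows: Iterable[tuple[str, str, str, Optional[date], float]],
    variable_id: str,
    repeated: str,
) -> TraitSummary:
    """rows: (study_id, genotype, unit-key-or-genotype-level-flag, date, value).

    The unit key is "" for genotype-level (pre-averaged) records.  Repeated
    dated measures of one unit collapse per the ``repeated`` policy before
    the per-genotype mean.
    """
    if repeated not in ("last", "first", "mean"):
        raise PhenofairError(f"repeated policy must be last/first/mean, "
                             f"got {repeated!r}")
    # collapse repeated measures per unit
    per_unit: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    genotype_level: dict[tuple[str, str], list[float]] = {}
    for study_id, genotype, unit_key, d, value in rows:
        if unit_key == "":
            genotype_level.setdefault((genotype, study_id), []).append(value)
            continue
        dkey = d.isoformat() if d else ""
        per_unit.setdefault((study_id, genotype, unit_key), []).append((dkey, value))

    per_cell: dict[tuple[str, str], list[float]] = {}
    for (study_id, genotype, _unit), dated in per_unit.items():
        dated.sort(key=lambda t: t[0])
        if repeated == "last":
            v = dated[-1][1]
        elif repeated == "first":
            v = dated[0][1]
        else:
            v = sum(x for _, x in dated) / len(dated)
        per_cell.setdefault((genotype, study_id), []).append(v)

    summary = TraitSummary(variable_id=variable_id)
    for cell, values in per_cell.items():
        summary.cells[cell] = sum(values) / len(values)
        summary.counts[cell] = len(values)
    for cell, values in genotype_level.items():
        # pre-averaged records pass through; plants-averaged count unknown
        summary.cells[cell] = sum(values) / len(values)
        summary.counts[cell] = 0
    return summary


def genotype_trait_means(
    source: PhenoSource,
    variable_id: str,
    study_ids: Optional[Sequence[str]] = None,
    *,
    repeated: str = "last",
) -> TraitSummary:
    """Mean trait value per (genotype, study), averaged over that genotype's
    units (plants/plots) in the study.

    A unit measured on several dates contributes one value per the
    ``repeated`` policy (default: its last dated record).  Genotype-level
    units (pre-averaged deposits) pass their value through directly, with
    the contributing plant count recorded as unknown.  An undeclared
    variable id fails naming it.
    """
    if isinstance(source, PhenoModelSource):
        inv = source.investigation
        if variable_id not in inv.variable_ids():
            raise PhenofairError(f"undeclared observed variable: {variable_id!r}")
        wanted = set(study_ids) if study_ids is not None else None
        units: dict[str, tuple[str, str, str]] = {}  # unit -> (study, geno, level)
        for s in inv.studies:
            for u in s.observation_units:
                units[u.id] = (s.id, u.biological_material_id, u.level)
        rows = []
        for r in source.records:
            if r.variable_id != variable_id or not isinstance(r.value, float):
                continue
            info = units.get(r.observation_unit_id)
            if info is None:
                continue
            study_id, genotype, level = info
            if wanted is not None and study_id not in wanted:
                continue
            unit_key = "" if level == "genotype" else r.observation_unit_id
            rows.append((study_id, genotype, unit_key, r.date, r.value))
        return _aggregate_trait(rows, variable_id, repeated)

    target = _query_target(source)
    declared = sparql_select(target, _PREFIXES + f"""
        SELECT ?v WHERE {{
          ?v rdf:type ppeo:ObservedVariable ;
             dct:identifier "{variable_id}" }}""")
    if not declared:
        raise PhenofairError(f"undeclared observed variable: {variable_id!r}")

    q = _PREFIXES + f"""
    SELECT ?sid ?geno ?unit ?level ?d ?val WHERE {{
      ?s rdf:type ppeo:Study ; dct:identifier ?sid ;
         ppeo:hasObservationUnit ?u .
      ?u dct:identifier ?unit ; ppeo:observationLevel ?level ;
         ppeo:hasBiologicalMaterial ?m .
      ?m dct:identifier ?geno .
      ?o ppeo:onObservationUnit ?u ; ppeo:ofVariable ?v ;
         ppeo:hasValue ?val .
      ?v dct:identifier "{variable_id}" .
      OPTIONAL {{ ?o ppeo:observationDate ?d }}
    }}"""
    wanted = set(study_ids) if study_ids is not None else None
    rows = []
    for r in sparql_select(target, q):
        if not isinstance(r["val"], float):
            continue  # categorical token: not averageable
        study_id = str(r["sid"])
        if wanted is not None and study_id not in wanted:
            continue
        unit_key = "" if str(r["level"]) == "genotype" else str(r["unit"])
        rows.append((study_id, str(r["geno"]), unit_key, r.get("d"), r["val"]))
    return _aggregate_trait(rows, variable_id, repeated)


# ---------------------------------------------------------------------------
# milestone f: PBTT and stability


def pbtt_per_study(
    pheno_source: PhenoSource,
    weather_source: WeatherSource,
    params: PbttParams = PbttParams(),
    *,
    matches: Optional[Sequence[StationMatch]] = None,
    on_missing: str = "error",
) -> dict[str, float]:
    """Cumulative PBTT of each study's window at its matched station.

    A study without an end date accumulates up to the matched station's
    last reading (the trial treated as still open).
    """
    summaries = summarize_studies(pheno_source)
    if matches is None:
        matches = match_weather_stations(summaries,
                                         weather_stations(weather_source))
    match_by_study = {m.study_id: m.station_id for m in matches}
    out: dict[str, float] = {}
    for su in summaries:
        if not isinstance(su.start_date, date):
            raise PhenofairError(
                f"study {su.study_id!r} has no full start date; cannot window PBTT")
        station = match_by_study[su.study_id]
        series = weather_series(weather_source, station)
        if isinstance(su.end_date, date):
            end = su.end_date
        else:
            dates = [o.date for o in series]
            if not dates:
                raise PhenofairError(f"station {station!r} has no readings")
            end = max(dates)
        out[su.study_id] = cumulative_pbtt(series, station, su.start_date, end,
                                           params, on_missing=on_missing)
    return out


def stability_lines(
    summary: TraitSummary,
    pbtt_by_study: dict[str, float],
    genotypes: Optional[Sequence[str]] = None,
) -> StabilityResult:
    """Per genotype, pair the min and max cell value with the PBTT of the
    study each occurred in, and classify the line direction.

    Ties (several studies sharing the extreme value) resolve to the
    lexicographically smallest study id, making the output deterministic.
    Genotypes listed in ``genotypes`` but absent from the table are
    excluded and reported.
    """
    for s in summary.studies():
        if s not in pbtt_by_study:
            raise PhenofairError(f"no PBTT value for study {s!r}")
    by_geno: dict[str, list[tuple[str, float]]] = {}
    for (g, s), v in summary.cells.items():
        by_geno.setdefault(g, []).append((s, v))

    lines = []
    for g in sorted(by_geno):
        cells = by_geno[g]
        v_min = min(v for _, v in cells)
        v_max = max(v for _, v in cells)
        s_min = min(s for s, v in cells if v == v_min)
        s_max = min(s for s, v in cells if v == v_max)
        p_min, p_max = pbtt_by_study[s_min], pbtt_by_study[s_max]
        if len(cells) == 1 or v_min == v_max or p_min == p_max:
            direction = "flat"
        elif p_max > p_min:
            direction = "rising"
        else:
            direction = "falling"
        lines.append(StabilityLine(g, p_min, v_min, p_max, v_max, direction))

    excluded = sorted(set(genotypes or ()) - set(by_geno))
    return StabilityResult(lines=lines, excluded=excluded)


# ---------------------------------------------------------------------------
# federation


def federated_fetch(
    pheno_source: PhenoSource,
    weather_source: WeatherSource,
    request: str,
) -> list[dict]:
    """Cross-source joins the milestones need, identical whether each source
    is a local graph or a live endpoint.

    Requests:
      - ``station_matching``: every (study, station) pair with its squared
        coordinate distance, ascending within each study.
      - ``weather_coverage``: per study, its matched station and how many
        window days carry temperature / photoperiod readings.
    """
    if request == "station_matching":
        summaries = summarize_studies(pheno_source)
        stations = weather_stations(weather_source)
        return [{"study_id": a, "station_id": b, "squared_distance": d}
                for a, b, d in station_distance_table(summaries, stations)]
    if request == "weather_coverage":
        summaries = summarize_studies(pheno_source)
        matches = match_weather_stations(summaries,
                                         weather_stations(weather_source))
        by_study = {m.study_id: m.station_id for m in matches}
        out = []
        for su in summaries:
            station = by_study[su.study_id]
            series = weather_series(weather_source, station)
            start = su.start_date if isinstance(su.start_date, date) else None
            end = su.end_date if isinstance(su.end_date, date) else None
            n_t = n_p = n_days = 0
            if start is not None:
                last = end or max((o.date for o in series), default=start)
                n_days = (last - start).days + 1
                in_window = [o for o in series if start <= o.date <= last]
                n_t = sum(o.variable == "daily_mean_temperature_C" for o in in_window)
                n_p = sum(o.variable == "photoperiod_hours" for o in in_window)
            out.append({"study_id": su.study_id, "station_id": station,
                        "n_days_window": float(n_days),
                        "n_days_temperature": float(n_t),
                        "n_days_photoperiod": float(n_p)})
        return out
    raise PhenofairError(f"unknown federated request {request!r}")
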