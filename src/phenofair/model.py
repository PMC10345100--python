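"""Typed in-memory model of a MIAPPE 1.1 investigation and its data.

The model mirrors the MIAPPE checklist sections used in multi-environment
field trials: an Investigation owning Studies, Persons, DataFileLinks,
BiologicalMaterials and ObservedVariables; Studies owning environment
parameters, experimental factors, dated Events and ObservationUnits.
Measurements live outside the metadata tree as sparse ObservationRecords
(one record per observed cell), and daily weather readings as
WeatherObservations attached to WeatherStations.

Objects are plain dataclasses and may be constructed in any state;
consistency is checked by :func:`validate_investigation`, which reports
every violation instead of raising, so that a partially broken deposit can
be diagnosed in one pass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Union

__all__ = [
    "PhenofairError",
    "UnknownIdentifier",
    "ValidationFailed",
    "Person",
    "DataFileLink",
    "BiologicalMaterial",
    "EnvironmentParameter",
    "ExperimentalFactor",
    "Event",
    "ObservationUnit",
    "ObservedVariable",
    "Study",
    "Investigation",
    "ObservationRecord",
    "WeatherStation",
    "WeatherObservation",
    "ValidationIssue",
    "ValidationReport",
    "OBSERVATION_LEVELS",
    "WEATHER_VARIABLES",
    "parse_flexible_date",
    "canonicalize",
    "validate_investigation",
    "common_genotype_ids",
    "genotype_of_unit",
]


class PhenofairError(Exception):
    """Base class for errors raised by this package."""


class UnknownIdentifier(PhenofairError):
    """An identifier does not resolve against the investigation."""


class ValidationFailed(PhenofairError):
    """An operation requiring a clean investigation received a dirty one."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(f"{c}:{o}" for c, o, _ in report.errors[:5])
        more = "" if len(report.errors) <= 5 else f" (+{len(report.errors) - 5} more)"
        super().__init__(f"investigation has validation errors: {lines}{more}")


# Observation levels, coarsest to finest; "genotype" marks pre-averaged
# records and takes part in no nesting.
OBSERVATION_LEVELS = ("block", "plot", "plant", "genotype")
_NESTING_RANK = {"block": 0, "plot": 1, "plant": 2}

WEATHER_VARIABLES = ("daily_mean_temperature_C", "photoperiod_hours")

# A metadata date is a full calendar date, or a year / year-month string for
# under-documented trials (accepted with a warning), or absent.
FlexibleDate = Union[date, str, None]
_PARTIAL_DATE_RE = re.compile(r"^\d{4}(-\d{2})?$")


def parse_flexible_date(text: str) -> FlexibleDate:
    """Parse an ISO-8601 date, keeping year / year-month strings verbatim.

    Returns ``None`` for an empty string. Raises ``ValueError`` for anything
    that is neither a full ISO date nor a partial one.
    """
    text = text.strip()
    if not text:
        return None
    if _PARTIAL_DATE_RE.match(text):
        return text
    return date.fromisoformat(text)


@dataclass(frozen=True)
class Person:
    name: str
    email: str = ""
    affiliation: str = ""
    role: str = ""


@dataclass(frozen=True)
class DataFileLink:
    path_or_url: str
    description: str = ""
    study_id: str = ""


@dataclass(frozen=True)
class BiologicalMaterial:
    """A genotype/accession; ``material_source`` names the originating cross
    (e.g. the CxE backcross population) or is empty for external cultivars."""

    id: str
    genus_species: str = ""
    material_source: str = ""
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnvironmentParameter:
    name: str
    value: str = ""
    unit: str = ""


@dataclass(frozen=True)
class ExperimentalFactor:
    """An un-timed experimental circumstance (e.g. a fertilizer amount with
    no recorded application date, which cannot be an Event)."""

    factor_type: str
    description: str = ""
    values: tuple[str, ...] = ()


@dataclass(frozen=True)
class Event:
    """A dated management action (planting, fungicide, water treatment).

    The date is mandatory in MIAPPE; a date-less event is a validation
    error, never silently accepted.
    """

    event_type: str
    description: str = ""
    date: Optional[date] = None


@dataclass(frozen=True)
class ObservationUnit:
    id: str
    level: str
    biological_material_id: str
    study_id: str
    parent_unit_id: str = ""


@dataclass(frozen=True)
class ObservedVariable:
    """Trait + method + scale with a stable id — the sole join key between
    data files and metadata. ``categories`` declares the legal tokens for a
    categorical scale (empty means numeric/unrestricted)."""

    id: str
    name: str = ""
    trait: str = ""
    method: str = ""
    scale: str = ""
    unit: str = ""
    categories: tuple[str, ...] = ()


@dataclass(frozen=True)
class Study:
    id: str
    title: str = ""
    start_date: FlexibleDate = None
    end_date: FlexibleDate = None
    country_code: str = ""
    location_name: str = ""
    location_address: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    altitude: Optional[float] = None
    design_description: str = ""
    environment_parameters: tuple[EnvironmentParameter, ...] = ()
    events: tuple[Event, ...] = ()
    experimental_factors: tuple[ExperimentalFactor, ...] = ()
    observation_units: tuple[ObservationUnit, ...] = ()


@dataclass(frozen=True)
class Investigation:
    id: str
    title: str = ""
    description: str = ""
    miappe_version: str = "1.1"
    license: str = ""
    publications: tuple[str, ...] = ()
    studies: tuple[Study, ...] = ()
    persons: tuple[Person, ...] = ()
    data_files: tuple[DataFileLink, ...] = ()
    biological_materials: tuple[BiologicalMaterial, ...] = ()
    observed_variables: tuple[ObservedVariable, ...] = ()

    # -- resolution helpers -------------------------------------------------

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.id == study_id:
                return s
        raise UnknownIdentifier(f"unknown study id: {study_id!r}")

    def unit(self, unit_id: str) -> ObservationUnit:
        for s in self.studies:
            for u in s.observation_units:
                if u.id == unit_id:
                    return u
        raise UnknownIdentifier(f"unknown observation unit id: {unit_id!r}")

    def variable_ids(self) -> set[str]:
        return {v.id for v in self.observed_variables}

    def material_ids(self) -> set[str]:
        return {m.id for m in self.biological_materials}

    def synonym_map(self) -> dict[str, str]:
        """Map every synonym (and every canonical id) to its canonical
        material id, emulating the genotype-name translation files that
        accompanied the Finnish trials."""
        table: dict[str, str] = {}
        for m in self.biological_materials:
            table[m.id] = m.id
            for syn in m.synonyms:
                table.setdefault(syn, m.id)
        return table


@dataclass(frozen=True)
class ObservationRecord:
    """One measured cell: (observation unit, optional date, variable, value).

    Missing cells in the sparse data files produce no record at all.
    """

    observation_unit_id: str
    variable_id: str
    value: Union[float, str]
    date: Optional[date] = None


@dataclass(frozen=True)
class WeatherStation:
    id: str
    name: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None


@dataclass(frozen=True)
class WeatherObservation:
    station_id: str
    date: date
    variable: str  # one of WEATHER_VARIABLES
    value: float


ValidationIssue = tuple[str, str, str]  # (code, object_id, message)


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error_codes(self) -> set[str]:
        return {c for c, _, _ in self.errors}

    def warning_codes(self) -> set[str]:
        return {c for c, _, _ in self.warnings}

    def _sort(self) -> None:
        self.errors.sort()
        self.warnings.sort()

    def __str__(self) -> str:  # human-readable summary for CLI output
        out = []
        for code, oid, msg in self.errors:
            out.append(f"ERROR   {code:24s} {oid}: {msg}")
        for code, oid, msg in self.warnings:
            out.append(f"WARNING {code:24s} {oid}: {msg}")
        return "\n".join(out) if out else "no problems found"


def _check_date(value: FlexibleDate, owner: str, what: str, report: ValidationReport) -> None:
    if isinstance(value, str):
        if _PARTIAL_DATE_RE.match(value):
            report.warnings.append(
                ("DATE_PARTIAL", owner, f"{what} is a partial date: {value!r}")
            )
        else:
            report.errors.append(
                ("DATE_UNPARSEABLE", owner, f"{what} is not ISO 8601: {value!r}")
            )


def validate_investigation(
    inv: Investigation,
    records: Iterable[ObservationRecord] = (),
    *,
    strict_categories: bool = True,
) -> ValidationReport:
    """Check every model invariant and cross-reference, returning a report.

    Nothing is raised: all problems are collected, ordered deterministically
    by (code, object id, message). ``strict_categories=False`` downgrades
    undeclared categorical tokens (stray symbols outside a declared scale)
    from errors to warnings, for deposits assembled by many hands.
    """
    report = ValidationReport()
    err, warn = report.errors.append, report.warnings.append

    if not inv.id:
        err(("INV_ID_MISSING", "", "investigation id is empty"))
    if not inv.miappe_version:
        err(("INV_VERSION_MISSING", inv.id, "miappe_version is mandatory"))

    for p in inv.persons:
        if not p.name:
            err(("PERSON_NAME_MISSING", p.email or p.affiliation, "person has no name"))

    seen_mat: set[str] = set()
    for m in inv.biological_materials:
        if not m.id:
            err(("MAT_ID_MISSING", "", "biological material with empty id"))
        elif m.id in seen_mat:
            err(("MAT_ID_DUP", m.id, "duplicate biological material id"))
        seen_mat.add(m.id)

    seen_var: set[str] = set()
    for v in inv.observed_variables:
        if not v.id:
            err(("VAR_ID_MISSING", "", "observed variable with empty id"))
        elif v.id in seen_var:
            err(("VAR_ID_DUP", v.id, "duplicate observed variable id"))
        seen_var.add(v.id)

    study_ids: set[str] = set()
    unit_index: dict[str, ObservationUnit] = {}
    for s in inv.studies:
        if not s.id:
            err(("STUDY_ID_MISSING", "", "study with empty id"))
        elif s.id in study_ids:
            err(("STUDY_ID_DUP", s.id, "duplicate study id"))
        study_ids.add(s.id)

        _check_date(s.start_date, s.id, "start_date", report)
        _check_date(s.end_date, s.id, "end_date", report)
        if isinstance(s.start_date, date) and isinstance(s.end_date, date):
            if s.start_date > s.end_date:
                err(("STUDY_DATES_ORDER", s.id,
                     f"start_date {s.start_date} after end_date {s.end_date}"))
        if s.latitude is not None and not -90.0 <= s.latitude <= 90.0:
            err(("STUDY_LAT_RANGE", s.id, f"latitude {s.latitude} outside [-90, 90]"))
        if s.longitude is not None and not -180.0 <= s.longitude <= 180.0:
            err(("STUDY_LON_RANGE", s.id, f"longitude {s.longitude} outside [-180, 180]"))

        for e in s.events:
            if e.date is None:
                err(("EVT_DATE_MISSING", s.id,
                     f"event {e.event_type!r} has no date; un-dated occurrences "
                     "belong in experimental factors"))

        seen_units_here: set[str] = set()
        for u in s.observation_units:
            if not u.id:
                err(("UNIT_ID_MISSING", s.id, "observation unit with empty id"))
                continue
            if u.id in seen_units_here:
                err(("UNIT_ID_DUP", u.id, f"duplicate unit id within study {s.id}"))
            seen_units_here.add(u.id)
            if u.id in unit_index:
                err(("UNIT_ID_DUP", u.id, "unit id reused across studies"))
            unit_index[u.id] = u
            if u.level not in OBSERVATION_LEVELS:
                err(("UNIT_LEVEL_UNKNOWN", u.id,
                     f"level {u.level!r} not in {OBSERVATION_LEVELS}"))
            if u.biological_material_id not in seen_mat:
                err(("UNIT_MAT_UNKNOWN", u.id,
                     f"biological material {u.biological_material_id!r} not declared"))
            if u.study_id != s.id:
                err(("UNIT_STUDY_MISMATCH", u.id,
                     f"unit carries study_id {u.study_id!r} but sits in study {s.id!r}"))

        # parent nesting (second pass so order inside the tuple is irrelevant)
        by_id = {u.id: u for u in s.observation_units}
        for u in s.observation_units:
            if not u.parent_unit_id:
                continue
            parent = by_id.get(u.parent_unit_id)
            if parent is None:
                err(("UNIT_PARENT_UNKNOWN", u.id,
                     f"parent unit {u.parent_unit_id!r} not found in study {s.id}"))
            else:
                cr, pr = _NESTING_RANK.get(u.level), _NESTING_RANK.get(parent.level)
                if cr is None or pr is None or pr >= cr:
                    err(("UNIT_PARENT_LEVEL", u.id,
                         f"parent {parent.id!r} level {parent.level!r} is not coarser "
                         f"than {u.level!r}"))

    for f in inv.data_files:
        if f.study_id and f.study_id not in study_ids:
            err(("DF_STUDY_UNKNOWN", f.path_or_url,
                 f"data file references unknown study {f.study_id!r}"))

    categories = {v.id: set(v.categories) for v in inv.observed_variables if v.categories}
    for r in records:
        if r.observation_unit_id not in unit_index:
            err(("REC_UNIT_UNKNOWN", r.observation_unit_id,
                 "record references an undeclared observation unit"))
        if r.variable_id not in seen_var:
            err(("REC_VAR_UNKNOWN", r.variable_id,
                 "record references an undeclared observed variable"))
        elif r.variable_id in categories and isinstance(r.value, str):
            if r.value not in categories[r.variable_id]:
                issue = ("REC_TOKEN_UNDECLARED", r.variable_id,
                         f"token {r.value!r} outside the declared scale categories")
                (err if strict_categories else warn)(issue)

    report._sort()
    return report


def canonicalize(inv: Investigation) -> Investigation:
    """Return an equal investigation with every collection in canonical
    (sorted) order — the order the deterministic writers emit.

    Two investigations describing the same deposit compare equal after
    canonicalization regardless of the order their sections were assembled
    in.
    """
    from dataclasses import replace

    def _dkey(d: FlexibleDate) -> str:
        return d.isoformat() if isinstance(d, date) else (d or "")

    studies = tuple(
        replace(
            s,
            environment_parameters=tuple(sorted(s.environment_parameters,
                                                key=lambda p: (p.name, p.value, p.unit))),
            events=tuple(sorted(s.events,
                                key=lambda e: (_dkey(e.date) if e.date else "",
                                               e.event_type, e.description))),
            experimental_factors=tuple(
                replace(f, values=tuple(sorted(f.values)))
                for f in sorted(s.experimental_factors,
                                key=lambda f: (f.factor_type, f.description))),
            observation_units=tuple(sorted(s.observation_units, key=lambda u: u.id)),
        )
        for s in sorted(inv.studies, key=lambda s: s.id)
    )
    return replace(
        inv,
        studies=studies,
        persons=tuple(sorted(inv.persons, key=lambda p: (p.name, p.email))),
        data_files=tuple(sorted(inv.data_files, key=lambda f: (f.study_id, f.path_or_url))),
        biological_materials=tuple(
            replace(m, synonyms=tuple(sorted(m.synonyms)))
            for m in sorted(inv.biological_materials, key=lambda m: m.id)),
        observed_variables=tuple(
            replace(v, categories=tuple(sorted(v.categories)))
            for v in sorted(inv.observed_variables, key=lambda v: v.id)),
        publications=tuple(sorted(inv.publications)),
    )


def common_genotype_ids(inv: Investigation, study_ids: Iterable[str]) -> list[str]:
    """Genotype ids present (via observation units) in *every* named study.

    The genotype of a unit is its biological material id; the result is the
    intersection of per-study genotype sets, sorted lexicographically.
    """
    sets = []
    for sid in study_ids:
        s = inv.study(sid)  # raises UnknownIdentifier for a bad id
        sets.append({u.biological_material_id for u in s.observation_units})
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)


def genotype_of_unit(inv: Investigation, unit_id: str) -> str:
    """The biological material id of a unit; for genotype-level units this
    is the identity mapping onto the pre-averaged genotype."""
    return inv.unit(unit_id).biological_material_id
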