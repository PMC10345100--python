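"""Readers and writers for the MIAPPE spreadsheet layout and the sparse
tab-delimited observation and weather tables.

The workbook layout uses one tab per MIAPPE section (eleven sections).  A
workbook may be a single ``.xlsx`` file or a directory of per-section TSV
files; both forms carry identical content and round-trip losslessly.

Observation tables follow the convention of one column for the observation
unit id, one for the measurement date, then one column per observed-variable
id.  Empty cells mean "not measured" and produce no record, so time-series
files are naturally sparse.  Weather tables hold one row per (station, day)
with daily mean temperature and photoperiod columns.

All files are UTF-8, tab-separated where tabular-text, decimal point only.
"""

from __future__ import annotations

import csv
import os
from dataclasses import replace
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import openpyxl

from .model import (
    BiologicalMaterial,
    DataFileLink,
    EnvironmentParameter,
    Event,
    ExperimentalFactor,
    Investigation,
    ObservationRecord,
    ObservationUnit,
    ObservedVariable,
    Person,
    PhenofairError,
    Study,
    ValidationFailed,
    ValidationReport,
    WeatherObservation,
    WeatherStation,
    canonicalize,
    parse_flexible_date,
    validate_investigation,
)

__all__ = [
    "SECTION_NAMES",
    "read_miappe_workbook",
    "write_miappe_workbook",
    "read_observation_table",
    "write_observation_table",
    "read_weather_table",
    "write_weather_table",
]

# The eleven MIAPPE 1.1 sections, in checklist order.
SECTION_NAMES = (
    "Investigation",
    "Study",
    "Person",
    "Data file",
    "Biological material",
    "Environment",
    "Experimental factor",
    "Event",
    "Observation unit",
    "Sample",
    "Observed variable",
)

_LIST_SEP = "|"  # separator for list-valued cells (publications, synonyms, ...)

_HEADERS: dict[str, tuple[str, ...]] = {
    "Investigation": ("id", "title", "description", "miappe_version",
                      "license", "publications"),
    "Study": ("id", "title", "start_date", "end_date", "country_code",
              "location_name", "location_address", "latitude", "longitude",
              "altitude", "design_description"),
    "Person": ("name", "email", "affiliation", "role"),
    "Data file": ("path_or_url", "description", "study_id"),
    "Biological material": ("id", "genus_species", "material_source", "synonyms"),
    "Environment": ("study_id", "name", "value", "unit"),
    "Experimental factor": ("study_id", "factor_type", "description", "values"),
    "Event": ("study_id", "event_type", "description", "date"),
    "Observation unit": ("id", "study_id", "level", "biological_material_id",
                         "parent_unit_id"),
    "Sample": ("id",),  # placeholder section: trials here carried no samples
    "Observed variable": ("id", "name", "trait", "method", "scale", "unit",
                          "categories"),
}


def _fmt_date(d) -> str:
    if d is None:
        return ""
    return d.isoformat() if isinstance(d, date) else str(d)


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(t for t in (cell or "").split(_LIST_SEP) if t)


def _join_list(items: Sequence[str]) -> str:
    return _LIST_SEP.join(items)


# ---------------------------------------------------------------------------
# section grids <-> model


def _investigation_rows(inv: Investigation) -> list[list[str]]:
    return [[inv.id, inv.title, inv.description, inv.miappe_version,
             inv.license, _join_list(inv.publications)]]


def _section_grids(inv: Investigation) -> dict[str, list[list[str]]]:
    inv = canonicalize(inv)
    g: dict[str, list[list[str]]] = {name: [] for name in SECTION_NAMES}
    g["Investigation"] = _investigation_rows(inv)
    for s in inv.studies:
        g["Study"].append([s.id, s.title, _fmt_date(s.start_date),
                           _fmt_date(s.end_date), s.country_code,
                           s.location_name, s.location_address,
                           _fmt_num(s.latitude), _fmt_num(s.longitude),
                           _fmt_num(s.altitude), s.design_description])
        for p in s.environment_parameters:
            g["Environment"].append([s.id, p.name, p.value, p.unit])
        for f in s.experimental_factors:
            g["Experimental factor"].append([s.id, f.factor_type, f.description,
                                             _join_list(f.values)])
        for e in s.events:
            g["Event"].append([s.id, e.event_type, e.description, _fmt_date(e.date)])
        for u in s.observation_units:
            g["Observation unit"].append([u.id, u.study_id, u.level,
                                          u.biological_material_id,
                                          u.parent_unit_id])
    for p in inv.persons:
        g["Person"].append([p.name, p.email, p.affiliation, p.role])
    for f in inv.data_files:
        g["Data file"].append([f.path_or_url, f.description, f.study_id])
    for m in inv.biological_materials:
        g["Biological material"].append([m.id, m.genus_species, m.material_source,
                                         _join_list(m.synonyms)])
    for v in inv.observed_variables:
        g["Observed variable"].append([v.id, v.name, v.trait, v.method, v.scale,
                                       v.unit, _join_list(v.categories)])
    return g


def _parse_float(cell: str, where: str, report: ValidationReport) -> Optional[float]:
    cell = (cell or "").strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        report.errors.append(("CELL_UNPARSEABLE", where, f"not a number: {cell!r}"))
        return None


def _parse_date_cell(cell: str, where: str, report: ValidationReport):
    try:
        return parse_flexible_date(cell or "")
    except ValueError:
        report.errors.append(("CELL_UNPARSEABLE", where, f"not a date: {cell!r}"))
        return None


def _grids_to_investigation(
    grids: dict[str, list[list[str]]], report: ValidationReport
) -> Investigation:
    def rows(section: str) -> list[dict[str, str]]:
        width = len(_HEADERS[section])
        out = []
        for raw in grids.get(section, []):
            cells = list(raw) + [""] * (width - len(raw))
            out.append(dict(zip(_HEADERS[section], cells)))
        return out

    inv_rows = rows("Investigation")
    if not inv_rows:
        raise PhenofairError("workbook has no Investigation row")
    r0 = inv_rows[0]

    persons = tuple(Person(r["name"], r["email"], r["affiliation"], r["role"])
                    for r in rows("Person"))
    data_files = tuple(DataFileLink(r["path_or_url"], r["description"], r["study_id"])
                       for r in rows("Data file"))
    materials = tuple(
        BiologicalMaterial(r["id"], r["genus_species"], r["material_source"],
                           _split_list(r["synonyms"]))
        for r in rows("Biological material"))
    variables = tuple(
        ObservedVariable(r["id"], r["name"], r["trait"], r["method"], r["scale"],
                         r["unit"], _split_list(r["categories"]))
        for r in rows("Observed variable"))

    env: dict[str, list[EnvironmentParameter]] = {}
    for r in rows("Environment"):
        env.setdefault(r["study_id"], []).append(
            EnvironmentParameter(r["name"], r["value"], r["unit"]))
    factors: dict[str, list[ExperimentalFactor]] = {}
    for r in rows("Experimental factor"):
        factors.setdefault(r["study_id"], []).append(
            ExperimentalFactor(r["factor_type"], r["description"],
                               _split_list(r["values"])))
    events: dict[str, list[Event]] = {}
    for r in rows("Event"):
        d = _parse_date_cell(r["date"], f"Event/{r['event_type']}", report)
        if isinstance(d, str):  # events need a full calendar date
            report.errors.append(("CELL_UNPARSEABLE", f"Event/{r['event_type']}",
                                  f"event date must be a full date: {d!r}"))
            d = None
        events.setdefault(r["study_id"], []).append(
            Event(r["event_type"], r["description"], d))
    units: dict[str, list[ObservationUnit]] = {}
    for r in rows("Observation unit"):
        units.setdefault(r["study_id"], []).append(
            ObservationUnit(r["id"], r["level"], r["biological_material_id"],
                            r["study_id"], r["parent_unit_id"]))

    studies = []
    for r in rows("Study"):
        sid = r["id"]
        studies.append(Study(
            id=sid,
            title=r["title"],
            start_date=_parse_date_cell(r["start_date"], f"Study/{sid}", report),
            end_date=_parse_date_cell(r["end_date"], f"Study/{sid}", report),
            country_code=r["country_code"],
            location_name=r["location_name"],
            location_address=r["location_address"],
            latitude=_parse_float(r["latitude"], f"Study/{sid}", report),
            longitude=_parse_float(r["longitude"], f"Study/{sid}", report),
            altitude=_parse_float(r["altitude"], f"Study/{sid}", report),
            design_description=r["design_description"],
            environment_parameters=tuple(env.get(sid, ())),
            events=tuple(events.get(sid, ())),
            experimental_factors=tuple(factors.get(sid, ())),
            observation_units=tuple(units.get(sid, ())),
        ))

    return Investigation(
        id=r0["id"], title=r0["title"], description=r0["description"],
        miappe_version=r0["miappe_version"], license=r0["license"],
        publications=_split_list(r0["publications"]),
        studies=tuple(studies), persons=persons, data_files=data_files,
        biological_materials=materials, observed_variables=variables,
    )


# ---------------------------------------------------------------------------
# workbook file forms


def _slug(section: str) -> str:
    return section.lower().replace(" ", "_")


_SLUG_TO_SECTION = {_slug(s): s for s in SECTION_NAMES}


def read_miappe_workbook(path: Union[str, Path]) -> tuple[Investigation, ValidationReport]:
    """Read a MIAPPE workbook (``.xlsx`` file or directory of per-section
    ``.tsv`` files) into an :class:`Investigation`.

    A missing Investigation section is a hard failure; any other missing
    section yields a ``SECTION_MISSING`` warning and an empty section (the
    potato deposit itself has an empty Sample tab).  Unknown tabs are
    reported as ``SECTION_UNKNOWN`` warnings, never silently dropped.
    Unparseable cells become report errors.
    """
    path = Path(path)
    report = ValidationReport()
    grids: dict[str, list[list[str]]] = {}

    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.suffix != ".tsv":
                continue
            section = _SLUG_TO_SECTION.get(f.stem)
            if section is None:
                report.warnings.append(("SECTION_UNKNOWN", f.name,
                                        "file does not match a MIAPPE section"))
                continue
            with open(f, newline="", encoding="utf-8") as fh:
                rows = list(csv.reader(fh, delimiter="\t"))
            grids[section] = [list(r) for r in rows[1:]]  # drop header
    elif path.is_file():
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        for name in wb.sheetnames:
            if name not in _HEADERS:
                report.warnings.append(("SECTION_UNKNOWN", name,
                                        "tab does not match a MIAPPE section"))
                continue
            ws = wb[name]
            rows = [["" if c is None else str(c) for c in row]
                    for row in ws.iter_rows(values_only=True)]
            grids[name] = [r for r in rows[1:] if any(cell.strip() for cell in r)]
        wb.close()
    else:
        raise PhenofairError(f"workbook not found: {path}")

    if "Investigation" not in grids:
        raise PhenofairError(f"workbook {path} is missing the Investigation section")
    for section in SECTION_NAMES:
        if section not in grids:
            report.warnings.append(("SECTION_MISSING", section,
                                    "section absent; treated as empty"))

    inv = _grids_to_investigation(grids, report)
    report._sort()
    return inv, report


def write_miappe_workbook(inv: Investigation, path: Union[str, Path]) -> Path:
    """Write all eleven sections with deterministic (sorted) row order.

    Refuses an investigation that does not validate cleanly; the refusal
    carries the validation report.
    """
    report = validate_investigation(inv)
    if not report.ok:
        raise ValidationFailed(report)

    path = Path(path)
    grids = _section_grids(inv)
    if path.suffix == ".xlsx":
        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for section in SECTION_NAMES:
            ws = wb.create_sheet(section)
            ws.append(list(_HEADERS[section]))
            for row in grids[section]:
                ws.append(row)
        path.parent.mkdir(parents=True, exist_ok=True)
        wb.save(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for section in SECTION_NAMES:
            with open(path / f"{_slug(section)}.tsv", "w", newline="",
                      encoding="utf-8") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(_HEADERS[section])
                w.writerows(grids[section])
    return path


# ---------------------------------------------------------------------------
# observation tables


def read_observation_table(
    path: Union[str, Path],
    inv: Investigation,
    *,
    na_tokens: Sequence[str] = ("",),
    on_duplicate: str = "error",
    resolve_synonyms: bool = False,
) -> list[ObservationRecord]:
    """Read a sparse observation table into records, one per non-empty cell.

    Header layout: ``observation_unit_id<TAB>date<TAB><var_id_1>...``.  Cells
    matching ``na_tokens`` yield no record.  A header variable id that the
    investigation does not declare, or a row of the wrong width, is a hard
    error naming the column / line.  Duplicate (unit, date, variable) cells
    with conflicting values are an error unless ``on_duplicate='keep_last'``.
    """
    if on_duplicate not in ("error", "keep_last"):
        raise PhenofairError(f"on_duplicate must be 'error' or 'keep_last', "
                             f"got {on_duplicate!r}")
    declared = inv.variable_ids()
    # cells of a category-declaring (scale-typed) variable stay tokens even
    # when they look numeric (e.g. a 0-7 flowering score)
    categorical = {v.id for v in inv.observed_variables if v.categories}
    syn = inv.synonym_map() if resolve_synonyms else {}
    na = set(na_tokens)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PhenofairError(f"{path}: empty observation table") from None
        if len(header) < 2 or header[0] != "observation_unit_id" or header[1] != "date":
            raise PhenofairError(
                f"{path}: header must start with 'observation_unit_id', 'date'")
        var_ids = header[2:]
        unknown = [v for v in var_ids if v not in declared]
        if unknown:
            raise PhenofairError(
                f"{path}: undeclared observed-variable columns: {', '.join(unknown)}")

        records: list[ObservationRecord] = []
        seen: dict[tuple[str, Optional[date], str], float | str] = {}
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise PhenofairError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            unit_id = row[0].strip()
            if resolve_synonyms:
                unit_id = syn.get(unit_id, unit_id)
            cell_date = row[1].strip()
            d = date.fromisoformat(cell_date) if cell_date else None
            for var_id, cell in zip(var_ids, row[2:]):
                cell = cell.strip()
                if cell in na:
                    continue
                if var_id in categorical:
                    value: float | str = cell
                else:
                    try:
                        value = float(cell)
                    except ValueError:
                        value = cell
                key = (unit_id, d, var_id)
                if key in seen:
                    if seen[key] != value and on_duplicate == "error":
                        raise PhenofairError(
                            f"{path}:{lineno}: conflicting duplicate measurement "
                            f"for unit {unit_id!r}, date {d}, variable {var_id!r}")
                    # keep_last: drop the earlier record
                    records = [r for r in records
                               if (r.observation_unit_id, r.date, r.variable_id) != key]
                seen[key] = value
                records.append(ObservationRecord(unit_id, var_id, value, d))
    return records


def write_observation_table(
    records: Iterable[ObservationRecord],
    path: Union[str, Path],
    *,
    variable_ids: Optional[Sequence[str]] = None,
) -> Path:
    """Write records as a sparse wide table (inverse of the reader).

    Rows are (unit, date) pairs sorted lexicographically; columns are the
    sorted variable ids (or ``variable_ids`` if given, preserving that
    order); unmeasured cells are left empty.
    """
    records = list(records)
    if variable_ids is None:
        variable_ids = sorted({r.variable_id for r in records})
    cells: dict[tuple[str, str], dict[str, str]] = {}
    for r in records:
        dkey = r.date.isoformat() if r.date else ""
        val = repr(r.value) if isinstance(r.value, float) else str(r.value)
        cells.setdefault((r.observation_unit_id, dkey), {})[r.variable_id] = val

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["observation_unit_id", "date", *variable_ids])
        for (unit, dkey) in sorted(cells):
            row_cells = cells[(unit, dkey)]
            w.writerow([unit, dkey, *(row_cells.get(v, "") for v in variable_ids)])
    return path


# ---------------------------------------------------------------------------
# weather tables

_WEATHER_HEADER = ("station_id", "station_name", "latitude", "longitude",
                   "date", "daily_mean_temperature_C", "photoperiod_hours")


def read_weather_table(
    path: Union[str, Path],
) -> tuple[list[WeatherStation], list[WeatherObservation]]:
    """Read a daily weather table: one row per (station, day), temperature
    and photoperiod columns; gaps (empty cells) are allowed and preserved.

    Stations are deduplicated by id; conflicting coordinates for one id,
    photoperiod outside [0, 24], and conflicting duplicate (station, date,
    variable) readings are hard errors.
    """
    stations: dict[str, WeatherStation] = {}
    obs: list[WeatherObservation] = []
    seen: dict[tuple[str, date, str], float] = {}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != _WEATHER_HEADER:
            raise PhenofairError(
                f"{path}: weather header must be {list(_WEATHER_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_WEATHER_HEADER):
                raise PhenofairError(
                    f"{path}:{lineno}: expected {len(_WEATHER_HEADER)} fields, "
                    f"got {len(row)}")
            sid, name, lat, lon, dstr, temp, photo = (c.strip() for c in row)
            station = WeatherStation(sid, name, float(lat), float(lon))
            if sid in stations and stations[sid] != station:
                raise PhenofairError(
                    f"{path}:{lineno}: station {sid!r} redefined with "
                    f"different attributes")
            stations[sid] = station
            d = date.fromisoformat(dstr)
            for variable, cell in (("daily_mean_temperature_C", temp),
                                   ("photoperiod_hours", photo)):
                if not cell:
                    continue
                value = float(cell)
                if variable == "photoperiod_hours" and not 0.0 <= value <= 24.0:
                    raise PhenofairError(
                        f"{path}:{lineno}: photoperiod {value} outside [0, 24]")
                key = (sid, d, variable)
                if key in seen and seen[key] != value:
                    raise PhenofairError(
                        f"{path}:{lineno}: conflicting duplicate reading for "
                        f"{key}")
                if key not in seen:
                    obs.append(WeatherObservation(sid, d, variable, value))
                seen[key] = value
    return sorted(stations.values(), key=lambda s: s.id), obs


def write_weather_table(
    stations: Iterable[WeatherStation],
    observations: Iterable[WeatherObservation],
    path: Union[str, Path],
) -> Path:
    """Write stations and observations back to the daily-table form."""
    by_id = {s.id: s for s in stations}
    days: dict[tuple[str, date], dict[str, float]] = {}
    for o in observations:
        if o.station_id not in by_id:
            raise PhenofairError(f"observation references undeclared station "
                                 f"{o.station_id!r}")
        days.setdefault((o.station_id, o.date), {})[o.variable] = o.value

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_WEATHER_HEADER)
        for (sid, d) in sorted(days):
            s = by_id[sid]
            vals = days[(sid, d)]
            temp = vals.get("daily_mean_temperature_C")
            photo = vals.get("photoperiod_hours")
            w.writerow([s.id, s.name, repr(s.latitude), repr(s.longitude),
                        d.isoformat(),
                        "" if temp is None else repr(temp),
                        "" if photo is None else repr(photo)])
    return path
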