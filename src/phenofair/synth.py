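"""Seeded generator of deposit-shaped fixtures with a ground-truth ledger.

The generator emulates the structure of a five-trial multi-environment
potato deposit: partially overlapping genotype subsets drawn from one
mapping population (plus the overlap's complement spread over the trials),
plant/plot/block observation levels with one trial recorded only as
per-genotype averages, a sparse time-series trait file per trial, and one
weather station per trial location.

Everything is a deterministic function of the spec (including its seed):
generating twice yields byte-identical files.  Alongside the files, a
:class:`GroundTruth` ledger records what every downstream milestone should
find — common genotypes, per-cell trait means, station matches, PBTT — each
computed here by independent brute force (plain dict folds and an explicit
per-day loop), so pipeline outputs can be checked against construction.

Default values describe the emulated deposit: 5 trials, 292 genotypes of
which 101 are common to all trials and 80 carry the focal trait everywhere,
the second trial pre-averaged per genotype.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Union

import numpy as np

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
    WeatherObservation,
    WeatherStation,
    canonicalize,
)
from .pbtt import PbttParams
from .tabular import (
    write_miappe_workbook,
    write_observation_table,
    write_weather_table,
)

__all__ = ["FixtureSpec", "StudyShape", "GroundTruth", "Fixture",
           "generate_fixture", "perturb_fixture", "DEFECTS"]

FOCAL_VARIABLE = "tubwtotal"
CATEGORICAL_VARIABLE = "flower07"


@dataclass(frozen=True)
class StudyShape:
    """Location and window of one emulated trial."""

    id: str
    country_code: str
    location_name: str
    latitude: float
    longitude: float
    altitude: float
    start: date
    end: date


# The five emulated trials: northern Europe, tropical highland, two boreal
# seasons, east-African highland — the latitude spread that makes
# photoperiod interesting.
PAPER_STUDY_SHAPES = (
    StudyShape("1999NL", "NL", "Wageningen", 51.97, 5.66, 10.0,
               date(1999, 4, 15), date(1999, 9, 15)),
    StudyShape("2003VE", "VE", "Merida highlands", 8.60, -71.15, 1800.0,
               date(2003, 1, 15), date(2003, 5, 15)),
    StudyShape("2004Fin", "FI", "Jokioinen", 60.81, 23.48, 104.0,
               date(2004, 5, 20), date(2004, 9, 10)),
    StudyShape("2005Fin", "FI", "Ylistaro", 62.94, 22.50, 27.0,
               date(2005, 5, 20), date(2005, 9, 10)),
    StudyShape("2010ET", "ET", "Holetta", 9.06, 38.50, 2400.0,
               date(2010, 6, 15), date(2010, 10, 30)),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a generated deposit; defaults emulate the five-trial case.

    ``overlap_count`` genotypes appear in every study; the rest are split
    round-robin as per-study extras.  ``complete_case_count`` of the common
    genotypes keep a focal-trait value in every study (the others lose the
    trait in exactly one study each).  ``genotype_level_study`` names the
    study recorded only as per-genotype averages.
    """

    seed: int = 0
    n_studies: int = 5
    n_genotypes_total: int = 292
    overlap_count: int = 101
    complete_case_count: Optional[int] = 80
    plants_per_genotype: int = 4
    genotype_level_study: Optional[str] = "2003VE"
    repeated_measure_fraction: float = 0.25
    trait_baseline_mean: float = 40.0   # g tuber weight per plant
    trait_baseline_sd: float = 12.0
    study_effect_sd: float = 15.0
    interaction_sd: float = 8.0
    noise_sd: float = 5.0
    temperature_noise_sd: float = 1.5
    station_jitter_deg: float = 0.05
    pbtt_params: PbttParams = field(default_factory=PbttParams)
    study_shapes: Optional[tuple[StudyShape, ...]] = None

    def shapes(self) -> tuple[StudyShape, ...]:
        if self.study_shapes is not None:
            return self.study_shapes[: self.n_studies]
        if self.n_studies <= len(PAPER_STUDY_SHAPES):
            return PAPER_STUDY_SHAPES[: self.n_studies]
        extra = tuple(
            StudyShape(f"S{i:02d}", "XX", f"site {i}",
                       10.0 + 50.0 * i / max(1, self.n_studies - 1),
                       5.0 + 3.0 * i, 100.0,
                       date(2000, 5, 1), date(2000, 8, 31))
            for i in range(len(PAPER_STUDY_SHAPES), self.n_studies))
        return PAPER_STUDY_SHAPES + extra

    @staticmethod
    def small(seed: int = 0, n_studies: int = 3, n_genotypes_total: int = 12,
              overlap_count: int = 5, plants_per_genotype: int = 2,
              **kw) -> "FixtureSpec":
        """A desk-scale spec for fast property tests."""
        kw.setdefault("complete_case_count", None)
        kw.setdefault("genotype_level_study",
                      "2003VE" if n_studies >= 2 else None)
        kw.setdefault("repeated_measure_fraction", 0.3)
        return FixtureSpec(seed=seed, n_studies=n_studies,
                           n_genotypes_total=n_genotypes_total,
                           overlap_count=overlap_count,
                           plants_per_genotype=plants_per_genotype, **kw)


@dataclass
class GroundTruth:
    """What the pipeline must find, computed independently at build time."""

    common_genotypes: list[str]
    union_genotypes: list[str]          # genotypes with >=1 focal value
    complete_case_genotypes: list[str]  # focal value in every study
    trait_means: dict[tuple[str, str], float]
    station_match: dict[str, str]
    pbtt: dict[str, float]
    unit_to_genotype: dict[str, str]
    genotypes_per_study: dict[str, list[str]]


@dataclass
class Fixture:
    spec: FixtureSpec
    investigation: Investigation
    records: dict[str, list[ObservationRecord]]
    stations: list[WeatherStation]
    weather: list[WeatherObservation]
    truth: GroundTruth
    paths: Optional[dict] = None

    @property
    def all_records(self) -> list[ObservationRecord]:
        return [r for sid in sorted(self.records) for r in self.records[sid]]


# ---------------------------------------------------------------------------
# weather synthesis


def _day_length_hours(latitude: float, d: date) -> float:
    """Astronomical day length from latitude and day of year (sinusoidal
    solar-declination approximation) — a stand-in for a table of published
    photoperiods."""
    doy = d.timetuple().tm_yday
    decl = math.radians(23.44) * math.sin(2 * math.pi * (doy - 81) / 365.25)
    x = -math.tan(math.radians(latitude)) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 24.0 * math.acos(x) / math.pi


def _seasonal_temperature(latitude: float, d: date, rng) -> float:
    doy = d.timetuple().tm_yday
    base = 27.0 - 0.35 * abs(latitude)
    amp = 2.0 + 0.25 * abs(latitude)
    sign = 1.0 if latitude >= 0 else -1.0
    return base + sign * amp * math.sin(2 * math.pi * (doy - 105) / 365.25)


# independent per-day PBTT oracle (deliberately re-derived here, not imported
# from phenofair.pbtt, so the ledger can stand against the implementation)
def _oracle_pbtt(temps: dict[date, float], photos: dict[date, float],
                 start: date, end: date, p: PbttParams) -> float:
    total = 0.0
    d = start
    while d <= end:
        t = temps[d]
        if p.t_base < t < p.t_ceil:
            rise = (t - p.t_base) / (p.t_opt - p.t_base)
            fall = ((p.t_ceil - t) / (p.t_ceil - p.t_opt)) \
                ** ((p.t_ceil - p.t_opt) / (p.t_opt - p.t_base))
            f_t = (rise * fall) ** p.curvature
        else:
            f_t = 0.0
        f_p = 1.0 - p.photoperiod_sensitivity * max(
            0.0, p.critical_photoperiod - photos[d])
        f_p = min(1.0, max(0.0, f_p))
        total += f_p * f_t
        d += timedelta(days=1)
    return total


# ---------------------------------------------------------------------------
# generation


def generate_fixture(
    spec: FixtureSpec,
    out_dir: Optional[Union[str, Path]] = None,
    *,
    workbook_format: str = "dir",
) -> Fixture:
    """Generate metadata, observations, weather, and the ground-truth ledger.

    With ``out_dir`` set, also writes the MIAPPE workbook (TSV directory or
    ``.xlsx`` per ``workbook_format``), one observation TSV per study, and
    the weather TSV; the emitted files validate cleanly and reload to the
    in-memory objects.
    """
    if spec.overlap_count > spec.n_genotypes_total:
        raise PhenofairError(
            f"overlap_count {spec.overlap_count} exceeds total genotypes "
            f"{spec.n_genotypes_total}")
    if spec.n_studies < 1:
        raise PhenofairError("need at least one study")
    if spec.complete_case_count is not None \
            and spec.complete_case_count > spec.overlap_count:
        raise PhenofairError(
            f"complete_case_count {spec.complete_case_count} exceeds "
            f"overlap_count {spec.overlap_count}")

    rng = np.random.default_rng(spec.seed)
    shapes = spec.shapes()
    study_ids = [s.id for s in shapes]
    if spec.genotype_level_study is not None \
            and spec.genotype_level_study not in study_ids:
        raise PhenofairError(
            f"genotype_level_study {spec.genotype_level_study!r} is not one "
            f"of {study_ids}")

    # genotypes: zero-padded CxE clone ids; a stable synonym for a few,
    # emulating genotype-name translation files
    width = len(str(spec.n_genotypes_total))
    genotypes = [f"CE-{i + 1:0{width}d}" for i in range(spec.n_genotypes_total)]
    common = genotypes[: spec.overlap_count]
    extras = genotypes[spec.overlap_count:]
    per_study: dict[str, list[str]] = {sid: list(common) for sid in study_ids}
    if spec.n_studies == 1:
        per_study[study_ids[0]].extend(extras)
    else:
        for i, g in enumerate(extras):
            per_study[study_ids[i % spec.n_studies]].append(g)
    for sid in per_study:
        per_study[sid].sort()

    materials = tuple(
        BiologicalMaterial(
            id=g, genus_species="Solanum tuberosum", material_source="CxE",
            synonyms=(f"syn-{g}",) if i % 37 == 0 else ())
        for i, g in enumerate(genotypes))

    variables = (
        ObservedVariable(FOCAL_VARIABLE, "total tuber weight",
                         "tuber yield", "harvest weighing per plant",
                         "gram scale", "g"),
        ObservedVariable(CATEGORICAL_VARIABLE, "flowering score",
                         "flowering", "visual scoring", "ordinal 0-7", "",
                         tuple(str(i) for i in range(8))),
    )

    # trait model: per-genotype baseline + per-study shift + GxE interaction
    baseline = {g: spec.trait_baseline_mean
                + spec.trait_baseline_sd * rng.standard_normal()
                for g in genotypes}
    study_effect = {sid: spec.study_effect_sd * rng.standard_normal()
                    for sid in study_ids}

    # which common genotypes lose the focal trait in one study (fixing the
    # complete-case count structurally)
    dropped_cells: set[tuple[str, str]] = set()
    if spec.complete_case_count is not None and spec.n_studies > 1:
        to_drop = common[spec.complete_case_count:]  # deterministic choice
        for i, g in enumerate(to_drop):
            dropped_cells.add((g, study_ids[i % spec.n_studies]))

    studies = []
    records: dict[str, list[ObservationRecord]] = {}
    truth_means: dict[tuple[str, str], float] = {}
    unit_to_genotype: dict[str, str] = {}

    for shape in shapes:
        sid = shape.id
        genos = per_study[sid]
        units: list[ObservationUnit] = []
        recs: list[ObservationRecord] = []
        genotype_level = sid == spec.genotype_level_study

        if genotype_level:
            for g in genos:
                uid = f"{sid}_{g}"
                units.append(ObservationUnit(uid, "genotype", g, sid))
                unit_to_genotype[uid] = g
                if (g, sid) in dropped_cells:
                    continue
                value = float(baseline[g] + study_effect[sid]
                              + spec.interaction_sd * rng.standard_normal()
                              + spec.noise_sd * rng.standard_normal()
                              / math.sqrt(max(1, spec.plants_per_genotype)))
                value = round(max(0.0, value), 3)
                recs.append(ObservationRecord(uid, FOCAL_VARIABLE, value,
                                              shape.end))
                truth_means[(g, sid)] = value
        else:
            n_blocks = 2
            block_ids = [f"{sid}_b{k + 1}" for k in range(n_blocks)]
            for b in block_ids:
                units.append(ObservationUnit(b, "block", genos[0], sid))
                unit_to_genotype[b] = genos[0]
            for g in genos:
                interaction = spec.interaction_sd * rng.standard_normal()
                cell_mu = baseline[g] + study_effect[sid] + interaction
                plot_of_block = {}
                for k, b in enumerate(block_ids):
                    pid = f"{sid}_p_{g}_{k + 1}"
                    units.append(ObservationUnit(pid, "plot", g, sid, b))
                    unit_to_genotype[pid] = g
                    plot_of_block[k] = pid
                plant_values = []
                for i in range(spec.plants_per_genotype):
                    uid = f"{sid}_{g}_pl{i + 1}"
                    pid = plot_of_block[i % n_blocks]
                    units.append(ObservationUnit(uid, "plant", g, sid, pid))
                    unit_to_genotype[uid] = g
                    if (g, sid) in dropped_cells:
                        continue
                    value = round(max(0.0, float(
                        cell_mu + spec.noise_sd * rng.standard_normal())), 3)
                    # an optional earlier interim weighing: the harvest
                    # record (later date) is the one that counts
                    if rng.random() < spec.repeated_measure_fraction:
                        interim = round(max(0.0, value
                                            * float(rng.uniform(0.3, 0.8))), 3)
                        recs.append(ObservationRecord(
                            uid, FOCAL_VARIABLE, interim,
                            shape.end - timedelta(days=30)))
                    recs.append(ObservationRecord(uid, FOCAL_VARIABLE, value,
                                                  shape.end))
                    plant_values.append(value)
                    if i % 3 == 0:
                        recs.append(ObservationRecord(
                            uid, CATEGORICAL_VARIABLE,
                            str(int(rng.integers(0, 8))),
                            shape.start + timedelta(days=45)))
                if plant_values:
                    truth_means[(g, sid)] = sum(plant_values) / len(plant_values)

        records[sid] = recs
        studies.append(Study(
            id=sid,
            title=f"{shape.location_name} field trial {shape.start.year}",
            start_date=shape.start, end_date=shape.end,
            country_code=shape.country_code,
            location_name=shape.location_name,
            location_address=f"{shape.location_name}, {shape.country_code}",
            latitude=shape.latitude, longitude=shape.longitude,
            altitude=shape.altitude,
            design_description=("per-genotype averages as communicated"
                                if genotype_level
                                else "randomized blocks, plants within plots"),
            environment_parameters=(
                EnvironmentParameter("type of soil", "sandy loam"),
                EnvironmentParameter("rainfall regime", "rain-fed"),
            ),
            events=(Event("planting", "", shape.start),
                    Event("fungicide application", "",
                          shape.start + timedelta(days=40))),
            experimental_factors=(
                (ExperimentalFactor("fertilizer", "amount known, date not",
                                    ("120 kg N/ha",)),)
                if genotype_level else ()),
            observation_units=tuple(units),
        ))

    inv = canonicalize(Investigation(
        id="cxe-multi-env",
        title="CxE multi-environment potato trials (synthetic emulation)",
        description=("Synthetic deposit emulating five multi-environment "
                     "potato field trials with partially overlapping CxE "
                     "genotype subsets"),
        miappe_version="1.1",
        license="CC-BY-4.0",
        publications=("https://doi.org/10.0000/synthetic",),
        studies=tuple(studies),
        persons=(Person("Data Curator", "curator@example.org",
                        "Example University", "data curator"),
                 Person("Trial Coordinator", "", "Example University",
                        "scientific coordinator")),
        data_files=tuple(DataFileLink(f"obs_{sid}.tsv",
                                      f"observation data for {sid}", sid)
                         for sid in study_ids),
        biological_materials=materials,
        observed_variables=variables,
    ))

    # weather: one station per study location, coordinates jittered
    stations = []
    weather: list[WeatherObservation] = []
    temps_by_station: dict[str, dict[date, float]] = {}
    photos_by_station: dict[str, dict[date, float]] = {}
    for shape in shapes:
        st_id = f"ws_{shape.id}"
        lat = shape.latitude + float(rng.uniform(-spec.station_jitter_deg,
                                                 spec.station_jitter_deg))
        lon = shape.longitude + float(rng.uniform(-spec.station_jitter_deg,
                                                  spec.station_jitter_deg))
        stations.append(WeatherStation(st_id, f"station near {shape.location_name}",
                                       round(lat, 4), round(lon, 4)))
        temps: dict[date, float] = {}
        photos: dict[date, float] = {}
        d = shape.start - timedelta(days=5)
        while d <= shape.end + timedelta(days=5):
            t = _seasonal_temperature(shape.latitude, d, rng) \
                + spec.temperature_noise_sd * float(rng.standard_normal())
            p = _day_length_hours(shape.latitude, d)
            temps[d] = round(t, 2)
            photos[d] = round(p, 2)
            weather.append(WeatherObservation(st_id, d,
                                              "daily_mean_temperature_C",
                                              temps[d]))
            weather.append(WeatherObservation(st_id, d, "photoperiod_hours",
                                              photos[d]))
            d += timedelta(days=1)
        temps_by_station[st_id] = temps
        photos_by_station[st_id] = photos

    # ---- ground truth by brute force --------------------------------------
    common_truth = sorted(set(per_study[study_ids[0]]).intersection(
        *(set(per_study[sid]) for sid in study_ids[1:])))
    union_truth = sorted({g for (g, _sid) in truth_means})
    complete_truth = sorted(
        g for g in union_truth
        if all((g, sid) in truth_means for sid in study_ids))
    station_match = {}
    for shape in shapes:
        dists = sorted((
            (shape.latitude - st.latitude) ** 2
            + (shape.longitude - st.longitude) ** 2, st.id)
            for st in stations)
        station_match[shape.id] = dists[0][1]
    pbtt_truth = {
        shape.id: _oracle_pbtt(temps_by_station[station_match[shape.id]],
                               photos_by_station[station_match[shape.id]],
                               shape.start, shape.end, spec.pbtt_params)
        for shape in shapes}

    truth = GroundTruth(
        common_genotypes=common_truth,
        union_genotypes=union_truth,
        complete_case_genotypes=complete_truth,
        trait_means=truth_means,
        station_match=station_match,
        pbtt=pbtt_truth,
        unit_to_genotype=unit_to_genotype,
        genotypes_per_study={sid: list(per_study[sid]) for sid in study_ids},
    )

    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wb_path = out_dir / ("workbook.xlsx" if workbook_format == "xlsx"
                             else "workbook")
        write_miappe_workbook(inv, wb_path)
        obs_paths = {}
        for sid in study_ids:
            p = out_dir / f"obs_{sid}.tsv"
            write_observation_table(records[sid], p,
                                    variable_ids=[FOCAL_VARIABLE,
                                                  CATEGORICAL_VARIABLE])
            obs_paths[sid] = p
        weather_path = out_dir / "weather.tsv"
        write_weather_table(stations, weather, weather_path)
        paths = {"workbook": wb_path, "observations": obs_paths,
                 "weather": weather_path}

    return Fixture(spec=spec, investigation=inv, records=records,
                   stations=stations, weather=weather, truth=truth,
                   paths=paths)


# ---------------------------------------------------------------------------
# defect injection

DEFECTS = ("dateless_event", "unknown_variable_column", "undeclared_token",
           "conflicting_duplicate", "missing_weather_day")


def perturb_fixture(fixture: Fixture, defect: str,
                    out_dir: Union[str, Path]) -> dict:
    """Copy the fixture's files and inject one named defect, returning a
    description of what was broken (so tests can assert the exact error
    path).  Requires a fixture generated with ``out_dir`` in TSV-directory
    workbook form.
    """
    if defect not in DEFECTS:
        raise PhenofairError(f"unknown defect {defect!r}; choose from {DEFECTS}")
    if fixture.paths is None:
        raise PhenofairError("fixture was generated without files")
    if not Path(fixture.paths["workbook"]).is_dir():
        raise PhenofairError("defect injection needs the TSV-directory "
                             "workbook form")

    out_dir = Path(out_dir)
    if out_dir.exists():
        shutil.rmtree(out_dir)
    shutil.copytree(Path(fixture.paths["workbook"]).parent, out_dir)
    wb = out_dir / Path(fixture.paths["workbook"]).name
    first_study = sorted(fixture.records)[0]
    plant_study = next(sid for sid in sorted(fixture.records)
                       if sid != fixture.spec.genotype_level_study)
    info: dict = {"defect": defect}

    if defect == "dateless_event":
        with open(wb / "event.tsv", "a", encoding="utf-8", newline="") as fh:
            fh.write(f"{first_study}\twater treatment\tundocumented\t\n")
        info["study"] = first_study

    elif defect == "unknown_variable_column":
        p = out_dir / f"obs_{first_study}.tsv"
        lines = p.read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        info["column"] = "mystery01"
        info["path"] = p
        header[-1] = "mystery01"
        lines[0] = "\t".join(header)
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")

    elif defect == "undeclared_token":
        p = out_dir / f"obs_{plant_study}.tsv"
        lines = p.read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        col = header.index(CATEGORICAL_VARIABLE)
        for i, line in enumerate(lines[1:], start=1):
            cells = line.split("\t")
            if len(cells) > col and cells[col].strip():
                cells[col] = "*"
                lines[i] = "\t".join(cells)
                info["unit"] = cells[0]
                break
        info["path"] = p
        info["token"] = "*"
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")

    elif defect == "conflicting_duplicate":
        p = out_dir / f"obs_{plant_study}.tsv"
        lines = p.read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:
            cells = line.split("\t")
            if cells[2].strip():  # a focal-trait cell
                cells[2] = repr(float(cells[2]) + 1.0)
                lines.append("\t".join(cells))
                info["unit"] = cells[0]
                break
        info["path"] = p
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")

    elif defect == "missing_weather_day":
        p = out_dir / "weather.tsv"
        lines = p.read_text(encoding="utf-8").splitlines()
        shape = fixture.spec.shapes()[0]
        station = fixture.truth.station_match[shape.id]
        target = (shape.start + (shape.end - shape.start) / 2).isoformat()
        kept, removed = [], None
        for line in lines:
            cells = line.split("\t")
            if removed is None and cells[0] == station and cells[4:5] == [target]:
                removed = date.fromisoformat(target)
                continue
            kept.append(line)
        if removed is None:
            raise PhenofairError("no mid-window weather row found to remove")
        info["station"] = station
        info["date"] = removed
        info["study"] = shape.id
        info["path"] = p
        p.write_text("\n".join(kept) + "\n", encoding="utf-8")

    info["dir"] = out_dir
    return info
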