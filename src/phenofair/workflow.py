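"""End-to-end milestone workflow with deterministic report output.

Runs the milestone sequence — study summaries, genotype overlap, station
matching, trait aggregation, PBTT, stability lines — over any pheno/weather
source pair and optionally writes the report directory: one TSV per table,
a plain-text log of the counts at each step, and two presentation plots
(all asserted numbers live in the TSVs; the plots are illustrations).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional, Sequence, Union

from .milestones import (
    PhenoSource,
    StabilityResult,
    StationMatch,
    StudySummary,
    TraitSummary,
    WeatherSource,
    genotype_overlap,
    genotype_trait_means,
    match_weather_stations,
    pbtt_per_study,
    stability_lines,
    station_distance_table,
    summarize_studies,
    weather_stations,
)
from .pbtt import PbttParams

__all__ = ["MilestoneReport", "run_milestones"]


@dataclass
class MilestoneReport:
    summaries: list[StudySummary]
    common_genotypes: list[str]
    matches: list[StationMatch]
    trait: TraitSummary
    pbtt: dict[str, float]
    stability: StabilityResult
    log: list[str]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    if isinstance(x, date):
        return x.isoformat()
    return str(x)


def _write_tsv(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(c) for c in row])


def run_milestones(
    pheno_source: PhenoSource,
    weather_source: WeatherSource,
    variable_id: str,
    params: PbttParams = PbttParams(),
    out_dir: Optional[Union[str, Path]] = None,
    *,
    repeated: str = "last",
    on_missing: str = "error",
) -> MilestoneReport:
    """Milestones in order, halting on the first failing stage (the raised
    error names the stage via its message)."""
    log: list[str] = []

    summaries = summarize_studies(pheno_source)
    log.append(f"studies: {len(summaries)} "
               f"({', '.join(s.study_id for s in summaries)})")

    common = genotype_overlap(pheno_source)
    log.append(f"common genotypes across all studies: {len(common)}")

    stations = weather_stations(weather_source)
    matches = match_weather_stations(summaries, stations)
    log.append(f"weather stations: {len(stations)}; matched studies: "
               f"{len(matches)}")

    trait = genotype_trait_means(pheno_source, variable_id, repeated=repeated)
    union = trait.genotypes()
    complete = trait.complete_cases([s.study_id for s in summaries])
    log.append(f"trait {variable_id}: {len(union)} genotypes with values; "
               f"{len(complete)} with a value in every study")

    pbtt = pbtt_per_study(pheno_source, weather_source, params,
                          matches=matches, on_missing=on_missing)
    log.append("cumulative PBTT per study: "
               + ", ".join(f"{k}={v:.2f}" for k, v in sorted(pbtt.items())))

    stability = stability_lines(trait, pbtt, genotypes=union)
    directions = {d: sum(1 for l in stability.lines if l.direction == d)
                  for d in ("rising", "falling", "flat")}
    log.append(f"stability lines: {len(stability.lines)} "
               f"(rising {directions['rising']}, falling "
               f"{directions['falling']}, flat {directions['flat']}); "
               f"excluded {len(stability.excluded)}")

    report = MilestoneReport(summaries=summaries, common_genotypes=common,
                             matches=matches, trait=trait, pbtt=pbtt,
                             stability=stability, log=log)
    if out_dir is not None:
        _write_report(report, Path(out_dir), weather_source, variable_id)
    return report


def _write_report(rep: MilestoneReport, out_dir: Path,
                  weather_source: WeatherSource, variable_id: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    _write_tsv(out_dir / "studies.tsv",
               ["study_id", "country_code", "location_name",
                "location_address", "start_date", "end_date", "latitude",
                "longitude", "altitude"],
               [(s.study_id, s.country_code, s.location_name,
                 s.location_address, s.start_date, s.end_date, s.latitude,
                 s.longitude, s.altitude) for s in rep.summaries])

    (out_dir / "common_genotypes.txt").write_text(
        "".join(g + "\n" for g in rep.common_genotypes), encoding="utf-8")

    stations = weather_stations(weather_source)
    table = station_distance_table(rep.summaries, stations)
    matched = {(m.study_id, m.station_id) for m in rep.matches}
    _write_tsv(out_dir / "station_matches.tsv",
               ["study_id", "station_id", "squared_distance", "matched"],
               [(a, b, d, "yes" if (a, b) in matched else "no")
                for a, b, d in table])

    studies = [s.study_id for s in rep.summaries]
    genos = rep.trait.genotypes()
    _write_tsv(out_dir / "trait_matrix.tsv",
               ["genotype", *studies],
               [(g, *(rep.trait.cells.get((g, s)) for s in studies))
                for g in genos])

    _write_tsv(out_dir / "pbtt.tsv", ["study_id", "cumulative_pbtt"],
               sorted(rep.pbtt.items()))

    _write_tsv(out_dir / "stability.tsv",
               ["genotype", "pbtt_low", "value_at_low", "pbtt_high",
                "value_at_high", "spread", "direction"],
               [(l.genotype_id, l.pbtt_low, l.value_at_low, l.pbtt_high,
                 l.value_at_high, l.spread, l.direction)
                for l in rep.stability.lines])

    (out_dir / "summary.log").write_text(
        "".join(line + "\n" for line in rep.log), encoding="utf-8")

    _plot_trait_dots(rep, out_dir / "trait_by_genotype.png", variable_id)
    _plot_stability(rep, out_dir / "stability_lines.png", variable_id)


def _plot_trait_dots(rep: MilestoneReport, path: Path, variable_id: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genos = rep.trait.genotypes()
    idx = {g: i for i, g in enumerate(genos)}
    fig, ax = plt.subplots(figsize=(10, 4))
    for s in rep.trait.studies():
        xs = [idx[g] for g in genos if (g, s) in rep.trait.cells]
        ys = [rep.trait.cells[(g, s)] for g in genos
              if (g, s) in rep.trait.cells]
        ax.plot(xs, ys, ".", label=s, markersize=3)
    ax.set_xlabel("genotype")
    ax.set_ylabel(f"mean {variable_id} per plant")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_stability(rep: MilestoneReport, path: Path, variable_id: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"rising": "tab:green", "falling": "tab:red", "flat": "tab:gray"}
    fig, ax = plt.subplots(figsize=(7, 5))
    for line in rep.stability.lines:
        ax.plot([line.pbtt_low, line.pbtt_high],
                [line.value_at_low, line.value_at_high],
                color=colors[line.direction], alpha=0.4, linewidth=0.8)
    ax.set_xlabel("cumulative PBTT")
    ax.set_ylabel(f"mean {variable_id} per plant")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
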