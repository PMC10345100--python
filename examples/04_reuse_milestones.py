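"""Run the cross-study reuse milestones on the deposit-shaped fixture.

Study summaries, genotype overlap, weather-station matching, per-genotype
trait means, cumulative photo-beta thermal time (PBTT), and stability
lines — the sequence a researcher follows to integrate five trials with
their local weather before any biological analysis.
"""

from phenofair.milestones import (
    PhenoModelSource,
    WeatherModelSource,
    genotype_overlap,
    genotype_trait_means,
    match_weather_stations,
    pbtt_per_study,
    stability_lines,
    summarize_studies,
    weather_stations,
)
from phenofair.synth import FOCAL_VARIABLE, FixtureSpec, generate_fixture

fx = generate_fixture(FixtureSpec(seed=1))  # deposit-shaped: 5 trials
pheno = PhenoModelSource(fx.investigation, fx.all_records)
weather = WeatherModelSource(fx.stations, fx.weather)

summaries = summarize_studies(pheno)
print("studies:", ", ".join(s.study_id for s in summaries))

overlap = genotype_overlap(pheno)
print(f"genotypes common to all {len(summaries)} studies: {len(overlap)}")

matches = match_weather_stations(summaries, weather_stations(weather))
for m in matches:
    print(f"  {m.study_id} -> {m.station_id} "
          f"(squared distance {m.squared_distance:.4f} deg^2)")

trait = genotype_trait_means(pheno, FOCAL_VARIABLE)
print(f"{FOCAL_VARIABLE}: {len(trait.genotypes())} genotypes with values; "
      f"{len(trait.complete_cases([s.study_id for s in summaries]))} "
      "with a value in every study")

pbtt = pbtt_per_study(pheno, weather, matches=matches)
for sid, value in sorted(pbtt.items()):
    print(f"  cumulative PBTT {sid}: {value:.2f}")

result = stability_lines(trait, pbtt)
counts = {d: sum(1 for l in result.lines if l.direction == d)
          for d in ("rising", "falling", "flat")}
print(f"stability lines: {counts['rising']} rising, {counts['falling']} "
      f"falling, {counts['flat']} flat "
      "(rising = better performance in longer, warmer seasons)")
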