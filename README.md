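# phenofair

FAIRify multi-environment plant phenotyping trials and re-run the
cross-study data-reuse workflow that motivates the effort.

Plant phenotyping experiments are run by uncoordinated groups over many
years; reusing them together ("data archaeology") fails on missing dates,
undocumented abbreviations, and incompatible layouts. `phenofair` addresses
this for the canonical hard case — five potato field trials grown across a
wide latitude span (Netherlands, Venezuela, Finland ×2, Ethiopia) with
partially overlapping subsets of one diploid mapping population (CxE) — by
providing:

- a typed model of **MIAPPE 1.1** metadata (investigation, studies,
  persons, biological materials, observed variables, observation units at
  plant/plot/block/genotype level, dated events) with a validator that
  reports every violation as a stable machine-readable code;
- readers/writers for the MIAPPE spreadsheet layout (one tab per section,
  as `.xlsx` or a TSV directory) and for sparse tab-delimited observation
  and daily-weather tables;
- lossless RDF serialization: **PPEO**-shaped graphs for phenotyping
  (meta)data, **AEMET**-shaped graphs for weather, deterministic Turtle;
- a **FAIR Data Point** layer (root / catalog / dataset / distribution)
  that embeds a MIAPPE investigation summary into the dataset-level
  document, so harvesters can pick the relevant dataset without opening
  its distributions, plus a crawler and a local SPARQL endpoint;
- the six **reuse milestones**: study summaries, genotype overlap,
  nearest-weather-station matching, per-genotype trait means, cumulative
  photo-beta thermal time (PBTT), and genotype stability lines — each
  runnable identically over in-memory objects, Turtle graphs, or live
  SPARQL endpoints (including a federated pheno × weather join);
- a seeded **synthetic-deposit generator** shaped like the real archive
  (5 studies, 292 genotypes, 101 common to all studies, 80 with the focal
  trait everywhere, one trial pre-averaged per genotype) with a
  ground-truth ledger for every quantity.

## The quantities at the core

Genotype overlap across studies $S$ is the intersection
$\bigcap_{s \in S} G_s$ of per-study genotype sets (a genotype is the
biological-material id of an observation unit). Station matching minimizes
the squared coordinate difference
$d^2 = (\phi_{study}-\phi_{station})^2 + (\lambda_{study}-\lambda_{station})^2$
in raw decimal degrees. Trait cells are arithmetic means over plants of a
genotype within a study; pre-averaged (genotype-level) records pass
through. The environmental covariate is cumulative photo-beta thermal
time,

$$\mathrm{PBTT} = \sum_{d \in \text{window}} f_{photo}(P_d)\, f_{beta}(T_d),$$

with $f_{beta}$ the beta thermal response (0 at a base and a ceiling
temperature, 1 at the optimum) and $f_{photo} \in [0,1]$ a linear
photoperiod discount below a critical day length. Stability lines join each
genotype's worst and best study mean, placed at those studies' PBTT values;
a rising line means better performance in longer, warmer seasons.

## Worked example

```
$ python examples/04_reuse_milestones.py
studies: 1999NL, 2003VE, 2004Fin, 2005Fin, 2010ET
genotypes common to all 5 studies: 101
  1999NL -> ws_1999NL (squared distance 0.0000 deg^2)
  2003VE -> ws_2003VE (squared distance 0.0002 deg^2)
  2004Fin -> ws_2004Fin (squared distance 0.0006 deg^2)
  2005Fin -> ws_2005Fin (squared distance 0.0016 deg^2)
  2010ET -> ws_2010ET (squared distance 0.0013 deg^2)
tubwtotal: 292 genotypes with values; 80 with a value in every study
  cumulative PBTT 1999NL: 132.80
  cumulative PBTT 2003VE: 69.64
  cumulative PBTT 2004Fin: 105.66
  cumulative PBTT 2005Fin: 105.51
  cumulative PBTT 2010ET: 82.31
stability lines: 31 rising, 70 falling, 191 flat (rising = better performance in longer, warmer seasons)
```

Reading the output: 101 of the 292 genotypes were grown in all five
trials, and 80 of those carry a tuber-weight value everywhere — the subset
a multi-environment analysis can actually use. Each trial's location is
matched to the weather station minimizing the squared coordinate
difference. The long northern-European season (1999NL) accumulates the
most photo-thermal time; the two tropical highland trials the least, their
short days discounted by the photoperiod term. Most single-study genotypes
yield flat (single-point) stability lines; among genotypes seen in several
environments, risers outperform in long warm seasons and fallers in short
cool ones.

The other examples cover validation and defect reporting
(`01_validate_workbook.py`), lossless RDF round trips
(`02_rdf_roundtrip.py`), and FDP publication + crawling
(`03_fdp_publish_and_crawl.py`).

## Command line

```
phenofair simulate  --seed 1 --out deposit/          # synthetic deposit
phenofair validate  deposit/workbook --data deposit/obs_1999NL.tsv
phenofair convert   deposit/workbook --data ... --weather deposit/weather.tsv --out ttl/
phenofair fdp build --meta ttl/metadata.ttl --out fdpdocs/ --endpoint-url http://...
phenofair fdp crawl fdpdocs/
phenofair milestones --meta ttl/metadata.ttl --obs ttl/obs_*.ttl \
    --weather ttl/weather.ttl --variable tubwtotal --out report/
```

Exit codes: 0 ok, 2 validation, 3 I/O, 4 configuration, 5 remote source.
`milestones` writes `studies.tsv`, `common_genotypes.txt`,
`station_matches.tsv`, `trait_matrix.tsv`, `pbtt.tsv`, `stability.tsv`,
two plots, and a `summary.log` of the counts at each step.

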