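# Methods

## Scope and data model

`phenofair` models the metadata and data of multi-environment plant
phenotyping trials after the MIAPPE 1.1 checklist. An `Investigation`
owns `Study` objects (location, window, design, environment parameters,
dated `Event`s, `ExperimentalFactor`s, observation units), plus the
investigation-wide registries: `Person`s, `DataFileLink`s (one data file
per study by convention), `BiologicalMaterial`s (genotypes; the originating
cross — here the CxE diploid potato backcross — recorded as the material
source), and `ObservedVariable`s (trait + method + scale under a stable
id, the sole join key between data files and metadata).

Measurements are *not* part of the metadata tree. An `ObservationRecord`
is one (observation unit, optional date, variable, value) tuple; an empty
cell in a data file produces no record, so time series stay sparse. Daily
weather is a `WeatherObservation` per (station, day, variable) for two
variables: daily mean temperature (°C) and photoperiod (hours, constrained
to [0, 24]).

Observation units carry one of four levels. `plant` nests in `plot` nests
in `block`; the `genotype` level marks deposits communicated only as
per-genotype averages (one of the five emulated trials arrived that way).
The level vocabulary is deliberately closed: extending it is a code
change, not a silent string.

Model objects are immutable dataclasses constructible in any state.
Consistency is judged solely by `validate_investigation`, which returns a
report of `(code, object_id, message)` triples sorted deterministically —
never raising — so a broken legacy deposit can be diagnosed in one pass.
Notable rules: events must carry a full calendar date (an un-dated
management action belongs in experimental factors instead); partial dates
(year or year-month) are accepted in study metadata but flagged;
categorical variables declare their legal tokens and stray symbols (the
dots and asterisks of hand-kept files) are errors, downgradable to
warnings with a permissive flag.

Genotype identity is the biological-material id after synonym resolution:
materials may list synonyms (emulating genotype-name translation files),
and loaders can map them onto canonical ids. A genotype-level unit's
genotype is the identity mapping.

## Interchange formats

The MIAPPE workbook has one tab per checklist section (all eleven,
including an empty Sample placeholder), written either as `.xlsx` or as a
directory of per-section TSVs with identical content. Row order is
canonical (sorted by id), so writing is deterministic and
`read(write(inv))` is the identity on canonical investigations
(`canonicalize` defines that order). A missing Investigation section is
fatal; any other missing section is a warning plus an empty section;
unknown tabs are reported, never silently dropped.

Observation tables are tab-delimited with header
`observation_unit_id, date, <variable id>...` — one record per non-empty
cell. Undeclared header variables and malformed row widths are hard errors
naming the column or line. Missing-value tokens default to the empty
string, configurable (`NA`, `-`) for files assembled by many hands.
Conflicting duplicate measurements for one (unit, date, variable) are an
error by default with a keep-last override, since silent ambiguity is the
root failure mode these deposits exhibit. Weather tables hold one row per
(station, day) with station coordinates repeated; stations deduplicate by
id, and conflicting redefinitions are errors. All text is UTF-8, decimal
point only, tab the only separator.

## RDF mapping

Phenotyping (meta)data maps to a graph using PPEO-style terms, weather to
AEMET-style terms. Both vocabularies are configuration (`phenofair.vocab`):
the bundled mapping table covers exactly the MIAPPE subset used here, and
term IRIs can be swapped without touching graph shape. Every node receives
a minted URI of the form `base/{type-tag}/{percent-encoded-id}` — no blank
nodes, because FDP harvesting requires stable references; minting is
injective on (tag, id) and invertible. Serialization refuses invalid
investigations, so only consistent metadata ever reaches RDF.

Turtle output is deterministic: a fixed sorted prefix table followed by
one statement per line in sorted order. Equal graphs serialize to
byte-identical files, making `.ttl` deposits diffable. The full cycle
model → graph → Turtle → graph → model is the identity on canonical
investigations.

Sub-objects without natural ids (persons, environment parameters, factors,
events, data-file links) are minted from their content fields; exact
duplicates of such objects within one investigation therefore collapse in
RDF. This is intentional set semantics — two indistinguishable environment
parameters carry no information the graph could preserve.

## FAIR Data Point layer

The FDP tree has four levels — root, catalog, dataset, distribution — each
emitted as its own Turtle document linking parent and children, so the
hierarchy is navigable in both directions and each document parses
independently of the data. Generic descriptors use DCAT2-compatible
predicates (title, description, theme, dataset, distribution, accessURL,
mediaType) so non-MIAPPE-aware harvesters degrade gracefully.

The dataset-level document is two-part: the generic DCAT block, plus an
embedded MIAPPE *summary* — investigation id/title/description, per-study
summaries (id, title, country, window, coordinates), the observed-variable
list, and a biological-material summary (count and source populations).
The only cross-link between the parts is Dataset → Investigation; aligning
other levels (e.g. distribution with study) has no meaning and is not
emitted. The summary deliberately omits observation-unit detail: it exists
to answer "is this dataset relevant?" during crawling, not to replace the
full metadata behind the distributions.

The crawler walks breadth-first from the root via a pluggable fetch
function (file-backed or HTTP-backed); unreachable children become
warnings rather than failures, an unreachable root is fatal. Serving over
HTTP is a thin wrapper (stdlib `http.server`) around the same documents,
so file-based tests exercise the identical contract.

## Milestones and the three-way contract

The six reuse milestones run over any source form: in-memory model
objects, merged Turtle graphs (queried via SPARQL with rdflib), or live
SPARQL endpoints (the same query text over the SPARQL 1.1 protocol). The
model route reads objects directly while the graph and endpoint routes
share query text — so agreement between routes genuinely tests the
serialization and queries, and the package's central property is that all
three give identical results on every fixture.

Milestone specifics:

- **Station matching** minimizes the squared difference of raw decimal
  degrees, `(Δlat)² + (Δlon)²` — exactly the quantity the discovery
  queries sort on. It is not a great-circle distance; a haversine mode
  exists behind a flag but is off by default for fidelity to that
  convention. Ties break lexicographically on station id, and the full
  sorted distance table is available for inspection.
- **Trait aggregation** averages per plant within (genotype, study). A
  plant measured on several dates contributes its *last* dated record by
  default (`first` and `mean` are selectable); genotype-level records pass
  through as the cell value with contributing count recorded as unknown
  (weight 1 — the deposits do not say how many plants were averaged).
  Helpers expose the union of genotypes and the complete cases (a value in
  every listed study).
- **PBTT** accumulates `f_photo(P_d) · f_beta(T_d)` over the study window.
  `f_beta` is the beta thermal response: 0 at/below `t_base` and at/above
  `t_ceil`, 1 at `t_opt`, with a curvature exponent. `f_photo` is
  `clamp(1 − s · max(0, P_crit − P), 0, 1)`: full credit at/above the
  critical photoperiod, linear discount below. Defaults (`t_base` 5.5 °C,
  `t_opt` 23.4 °C, `t_ceil` 34.6 °C, curvature 1, `P_crit` 14 h,
  sensitivity 0.2 h⁻¹) are potato-flavoured package configuration — the
  functional family and parameters are stated here because no single
  published parameterization is canonical for this covariate; analyses
  should treat them as tunable and report the values used. Both weather
  series must cover the window; gaps fail listing the missing dates (a
  skip override exists). A study without an end date accumulates to the
  station's last reading.
- **Stability lines** pair each genotype's minimum and maximum study mean
  with those studies' PBTT. Direction is rising/falling by comparing the
  PBTT at the max- vs min-value environment; ties in value or PBTT, and
  single-environment genotypes, are flat. Ties among studies sharing an
  extreme value resolve to the lexicographically smallest study id. The
  spread (max − min) is the instability indicator.
- **Federation** joins the phenotypic and weather sources client-side
  (study coordinates × station coordinates; study windows × series
  coverage), so results are identical whether each side is a local graph
  or an endpoint.

## Synthetic deposits

The generator emulates the archived five-trial deposit's structure, and
its defaults are those study conditions: 5 studies at the real trials'
locations and windows (Wageningen 1999, Mérida highlands 2003, two boreal
Finnish seasons 2004/2005, Holetta 2010); 292 genotypes of which 101 occur
in every study (extras split round-robin); the 2003 trial recorded at
genotype level; 80 of the 101 common genotypes keep the focal trait in all
studies (each of the other 21 loses it in exactly one study, chosen
deterministically) — the overlap, union, and complete-case cardinalities
are therefore structural, not statistical.

Trait values follow `baseline(genotype) + effect(study) +
interaction(genotype, study) + noise`, the simplest structure under which
per-cell means are well defined and rising/falling stability mixtures
arise; defaults are a 40 g per-plant baseline with 12 g genotype spread,
15 g study shifts, 8 g interaction, and 5 g plant noise. A configurable
fraction of plants carries an earlier interim weighing so the
repeated-measure policy is exercised; the harvest record is the one that
counts. Weather is synthesized per station: photoperiod from the
astronomical day-length formula (latitude and day of year; deterministic),
temperature from a latitude-dependent seasonal sinusoid with ±1.5 °C daily
noise. Stations sit within 0.05° of their study, far smaller than
inter-site separations, so each study matches its own station.

Every fixture ships a ground-truth ledger — common genotypes, per-cell
means, station matches, PBTT — computed at build time by independent brute
force (set folds, explicit per-day loops re-derived in the generator, not
imported from the implementation). What passing tests show is therefore
internal consistency of the whole pipeline against construction; what they
cannot show is robustness to the full messiness of real legacy files
(multilingual labels, layout drift, transcription errors), which the
defect injector only samples: date-less events, undeclared variable
columns, stray categorical tokens, conflicting duplicates, missing weather
days.

## Numerical and testing choices

Means use plain floating accumulation and are checked against two-pass
oracles at 1e-12 relative; PBTT additivity and ledger agreement at 1e-9
absolute. Coordinates and values round-trip through `repr` so TSV and RDF
forms are bit-faithful. The three-way consistency property is exercised
over 100 seeded fixtures kept small (3 studies, 8 genotypes, ~40-day
windows) so the sweep — including a live localhost SPARQL endpoint —
completes in about a minute; full deposit-scale runs back the acceptance
script. Determinism is absolute given a seed: fixture files are
byte-identical across runs, as are Turtle serializations and report TSVs.

## Known limitations

- The PBTT parameterization is configuration, not a reconstruction of any
  specific published calibration; absolute PBTT values are comparable only
  within one parameter set.
- Synonym resolution assumes synonym→canonical maps are injective; the
  first declaration wins on conflict.
- The SPARQL endpoint is a single-graph localhost convenience for testing
  and small deployments, not a production triple store; federation is
  executed client-side rather than via SERVICE delegation.
- Genotypic/marker data, sample handling, and biological (QTL-by-
  environment) analysis are out of scope by design.
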