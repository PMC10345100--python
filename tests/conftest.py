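from datetime import date

import pytest

from phenofair.model import (
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
    Study,
    canonicalize,
)
from phenofair.synth import FixtureSpec, StudyShape, generate_fixture
from phenofair.vocab import UriPolicy


@pytest.fixture
def policy() -> UriPolicy:
    return UriPolicy("https://fdp.test.example/id/")


@pytest.fixture
def tiny_investigation() -> Investigation:
    """A minimal but fully consistent hand-built investigation."""
    return canonicalize(Investigation(
        id="inv1", title="CxE trials", miappe_version="1.1",
        license="CC-BY-4.0", publications=("doi:10.1/x",),
        studies=(Study(
            id="1999NL", title="NL trial", start_date=date(1999, 4, 1),
            end_date=date(1999, 9, 30), country_code="NL",
            location_name="Wageningen", location_address="Wageningen, NL",
            latitude=51.97, longitude=5.66, altitude=10.0,
            design_description="blocks",
            environment_parameters=(EnvironmentParameter("type of soil", "clay"),),
            events=(Event("planting", "", date(1999, 4, 2)),),
            experimental_factors=(
                ExperimentalFactor("water", "drip", ("high", "low")),),
            observation_units=(
                ObservationUnit("b1", "block", "g1", "1999NL"),
                ObservationUnit("p1", "plot", "g1", "1999NL", "b1"),
                ObservationUnit("pl1", "plant", "g1", "1999NL", "p1"),
            )),),
        persons=(Person("A. Curator", "a@example.org", "WUR", "curator"),),
        data_files=(DataFileLink("data/1999NL.tsv", "obs", "1999NL"),),
        biological_materials=(
            BiologicalMaterial("g1", "Solanum tuberosum", "CxE", ("alt-g1",)),),
        observed_variables=(
            ObservedVariable("tubw", "tuber weight", "yield",
                             "harvest weighing", "grams", "g"),
            ObservedVariable("flow", "flowering", "development",
                             "visual", "0-7", "",
                             tuple(str(i) for i in range(8)))),
    ))


@pytest.fixture
def tiny_records() -> list[ObservationRecord]:
    return [
        ObservationRecord("pl1", "tubw", 1.5, date(1999, 8, 1)),
        ObservationRecord("pl1", "flow", "3", date(1999, 6, 1)),
    ]


# short-window shapes so consistency sweeps over many fixtures stay fast
SHORT_SHAPES = (
    StudyShape("1999NL", "NL", "Wageningen", 51.97, 5.66, 10.0,
               date(1999, 6, 1), date(1999, 7, 10)),
    StudyShape("2003VE", "VE", "Merida highlands", 8.60, -71.15, 1800.0,
               date(2003, 2, 1), date(2003, 3, 12)),
    StudyShape("2004Fin", "FI", "Jokioinen", 60.81, 23.48, 104.0,
               date(2004, 6, 5), date(2004, 7, 15)),
)


def small_spec(seed: int, **kw) -> FixtureSpec:
    kw.setdefault("study_shapes", SHORT_SHAPES)
    return FixtureSpec.small(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(small_spec(seed=11))


@pytest.fixture(scope="session")
def deposit_fixture():
    """The deposit-shaped default: 5 studies, 292/101/80 genotypes."""
    return generate_fixture(FixtureSpec(seed=1))
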