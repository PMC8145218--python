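import pytest

from surveyconcord import (GeoLevel, SurveyEstimate, build_cross_source_pairs,
                           build_same_source_scenarios, pairs_to_frame)
from surveyconcord.fixtures import anc_match_example, zambia_scenario_example


def make_estimate(**kw):
    """A valid record with overridable fields, for compact test setup."""
    base = dict(
        source_kind="field",
        source_name="SRC",
        country="Atlantis",
        geo_path=("Atlantis", "R1", "R1-P1", "R1-P1-D1"),
        geo_level=GeoLevel.DISTRICT,
        year=2016.0,
        season="unknown",
        indicator_id="ind00",
        n=500,
        estimate=50.0,
    )
    base.update(kw)
    return SurveyEstimate(**base)


@pytest.fixture(scope="session")
def anc_example():
    return anc_match_example()


@pytest.fixture(scope="session")
def anc_pairs(anc_example):
    field, ref = anc_example
    pairs, reports = build_cross_source_pairs(field, ref)
    assert not reports
    return pairs


@pytest.fixture(scope="session")
def anc_pairs_frame(anc_pairs):
    return pairs_to_frame(anc_pairs)


@pytest.fixture(scope="session")
def zambia_records():
    return zambia_scenario_example()


@pytest.fixture(scope="session")
def zambia_pairs(zambia_records):
    return build_same_source_scenarios(zambia_records)
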