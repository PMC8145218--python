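"""Pair construction: cycle selection, geography resolution, scenarios, metrics."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from surveyconcord import (GeoLevel, NoMatchError, PairingError,
                           build_cross_source_pairs, build_same_source_scenarios,
                           derive_pair_metrics, pairs_to_frame,
                           resolve_geography, select_reference_survey)
from surveyconcord.pairs import level_band, year_band

from conftest import make_estimate


class TestSelectReferenceSurvey:
    @pytest.mark.parametrize(
        "field_year, candidates, expected, fallback",
        [
            (2016.0, {2010.0, 2014.0}, 2014.0, False),
            (2012.0, {2013.0}, 2013.0, True),      # posterior-only cycle
            (2010.0, {2007.0}, 2007.0, False),
            (2014.0, {2014.0, 2018.0}, 2014.0, False),  # same-year cycle counts as prior
        ],
    )
    def test_most_recent_prior_with_fallback(self, field_year, candidates, expected, fallback):
        assert select_reference_survey(field_year, candidates) == (expected, fallback)

    def test_empty_candidates(self):
        with pytest.raises(NoMatchError):
            select_reference_survey(2016.0, set())


class TestResolveGeography:
    A = ("Atlantis",)

    def test_exact_unit_preferred(self):
        avail = [(self.A + ("R1", "P1"), 3), (self.A + ("R1",), 4)]
        path, lvl, climbed = resolve_geography(self.A + ("R1", "P1"), 3, avail)
        assert (path, lvl, climbed) == (self.A + ("R1", "P1"), 3, 0)

    def test_one_level_up(self):
        # district absent from the reference, province present
        avail = [(self.A + ("R1", "Inhambane"), 3)]
        path, lvl, climbed = resolve_geography(self.A + ("R1", "Inhambane", "Homoine"), 2, avail)
        assert (lvl, climbed) == (3, 1)

    def test_two_levels_up(self):
        avail = [(self.A + ("R1", "P1"), 3)]
        path, lvl, climbed = resolve_geography(self.A + ("R1", "P1", "D1", "V1"), 1, avail)
        assert (path, lvl, climbed) == (self.A + ("R1", "P1"), 3, 2)

    def test_never_returns_lower_level(self):
        avail = [(self.A + ("R1", "P1"), 2)]  # declared below the query level
        with pytest.raises(NoMatchError):
            resolve_geography(self.A + ("R1", "P1", "X"), 3, avail)

    def test_no_containing_unit(self):
        with pytest.raises(NoMatchError):
            resolve_geography(self.A + ("R9", "P9"), 3, [(self.A + ("R1",), 4)])


class TestDerivePairMetrics:
    def test_level_and_year_metrics(self):
        ref = make_estimate(source_kind="reference", source_name="DHS",
                            geo_path=("Atlantis", "R1", "R1-P1"),
                            geo_level=GeoLevel.PROVINCE, year=2005.5, estimate=40.0)
        field = make_estimate(year=2012.0, estimate=30.0)
        p = derive_pair_metrics(ref, field)
        assert p.difference == pytest.approx(10.0)
        assert p.level_difference == 1
        assert p.level_diff_band == "1"
        assert p.year_difference == pytest.approx(-6.5)
        assert p.year_diff_band == ">=3.5"
        assert p.season_concordance == "unknown"

    def test_self_pair_is_all_zero(self):
        rec = make_estimate()
        ref = dataclasses.replace(rec, source_kind="reference")
        p = derive_pair_metrics(ref, rec)
        assert (p.difference, p.year_difference, p.level_difference) == (0.0, 0.0, 0)
        assert p.level_diff_band == "0"

    def test_season_concordance(self):
        f = make_estimate(season="wet")
        same = dataclasses.replace(f, source_kind="reference", season="wet")
        diff = dataclasses.replace(f, source_kind="reference", season="dry")
        assert derive_pair_metrics(same, f).season_concordance == "same"
        assert derive_pair_metrics(diff, f).season_concordance == "different"

    def test_mismatch_raises(self):
        f = make_estimate()
        with pytest.raises(PairingError):
            derive_pair_metrics(dataclasses.replace(f, indicator_id="other"), f)
        with pytest.raises(PairingError):
            derive_pair_metrics(
                dataclasses.replace(f, country="Borduria", geo_path=("Borduria", "R", "P", "D")), f
            )

    @given(
        e_ref=st.floats(min_value=0, max_value=100),
        e_field=st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_difference_antisymmetric_under_swap(self, e_ref, e_field):
        a = make_estimate(source_kind="reference", estimate=e_ref)
        b = make_estimate(estimate=e_field)
        fwd = derive_pair_metrics(a, b)
        rev = derive_pair_metrics(
            dataclasses.replace(b, source_kind="reference"),
            dataclasses.replace(a, source_kind="field"),
        )
        assert fwd.difference == pytest.approx(-rev.difference)
        assert fwd.abs_difference == pytest.approx(rev.abs_difference)


@pytest.mark.parametrize("diff, band", [(0, "0"), (1, "1"), (-1, "1"), (2, "2+"), (-3, "2+")])
def test_level_bands_are_unsigned(diff, band):
    assert level_band(diff) == band


@pytest.mark.parametrize(
    "gap, band", [(0.5, "<=1"), (1.0, "<=1"), (-2.0, "1.5-3"), (3.0, "1.5-3"), (3.5, ">=3.5"), (-6.5, ">=3.5")]
)
def test_year_bands_are_unsigned(gap, band):
    assert year_band(gap) == band


class TestCrossSourcePairs:
    def test_empty_field_set(self, anc_example):
        _, ref = anc_example
        pairs, reports = build_cross_source_pairs([], ref)
        assert pairs == [] and reports == []

    def test_unmatched_records_reported(self):
        f = make_estimate(country="Borduria", geo_path=("Borduria", "R", "P", "D"))
        pairs, reports = build_cross_source_pairs([f], [])
        assert not pairs and len(reports) == 1
        assert "country" in reports[0]["reason"]

    def test_posterior_match_can_be_disallowed(self):
        field = make_estimate()
        ref = make_estimate(source_kind="reference", source_name="DHS",
                            geo_path=("Atlantis", "R1", "R1-P1"),
                            geo_level=GeoLevel.PROVINCE, year=2017.0)
        pairs, reports = build_cross_source_pairs([field], [ref], allow_posterior=False)
        assert not pairs and reports[0]["reason"].startswith("only posterior")
        pairs, _ = build_cross_source_pairs([field], [ref], allow_posterior=True)
        assert pairs[0].fallback

    def test_max_climb_policy(self):
        field = make_estimate()
        ref = make_estimate(source_kind="reference", source_name="DHS",
                            geo_path=("Atlantis",), geo_level=GeoLevel.COUNTRY, year=2015.0)
        pairs, reports = build_cross_source_pairs([field], [ref], max_climb=2)
        assert not pairs and "levels up" in reports[0]["reason"]
        pairs, _ = build_cross_source_pairs([field], [ref], max_climb=3)
        assert pairs and pairs[0].levels_climbed == 3

    def test_output_never_exceeds_field_count(self, anc_example):
        field, ref = anc_example
        pairs, _ = build_cross_source_pairs(field, ref)
        assert len(pairs) <= len(field)


class TestSameSourceScenarios:
    def test_zambia_scenario_counts(self, zambia_pairs):
        counts = {s: sum(p.scenario == s for p in zambia_pairs) for s in ("S1", "S2", "S3")}
        assert counts == {"S1": 11, "S2": 10, "S3": 10}

    def test_s1_example_difference(self, zambia_pairs):
        central = [p for p in zambia_pairs
                   if p.scenario == "S1" and p.field.geo_path[-1] == "Central"]
        (p,) = central
        assert p.ref.estimate == 89.2 and p.field.estimate == 89.0
        assert p.difference == pytest.approx(0.2)
        assert p.level_difference == 0 and p.year_difference != 0

    def test_scenario_invariants(self, zambia_pairs):
        for p in zambia_pairs:
            if p.scenario == "S1":
                assert p.level_difference == 0 and p.year_difference != 0
            elif p.scenario == "S2":
                assert p.year_difference == 0 and p.level_difference != 0
            else:
                assert p.year_difference != 0 and p.level_difference != 0

    def test_all_cycles_mode_adds_later_same_year_pairs(self, zambia_records):
        pairs = build_same_source_scenarios(zambia_records, s2_cycle="all")
        s2 = [p for p in pairs if p.scenario == "S2"]
        assert len(s2) == 20  # national vs provinces in both cycles

    def test_pairs_frame_columns(self, zambia_pairs):
        df = pairs_to_frame(zambia_pairs)
        assert len(df) == 31
        assert (df["abs_difference"] == df["difference"].abs()).all()
        assert set(df["scenario"]) == {"S1", "S2", "S3"}
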