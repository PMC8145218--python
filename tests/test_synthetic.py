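"""Synthetic landscape generator: reproducibility, aggregation, closed-form ties."""

import dataclasses

import numpy as np
import pytest

from surveyconcord import (DGMConfig, GeoLevel, aggregate_up, analytic_sd,
                           build_cross_source_pairs, generate_landscape,
                           pairs_to_frame, read_estimates, write_estimates)
from surveyconcord.synthetic import SyntheticTruth

from conftest import make_estimate

ZERO_DGM = DGMConfig(
    n_indicators=6,
    districts_per_province=6,
    sigma_region=0.0, sigma_province=0.0, sigma_district=0.0, sigma_village=0.0,
    drift_mean=0.0, drift_sd=0.0, seasonal_sd=0.0, method_bias_sd=0.0,
    deff=1.0,
    ref_cycles=(2015.0,), field_cycles=(2015.0,),
    ref_levels=(2,), field_levels=(2,),
    season_unknown_frac=0.0,
    seed=123,
)


class TestGenerateLandscape:
    def test_reproducible_under_seed(self):
        a_field, a_ref, _ = generate_landscape(ZERO_DGM)
        b_field, b_ref, _ = generate_landscape(ZERO_DGM)
        assert a_field == b_field and a_ref == b_ref

    def test_records_round_trip_through_io(self, tmp_path):
        field, ref, _ = generate_landscape(dataclasses.replace(ZERO_DGM, n_indicators=3))
        for recs, name in ((field, "f.csv"), (ref, "r.csv")):
            write_estimates(recs, tmp_path / name)
            assert read_estimates(tmp_path / name) == recs

    def test_degenerate_dgm_shares_one_truth_per_indicator(self):
        _, _, truth = generate_landscape(ZERO_DGM)
        for ind in ZERO_DGM.indicator_ids():
            ps = {
                truth.true_prevalence(ind, path, 2015.0, "dry")
                for path in truth.unit_effects
            }
            ps.add(truth.true_prevalence(ind, (ZERO_DGM.country,), 2015.0, "dry"))
            assert len(ps) == 1

    def test_truth_json_round_trip(self, tmp_path):
        _, _, truth = generate_landscape(ZERO_DGM)
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.mu == truth.mu and back.delta == truth.delta
        assert back.config == truth.config

    def test_method_bias_shifts_pair_means(self):
        # large per-source bias, no other structure: mean pair difference per
        # indicator matches the closed-form bias mapping within 3 MC SEs
        cfg = dataclasses.replace(ZERO_DGM, method_bias_sd=1.0, n_indicators=4,
                                  districts_per_province=10, seed=7)
        field, ref, truth = generate_landscape(cfg)
        pairs, _ = build_cross_source_pairs(field, ref)
        df = pairs_to_frame(pairs)
        for ind in cfg.indicator_ids():
            sub = df[df["indicator_id"] == ind]
            path = (cfg.country, "R1", "R1-P1", "R1-P1-D1")
            expected = 100.0 * (
                truth.observed_prevalence("reference", ind, path, 2015.0, "dry")
                - truth.observed_prevalence("field", ind, path, 2015.0, "dry")
            )
            p_mid = truth.true_prevalence(ind, path, 2015.0, "dry")
            mc_se = analytic_sd(p_mid, cfg.n_eff) / np.sqrt(len(sub))
            assert abs(sub["difference"].mean() - expected) < 3 * mc_se + 0.5

    def test_pair_sd_matches_binomial_closed_form(self):
        field, ref, truth = generate_landscape(
            dataclasses.replace(ZERO_DGM, districts_per_province=20, seed=11)
        )
        pairs, _ = build_cross_source_pairs(field, ref)
        df = pairs_to_frame(pairs)
        cfg = truth.config
        for ind in cfg.indicator_ids():
            sub = df[df["indicator_id"] == ind]["difference"]
            p = truth.true_prevalence(ind, (cfg.country, "R1", "R1-P1", "R1-P1-D1"),
                                      2015.0, "dry")
            sigma = analytic_sd(p, cfg.n_eff)
            mc_se = sigma / np.sqrt(2 * (len(sub) - 1))
            assert abs(sub.std(ddof=1) - sigma) < 3 * mc_se

    def test_design_effect_widens_differences(self):
        base = dataclasses.replace(ZERO_DGM, districts_per_province=15, seed=21)
        inflated = dataclasses.replace(base, deff=4.0)
        mean_abs = {}
        for name, cfg in (("deff1", base), ("deff4", inflated)):
            field, ref, _ = generate_landscape(cfg)
            pairs, _ = build_cross_source_pairs(field, ref)
            mean_abs[name] = pairs_to_frame(pairs)["abs_difference"].mean()
        assert mean_abs["deff4"] > mean_abs["deff1"]

    def test_season_masking_fraction(self):
        cfg = dataclasses.replace(ZERO_DGM, season_unknown_frac=1.0)
        field, _, _ = generate_landscape(cfg)
        assert all(r.season == "unknown" for r in field)

    def test_site_selection_restricts_field_units(self):
        cfg = dataclasses.replace(ZERO_DGM, sigma_district=0.5, field_site_quantile=0.5)
        field, _, _ = generate_landscape(cfg)
        full, _, _ = generate_landscape(dataclasses.replace(cfg, field_site_quantile=1.0))
        assert len({r.geo_path for r in field}) < len({r.geo_path for r in full})

    @pytest.mark.parametrize(
        "kw", [{"deff": 0.5}, {"sigma_region": -1.0}, {"baseline_range": (0.9, 0.1)},
               {"n_regions": 0}, {"field_site_quantile": 0.0}]
    )
    def test_config_invariants(self, kw):
        with pytest.raises(ValueError):
            dataclasses.replace(ZERO_DGM, **kw)


class TestAggregateUp:
    def test_weighted_mean(self):
        parent = ("Atlantis", "R1", "R1-P1")
        a = make_estimate(n=100, estimate=40.0)
        b = make_estimate(n=300, estimate=80.0,
                          geo_path=("Atlantis", "R1", "R1-P1", "R1-P1-D2"))
        out = aggregate_up([a, b], parent)
        assert out.n == 400 and out.estimate == pytest.approx(70.0)
        assert out.geo_level == GeoLevel.PROVINCE

    def test_idempotent_on_single_record(self):
        a = make_estimate()
        out = aggregate_up([a], a.geo_path, int(a.geo_level))
        assert out.estimate == a.estimate and out.n == a.n

    def test_order_invariant(self):
        parent = ("Atlantis", "R1", "R1-P1")
        recs = [
            make_estimate(n=n, estimate=e,
                          geo_path=parent + (f"R1-P1-D{i}",))
            for i, (n, e) in enumerate([(50, 10.0), (150, 30.0), (300, 90.0)], 1)
        ]
        fwd = aggregate_up(recs, parent)
        rev = aggregate_up(recs[::-1], parent)
        assert fwd.estimate == pytest.approx(rev.estimate) and fwd.n == rev.n

    def test_constant_estimates_pass_through(self):
        parent = ("Atlantis", "R1", "R1-P1")
        recs = [make_estimate(n=n, estimate=42.0, geo_path=parent + (f"D{n}",))
                for n in (10, 20)]
        assert aggregate_up(recs, parent).estimate == pytest.approx(42.0)

    def test_rejects_empty_and_mixed(self):
        with pytest.raises(ValueError):
            aggregate_up([], ("Atlantis",))
        a = make_estimate()
        b = make_estimate(indicator_id="other")
        with pytest.raises(ValueError, match="mixed"):
            aggregate_up([a, b], ("Atlantis", "R1"))
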