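"""Synthetic two-source survey landscapes with known ground truth.

The generator emulates the statistical structure the concordance analysis
assumes about real survey landscapes, so that matching, concordance
summaries, variance partitions and recovery tests can run without any
external data:

* a four-level administrative hierarchy (region > province > district >
  village) under one country;
* per-indicator true prevalences composed additively on the logit scale —
  a baseline per indicator, nested geographic effects per unit, a linear
  temporal drift per indicator, and a wet-season shift per indicator:

      logit p(i, g, t, s) = mu_i + sum_levels a_unit + beta_i (t - t0)
                            + gamma_i 1[s = wet]

* per-source method bias: each source measures prevalence shifted by
  delta_{source, i} on the logit scale (questionnaire / training / frame
  differences);
* binomial sampling error with a design effect, implemented as
  effective-sample-size deflation: counts are drawn binomial(n / DEFF, p).

Everything is reproducible from the configuration and one seed, and the
latent parameters are returned as a :class:`SyntheticTruth` so tests can
compare what the analysis attributes against what was injected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .records import GeoLevel, IndicatorCatalog, SurveyEstimate, validate_records

logger = logging.getLogger("surveyconcord")

__all__ = [
    "DGMConfig",
    "SyntheticTruth",
    "generate_landscape",
    "aggregate_up",
    "recovery_report",
    "synthetic_catalog",
]


@dataclass(frozen=True)
class DGMConfig:
    """Configuration of the synthetic data-generating mechanism.

    Variance components and effect sizes are on the logit scale; ``n`` is the
    per-estimate sample size before design-effect deflation. Defaults describe
    a realistic small landscape: moderate geographic heterogeneity, mild
    temporal drift and seasonality, a typical household-survey sample of 500
    per estimate with a clustered-design effect of 1.5, and a reference source
    observed one field-survey cycle earlier at higher aggregation levels.
    """

    country: str = "Atlantis"
    n_regions: int = 2
    provinces_per_region: int = 2
    districts_per_province: int = 5
    villages_per_district: int = 0

    n_indicators: int = 12
    baseline_range: tuple[float, float] = (0.05, 0.95)

    sigma_region: float = 0.3
    sigma_province: float = 0.2
    sigma_district: float = 0.2
    sigma_village: float = 0.2
    drift_mean: float = 0.0          # logit per year, common direction
    drift_sd: float = 0.05           # logit per year, indicator-specific spread
    seasonal_sd: float = 0.1         # logit, wet-season shift spread
    method_bias_sd: float = 0.3      # logit, per (source, indicator)

    n: int = 500
    deff: float = 1.5                # design effect >= 1

    ref_cycles: tuple[float, ...] = (2013.5,)
    field_cycles: tuple[float, ...] = (2016.0,)
    ref_levels: tuple[int, ...] = (3, 5)
    field_levels: tuple[int, ...] = (2,)
    ref_season: str = "dry"
    field_season: str = "dry"
    season_unknown_frac: float = 0.2   # fraction of emitted season labels masked

    field_site_quantile: float = 1.0   # < 1 restricts field sites to the
                                       # lowest-prevalence fraction of units
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_region", "sigma_province", "sigma_district",
                     "sigma_village", "drift_sd", "seasonal_sd", "method_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.deff < 1.0:
            raise ValueError("design effect must be >= 1")
        for name in ("n_regions", "provinces_per_region", "districts_per_province"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.villages_per_district < 0:
            raise ValueError("villages_per_district must be >= 0")
        if not (0.0 < self.baseline_range[0] < self.baseline_range[1] < 1.0):
            raise ValueError("baseline_range must satisfy 0 < lo < hi < 1")
        if not (0.0 <= self.season_unknown_frac <= 1.0):
            raise ValueError("season_unknown_frac must lie in [0, 1]")
        if not (0.0 < self.field_site_quantile <= 1.0):
            raise ValueError("field_site_quantile must lie in (0, 1]")
        if any(v == 1 for v in self.field_levels + self.ref_levels) and self.villages_per_district < 1:
            raise ValueError("level-1 emission requires villages_per_district >= 1")

    @property
    def n_eff(self) -> int:
        """Effective per-estimate sample size after design-effect deflation."""
        return max(1, round(self.n / self.deff))

    def indicator_ids(self) -> list[str]:
        return [f"ind{i:02d}" for i in range(self.n_indicators)]


@dataclass
class SyntheticTruth:
    """Latent parameters of one generated landscape (logit scale)."""

    config: DGMConfig
    t0: float
    mu: dict[str, float]                       # indicator baseline
    unit_effects: dict[tuple[str, ...], float]  # per geographic unit
    beta: dict[str, float]                     # drift, logit / year
    gamma: dict[str, float]                    # wet-season shift
    delta: dict[tuple[str, str], float]        # (source_kind, indicator) bias

    def true_prevalence(
        self, indicator_id: str, geo_path: tuple[str, ...], year: float, season: str
    ) -> float:
        """Latent prevalence in (0,1) at a unit/time/season (before method bias)."""
        eta = self.mu[indicator_id]
        for depth in range(2, len(geo_path) + 1):
            eta += self.unit_effects.get(tuple(geo_path[:depth]), 0.0)
        eta += self.beta[indicator_id] * (year - self.t0)
        if season == "wet":
            eta += self.gamma[indicator_id]
        return float(expit(eta))

    def observed_prevalence(
        self, source_kind: str, indicator_id: str,
        geo_path: tuple[str, ...], year: float, season: str,
    ) -> float:
        """Prevalence the source would measure in expectation (bias applied)."""
        p = self.true_prevalence(indicator_id, geo_path, year, season)
        return float(expit(logit(p) + self.delta[(source_kind, indicator_id)]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "t0": self.t0,
            "mu": self.mu,
            "unit_effects": {">".join(k): v for k, v in self.unit_effects.items()},
            "beta": self.beta,
            "gamma": self.gamma,
            "delta": {f"{s}|{i}": v for (s, i), v in self.delta.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg_raw = payload["config"]
        for key in ("baseline_range", "ref_cycles", "field_cycles", "ref_levels", "field_levels"):
            cfg_raw[key] = tuple(cfg_raw[key])
        return cls(
            config=DGMConfig(**cfg_raw),
            t0=payload["t0"],
            mu=payload["mu"],
            unit_effects={tuple(k.split(">")): v for k, v in payload["unit_effects"].items()},
            beta=payload["beta"],
            gamma=payload["gamma"],
            delta={(k.split("|")[0], k.split("|")[1]): v for k, v in payload["delta"].items()},
        )


def _units(config: DGMConfig) -> dict[int, list[tuple[str, ...]]]:
    """Geographic units per level, as full paths from the country down."""
    c = config.country
    units: dict[int, list[tuple[str, ...]]] = {5: [(c,)], 4: [], 3: [], 2: [], 1: []}
    for r in range(config.n_regions):
        rp = (c, f"R{r + 1}")
        units[4].append(rp)
        for p in range(config.provinces_per_region):
            pp = rp + (f"{rp[-1]}-P{p + 1}",)
            units[3].append(pp)
            for d in range(config.districts_per_province):
                dp = pp + (f"{pp[-1]}-D{d + 1}",)
                units[2].append(dp)
                for v in range(config.villages_per_district):
                    units[1].append(dp + (f"{dp[-1]}-V{v + 1}",))
    return units


def generate_landscape(
    config: DGMConfig,
) -> tuple[list[SurveyEstimate], list[SurveyEstimate], SyntheticTruth]:
    """Draw one landscape: (field_records, ref_records, truth).

    Latent parameters and sampling use separate child streams of the one
    configured seed, so the same seed always yields byte-identical tables.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_param, rng_sample = (np.random.default_rng(c) for c in ss.spawn(2))

    units = _units(config)
    sigmas = {4: config.sigma_region, 3: config.sigma_province,
              2: config.sigma_district, 1: config.sigma_village}
    unit_effects = {
        path: float(rng_param.normal(0.0, sigmas[lvl]))
        for lvl in (4, 3, 2, 1)
        for path in units[lvl]
    }

    inds = config.indicator_ids()
    lo, hi = logit(config.baseline_range[0]), logit(config.baseline_range[1])
    mu = {i: float(rng_param.uniform(lo, hi)) for i in inds}
    beta = {i: float(rng_param.normal(config.drift_mean, config.drift_sd)) for i in inds}
    gamma = {i: float(rng_param.normal(0.0, config.seasonal_sd)) for i in inds}
    delta = {
        (kind, i): float(rng_param.normal(0.0, config.method_bias_sd))
        for kind in ("reference", "field")
        for i in inds
    }
    all_cycles = config.ref_cycles + config.field_cycles
    truth = SyntheticTruth(
        config=config, t0=float(min(all_cycles)), mu=mu,
        unit_effects=unit_effects, beta=beta, gamma=gamma, delta=delta,
    )

    def emit(kind: str, name: str, cycles: Sequence[float],
             levels: Sequence[int], season: str) -> list[SurveyEstimate]:
        records = []
        for year in cycles:
            for lvl in levels:
                level_units = units[lvl]
                if kind == "field" and config.field_site_quantile < 1.0 and lvl < 5:
                    scores = np.array([
                        sum(unit_effects.get(tuple(u[:d]), 0.0) for d in range(2, len(u) + 1))
                        for u in level_units
                    ])
                    cut = np.quantile(scores, config.field_site_quantile)
                    level_units = [u for u, s in zip(level_units, scores) if s <= cut]
                for path in level_units:
                    for ind in inds:
                        p_obs = truth.observed_prevalence(kind, ind, path, year, season)
                        count = int(rng_sample.binomial(config.n_eff, p_obs))
                        label = season
                        if rng_sample.random() < config.season_unknown_frac:
                            label = "unknown"
                        records.append(
                            SurveyEstimate(
                                source_kind=kind,
                                source_name=name,
                                country=config.country,
                                geo_path=path,
                                geo_level=GeoLevel(lvl),
                                year=year,
                                season=label,
                                indicator_id=ind,
                                n=config.n_eff,
                                estimate=100.0 * count / config.n_eff,
                            )
                        )
        return records

    field_records = emit("field", "FieldSurvey", config.field_cycles,
                         config.field_levels, config.field_season)
    ref_records = emit("reference", "PublicSurvey", config.ref_cycles,
                       config.ref_levels, config.ref_season)
    logger.info(
        "generated landscape: %d field records, %d reference records, %d indicators",
        len(field_records), len(ref_records), len(inds),
    )
    return validate_records(field_records), validate_records(ref_records), truth


def synthetic_catalog(config: DGMConfig, group_size: int = 4) -> IndicatorCatalog:
    """Catalog for generated indicators: own subgroup, chunked broad groups."""
    return IndicatorCatalog(
        {i: (i, f"group{k // group_size + 1}") for k, i in enumerate(config.indicator_ids())}
    )


def aggregate_up(
    records: Sequence[SurveyEstimate],
    parent_path: tuple[str, ...],
    parent_level: int | None = None,
) -> SurveyEstimate:
    """Sample-size-weighted aggregate of child estimates into a parent unit.

    All records must share source, indicator, year and be contained in
    ``parent_path``. The aggregate's n is the children's total and its
    estimate their n-weighted mean; a single already-aggregated record passes
    through unchanged (idempotent).
    """
    recs = list(records)
    if not recs:
        raise ValueError("cannot aggregate an empty record set")
    first = recs[0]
    for r in recs:
        if r.indicator_id != first.indicator_id:
            raise ValueError("mixed indicators in aggregation")
        if (r.source_kind, r.source_name, r.year) != (first.source_kind, first.source_name, first.year):
            raise ValueError("mixed source or year in aggregation")
        if r.geo_path[: len(parent_path)] != parent_path:
            raise ValueError(f"{r.geo_path!r} not contained in parent {parent_path!r}")
    if parent_level is None:
        parent_level = 5 if len(parent_path) == 1 else 6 - len(parent_path)
    total_n = sum(r.n for r in recs)
    estimate = sum(r.n * r.estimate for r in recs) / total_n
    seasons = {r.season for r in recs}
    return SurveyEstimate(
        source_kind=first.source_kind,
        source_name=first.source_name,
        country=first.country,
        geo_path=parent_path,
        geo_level=GeoLevel(parent_level),
        year=first.year,
        season=seasons.pop() if len(seasons) == 1 else "unknown",
        indicator_id=first.indicator_id,
        n=total_n,
        estimate=estimate,
    )


def recovery_report(truth: SyntheticTruth, partition) -> dict:
    """Compare injected mechanisms against the variance shares attributed.

    ``partition`` is a :class:`surveyconcord.partition.VariancePartition`
    computed on pairs built from the generated records. The report states, per
    injected mechanism, which factor should absorb it and whether the
    qualitative ordering of shares matches the injection. It makes no claim
    about exact share values: shares depend on factor order and on how much
    binomial noise the landscape carries.
    """
    cfg = truth.config
    injected = {
        "method_bias": cfg.method_bias_sd > 0,
        "temporal_drift": cfg.drift_mean != 0 or cfg.drift_sd > 0,
        "geographic_heterogeneity": any(
            s > 0 for s in (cfg.sigma_region, cfg.sigma_province,
                            cfg.sigma_district, cfg.sigma_village)
        ),
        "seasonality": cfg.seasonal_sd > 0,
    }
    mechanism_factor = {
        "method_bias": "indicator_id",
        "temporal_drift": "year_difference",
        "geographic_heterogeneity": "level_diff_band",
        "seasonality": "season_concordance",
    }
    shares = dict(partition.shares)
    largest = max(shares, key=shares.get) if shares else None
    checks = {}
    for mech, factor in mechanism_factor.items():
        if factor not in shares:
            continue
        if injected[mech]:
            others = [v for k, v in shares.items() if k != factor]
            checks[mech] = {
                "factor": factor,
                "share": shares[factor],
                "is_largest_factor": not others or shares[factor] >= max(others),
            }
    return {
        "injected": injected,
        "shares": shares,
        "residual_share": partition.residual_share,
        "largest_factor": largest,
        "residual_dominates": partition.residual_share > max(shares.values(), default=0.0),
        "checks": checks,
        "n_pairs": partition.n,
    }
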