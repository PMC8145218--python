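"""End-to-end configured pipeline: validate, match, summarize, partition, simulate.

One :class:`PipelineConfig` (typically loaded from YAML) drives every stage;
a single root seed governs all stochastic stages. Outputs are CSV tables plus
a JSON run manifest recording the seed, package version and the record/pair
counts at every stage, so any output is reproducible from (inputs, config,
seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import reference_band_summary, summarize_strata, summarize_subgroups
from .partition import (CROSS_SOURCE_FACTORS, SAME_SOURCE_FACTORS, partition_variance)
from .pairs import build_cross_source_pairs, build_same_source_scenarios, pairs_to_frame
from .records import IndicatorCatalog, MIN_N_DEFAULT, filter_min_n, read_estimates
from .simulate import SimulationConfig, compare_distributions, simulate_difference_distribution

logger = logging.getLogger("surveyconcord")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    field_table: str
    reference_table: str
    output_dir: str
    catalog: str | None = None
    min_n: int = MIN_N_DEFAULT
    allow_posterior: bool = True
    max_climb: int | None = None
    within_k: tuple[float, ...] = (5.0, 20.0)
    s2_cycle: str = "earliest"
    run_scenarios: bool = False      # also build same-source pairs from the reference table
    simulation: SimulationConfig | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{**raw})
        if sim is not None:
            if "p_grid" in sim:
                sim["p_grid"] = tuple(sim["p_grid"])
            cfg.simulation = SimulationConfig(**{**sim, "seed": sim.get("seed", cfg.seed)})
        if isinstance(cfg.within_k, list):
            cfg.within_k = tuple(cfg.within_k)
        if not cfg.within_k:
            raise ValueError("within_k must be non-empty")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "simulation"},
        "counts": {},
        "outputs": [],
    }

    def write(df: pd.DataFrame, name: str, round_display: bool = True) -> None:
        df.to_csv(out / name, index=False)
        manifest["outputs"].append(name)
        if round_display:
            disp = df.copy()
            for c in disp.columns:
                if pd.api.types.is_float_dtype(disp[c]):
                    disp[c] = disp[c].round(1)
            disp.to_csv(out / name.replace(".csv", "_display.csv"), index=False)
            manifest["outputs"].append(name.replace(".csv", "_display.csv"))

    field_records = read_estimates(config.field_table)
    ref_records = read_estimates(config.reference_table)
    manifest["counts"]["field_read"] = len(field_records)
    manifest["counts"]["reference_read"] = len(ref_records)

    field_kept, field_drop = filter_min_n(field_records, config.min_n)
    ref_kept, ref_drop = filter_min_n(ref_records, config.min_n)
    manifest["counts"]["field_excluded_min_n"] = len(field_drop)
    manifest["counts"]["reference_excluded_min_n"] = len(ref_drop)

    pairs, reports = build_cross_source_pairs(
        field_kept, ref_kept,
        allow_posterior=config.allow_posterior, max_climb=config.max_climb,
    )
    pairs_df = pairs_to_frame(pairs)
    manifest["counts"]["pairs_cross_source"] = len(pairs)
    manifest["counts"]["field_unmatched"] = len(reports)
    write(pairs_df, "pairs.csv", round_display=False)
    write(pd.DataFrame(reports, columns=["source_name", "country", "geo_path",
                                         "year", "indicator_id", "reason"]),
          "no_match.csv", round_display=False)

    if len(pairs_df):
        ids = sorted(pairs_df["indicator_id"].unique())
        catalog = (IndicatorCatalog.from_csv(config.catalog)
                   if config.catalog else IndicatorCatalog.identity(ids))
        write(summarize_subgroups(pairs_df, catalog, config.within_k), "subgroup_summary.csv")
        strata = pd.concat(
            [summarize_strata(pairs_df, scheme) for scheme in
             ("year_band", "season", "level_band", "geo_level", "size_tertile")],
            ignore_index=True,
        )
        write(strata, "stratum_summary.csv")
        write(reference_band_summary(pairs_df), "reference_band_summary.csv")
        if len(pairs_df) >= 2 and pairs_df["difference"].nunique() > 1:
            parts = pd.concat(
                [partition_variance(pairs_df, resp, CROSS_SOURCE_FACTORS).to_frame()
                 for resp in ("difference", "abs_difference")],
                ignore_index=True,
            )
            write(parts, "variance_partition.csv")

    if config.run_scenarios:
        scen = build_same_source_scenarios(ref_kept, s2_cycle=config.s2_cycle)
        scen_df = pairs_to_frame(scen)
        manifest["counts"]["pairs_same_source"] = len(scen)
        write(scen_df, "scenario_pairs.csv", round_display=False)
        if len(scen_df) >= 2 and scen_df["difference"].nunique() > 1:
            parts = pd.concat(
                [partition_variance(scen_df, resp, SAME_SOURCE_FACTORS).to_frame()
                 for resp in ("difference", "abs_difference")],
                ignore_index=True,
            )
            write(parts, "scenario_variance_partition.csv")

    if config.simulation is not None:
        sim = simulate_difference_distribution(config.simulation)
        observed = {"cross_source": pairs_df} if len(pairs_df) else {}
        write(compare_distributions(sim, observed), "simulation_summary.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
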