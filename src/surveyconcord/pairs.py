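"""Matched-pair construction between reference and field estimates.

Cross-source mode pairs each field (NGO-style) estimate with the reference
(DHS/MICS-style) estimate for the same indicator, matched as closely as
possible in time and space:

* time — the most recent reference cycle carried out prior to the field
  survey; if none exists, the earliest later cycle may be used, flagged as a
  posterior match;
* space — the reference unit at the same level containing the field unit if
  available, otherwise the nearest ancestor in the administrative hierarchy,
  climbing one level at a time.

Same-source mode pairs estimates from a single source with itself across
cycles and levels, mimicking the cross-source matching conditions:

* Scenario 1 (S1): same unit and level, different cycles;
* Scenario 2 (S2): same cycle, a higher-level unit against each strictly
  contained lower-level unit;
* Scenario 3 (S3): earlier cycle at the higher level against later cycle at
  the lower level.

The signed difference is always reference minus field, so a positive
difference means the public source reports the higher prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import SurveyEstimate

logger = logging.getLogger("surveyconcord")

__all__ = [
    "MatchedPair",
    "PairingError",
    "NoMatchError",
    "select_reference_survey",
    "resolve_geography",
    "derive_pair_metrics",
    "build_cross_source_pairs",
    "build_same_source_scenarios",
    "pairs_to_frame",
    "level_band",
    "year_band",
]


class PairingError(ValueError):
    """Raised when two records cannot legally form a pair."""


class NoMatchError(LookupError):
    """Raised when no reference candidate exists for a field record."""


def level_band(level_difference: int) -> str:
    """Group a (signed) level difference as '0', '1' or '2+' (unsigned bands)."""
    a = abs(int(level_difference))
    return {0: "0", 1: "1"}.get(a, "2+")


def year_band(year_difference: float) -> str:
    """Group an (unsigned) year gap as '<=1', '1.5-3' or '>=3.5'.

    Gaps are multiples of 0.5 under midpoint year coding, so the three bands
    partition all attainable values.
    """
    a = abs(year_difference)
    if a <= 1.0:
        return "<=1"
    if a <= 3.0:
        return "1.5-3"
    return ">=3.5"


@dataclass(frozen=True)
class MatchedPair:
    """A reference-field estimate pair and its derived comparison metrics."""

    ref: SurveyEstimate
    field: SurveyEstimate
    scenario: str = "cross_source"   # or "S1" / "S2" / "S3"
    fallback: bool = False           # reference cycle is after the field survey
    levels_climbed: int = 0          # ancestor steps taken to find the reference unit

    @property
    def difference(self) -> float:
        """Reference minus field estimate, percentage points."""
        return self.ref.estimate - self.field.estimate

    @property
    def abs_difference(self) -> float:
        return abs(self.difference)

    @property
    def year_difference(self) -> float:
        """Reference year minus field year, decimal years (signed)."""
        return self.ref.year - self.field.year

    @property
    def abs_year_difference(self) -> float:
        return abs(self.year_difference)

    @property
    def level_difference(self) -> int:
        """Reference level minus field level (signed)."""
        return int(self.ref.geo_level) - int(self.field.geo_level)

    @property
    def level_diff_band(self) -> str:
        return level_band(self.level_difference)

    @property
    def year_diff_band(self) -> str:
        return year_band(self.year_difference)

    @property
    def season_concordance(self) -> str:
        """'same', 'different', or 'unknown' if either side lacks a season."""
        if self.ref.season == "unknown" or self.field.season == "unknown":
            return "unknown"
        return "same" if self.ref.season == self.field.season else "different"


def select_reference_survey(
    field_year: float, candidate_years: Iterable[float]
) -> tuple[float, bool]:
    """Choose the reference cycle for a field survey year.

    Returns ``(year, fallback)``: the most recent candidate at or before the
    field year; if every candidate is later, the earliest later one with the
    fallback flag set (a posterior match).
    """
    years = sorted(set(candidate_years))
    if not years:
        raise NoMatchError("empty candidate cycle set")
    prior = [y for y in years if y <= field_year]
    if prior:
        return max(prior), False
    return min(years), True


def resolve_geography(
    field_path: tuple[str, ...],
    field_level: int,
    available: Iterable[tuple[tuple[str, ...], int]],
) -> tuple[tuple[str, ...], int, int]:
    """Find the reference geography covering a field unit.

    ``available`` is the set of (geo_path, geo_level) present in the reference
    data. Preference order: the identical unit at the same level, then the
    nearest ancestor (longest proper path prefix), never a unit below the
    query's level. Returns ``(path, level, levels_climbed)`` with
    ``levels_climbed = reference level - field level >= 0``.
    """
    avail = list(available)
    for path, lvl in avail:
        if path == field_path and lvl == int(field_level):
            return path, lvl, 0
    # ancestors: proper prefixes of the field path, nearest (longest) first
    best: tuple[tuple[str, ...], int] | None = None
    for path, lvl in avail:
        if len(path) < len(field_path) and field_path[: len(path)] == path and lvl >= int(field_level):
            if best is None or len(path) > len(best[0]) or (
                len(path) == len(best[0]) and lvl < best[1]
            ):
                best = (path, lvl)
    if best is None:
        raise NoMatchError(
            f"no reference geography contains {'>'.join(field_path)} (level {field_level})"
        )
    return best[0], best[1], best[1] - int(field_level)


def derive_pair_metrics(
    ref: SurveyEstimate,
    field: SurveyEstimate,
    scenario: str = "cross_source",
    fallback: bool = False,
    levels_climbed: int = 0,
) -> MatchedPair:
    """Assemble a :class:`MatchedPair`, enforcing same indicator and country."""
    if ref.indicator_id != field.indicator_id:
        raise PairingError(
            f"indicator mismatch: {ref.indicator_id!r} vs {field.indicator_id!r}"
        )
    if ref.country != field.country:
        raise PairingError(f"country mismatch: {ref.country!r} vs {field.country!r}")
    return MatchedPair(
        ref=ref, field=field, scenario=scenario,
        fallback=fallback, levels_climbed=levels_climbed,
    )


def build_cross_source_pairs(
    field_records: Sequence[SurveyEstimate],
    ref_records: Sequence[SurveyEstimate],
    allow_posterior: bool = True,
    max_climb: int | None = None,
) -> tuple[list[MatchedPair], list[dict]]:
    """Pair every field record with its best reference estimate.

    Returns ``(pairs, no_match_reports)``; a field record that finds no
    admissible reference contributes a report (with a reason) instead of
    being silently dropped. Reference candidates must share country, indicator
    and cohort tag with the field record; the cycle is chosen first (most
    recent prior, optional posterior fallback), then the geography is resolved
    within that cycle.
    """
    pairs: list[MatchedPair] = []
    reports: list[dict] = []

    def report(rec: SurveyEstimate, reason: str) -> None:
        reports.append(
            {
                "source_name": rec.source_name,
                "country": rec.country,
                "geo_path": ">".join(rec.geo_path),
                "year": rec.year,
                "indicator_id": rec.indicator_id,
                "reason": reason,
            }
        )

    for frec in field_records:
        cands = [
            r for r in ref_records
            if r.country == frec.country and r.cohort == frec.cohort
        ]
        if not cands:
            report(frec, "no reference data for country")
            continue
        year, fallback = select_reference_survey(frec.year, {r.year for r in cands})
        if fallback and not allow_posterior:
            report(frec, "only posterior reference cycles available")
            continue
        cycle = [r for r in cands if r.year == year and r.indicator_id == frec.indicator_id]
        if not cycle:
            report(frec, f"indicator absent from reference cycle {year}")
            continue
        try:
            path, lvl, climbed = resolve_geography(
                frec.geo_path, int(frec.geo_level), [(r.geo_path, int(r.geo_level)) for r in cycle]
            )
        except NoMatchError:
            report(frec, "no containing reference geography")
            continue
        if max_climb is not None and climbed > max_climb:
            report(frec, f"nearest reference geography is {climbed} levels up (max {max_climb})")
            continue
        matches = [r for r in cycle if r.geo_path == path and int(r.geo_level) == lvl]
        rrec = matches[0]
        if len(matches) > 1:
            logger.warning(
                "ambiguous reference match for %s at %s; using first of %d",
                frec.indicator_id, ">".join(path), len(matches),
            )
        pairs.append(
            derive_pair_metrics(
                rrec, frec, scenario="cross_source",
                fallback=fallback, levels_climbed=climbed,
            )
        )
    logger.info(
        "cross-source pairing: %d pairs, %d unmatched field records",
        len(pairs), len(reports),
    )
    return pairs, reports


def build_same_source_scenarios(
    records: Sequence[SurveyEstimate],
    s2_cycle: str = "earliest",
) -> list[MatchedPair]:
    """Build S1/S2/S3 pairs from one source's multi-cycle, multi-level records.

    The reference side always plays the public-data role (earlier cycle
    and/or higher level); the field side mimics the purpose-run survey (later
    cycle and/or lower level). Same-year-same-level pairs are never emitted.

    ``s2_cycle`` anchors the same-year comparisons (Scenario 2) at the
    "earliest" cycle (the default, matching the convention that the reference
    estimate pre-exists) or at "all" cycles.
    """
    if s2_cycle not in ("earliest", "all"):
        raise ValueError("s2_cycle must be 'earliest' or 'all'")
    pairs: list[MatchedPair] = []
    by_indicator: dict[tuple[str, str], list[SurveyEstimate]] = {}
    for r in records:
        by_indicator.setdefault((r.country, r.indicator_id), []).append(r)

    for recs in by_indicator.values():
        years = sorted({r.year for r in recs})
        # S1: same unit and level, earlier cycle as reference
        by_unit: dict[tuple[tuple[str, ...], int], list[SurveyEstimate]] = {}
        for r in recs:
            by_unit.setdefault((r.geo_path, int(r.geo_level)), []).append(r)
        for unit_recs in by_unit.values():
            unit_recs = sorted(unit_recs, key=lambda r: r.year)
            for i, ref in enumerate(unit_recs):
                for field in unit_recs[i + 1:]:
                    if field.year > ref.year:
                        pairs.append(derive_pair_metrics(ref, field, scenario="S1"))
        # S2: same cycle, higher-level unit vs strictly contained lower unit
        s2_years = years[:1] if s2_cycle == "earliest" else years
        for y in s2_years:
            cycle = [r for r in recs if r.year == y]
            for ref in cycle:
                for field in cycle:
                    if _contains(ref, field):
                        pairs.append(derive_pair_metrics(ref, field, scenario="S2"))
        # S3: earlier cycle higher level vs later cycle lower level
        for ref in recs:
            for field in recs:
                if field.year > ref.year and _contains(ref, field):
                    pairs.append(derive_pair_metrics(ref, field, scenario="S3"))
    logger.info(
        "same-source scenarios: %d pairs (S1=%d, S2=%d, S3=%d)",
        len(pairs),
        sum(p.scenario == "S1" for p in pairs),
        sum(p.scenario == "S2" for p in pairs),
        sum(p.scenario == "S3" for p in pairs),
    )
    return pairs


def _contains(higher: SurveyEstimate, lower: SurveyEstimate) -> bool:
    """True if ``higher`` is a strictly higher-level unit whose path prefixes
    ``lower``'s path (national units contain every subunit)."""
    if int(higher.geo_level) <= int(lower.geo_level):
        return False
    hp, lp = higher.geo_path, lower.geo_path
    return len(hp) < len(lp) and lp[: len(hp)] == hp


def pairs_to_frame(pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    """Tabular view of pairs with every derived metric as a column."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "country": p.field.country,
                "indicator_id": p.field.indicator_id,
                "scenario": p.scenario,
                "ref_source": p.ref.source_name,
                "field_source": p.field.source_name,
                "ref_geo": ">".join(p.ref.geo_path),
                "field_geo": ">".join(p.field.geo_path),
                "ref_level": int(p.ref.geo_level),
                "field_level": int(p.field.geo_level),
                "ref_year": p.ref.year,
                "field_year": p.field.year,
                "ref_season": p.ref.season,
                "field_season": p.field.season,
                "ref_n": p.ref.n,
                "field_n": p.field.n,
                "ref_estimate": p.ref.estimate,
                "field_estimate": p.field.estimate,
                "difference": p.difference,
                "abs_difference": p.abs_difference,
                "year_difference": p.year_difference,
                "abs_year_difference": p.abs_year_difference,
                "year_diff_band": p.year_diff_band,
                "level_difference": p.level_difference,
                "level_diff_band": p.level_diff_band,
                "season_concordance": p.season_concordance,
                "fallback": p.fallback,
                "levels_climbed": p.levels_climbed,
            }
        )
    columns = [
        "country", "indicator_id", "scenario", "ref_source", "field_source",
        "ref_geo", "field_geo", "ref_level", "field_level", "ref_year",
        "field_year", "ref_season", "field_season", "ref_n", "field_n",
        "ref_estimate", "field_estimate", "difference", "abs_difference",
        "year_difference", "abs_year_difference", "year_diff_band",
        "level_difference", "level_diff_band", "season_concordance",
        "fallback", "levels_climbed",
    ]
    return pd.DataFrame(rows, columns=columns)
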