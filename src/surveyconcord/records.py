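"""Record model, coding rules and CSV I/O for survey indicator estimates.

The atomic record is a :class:`SurveyEstimate`: one prevalence-type indicator
estimate (a percentage) produced by one survey source at one place and time.
Two kinds of source are distinguished: ``reference`` (large public household
surveys such as DHS or MICS) and ``field`` (smaller purpose-run surveys such
as NGO baselines). Estimates are kept on the percent scale (0-100) throughout,
matching how both kinds of report print them.

Geography is coded on a five-level administrative hierarchy:

1. village / town / locality / traditional authority
2. district (or equivalent)
3. province / state / department / county
4. region (a grouping of level-3 units)
5. country

A record's location is an ordered ``geo_path`` of place names from the country
downward; matching between sources works on these paths (see
:mod:`surveyconcord.pairs`).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("surveyconcord")

__all__ = [
    "GeoLevel",
    "SurveyEstimate",
    "IndicatorCatalog",
    "ValidationError",
    "parse_year",
    "render_year",
    "assign_geo_level",
    "filter_min_n",
    "validate_records",
    "read_estimates",
    "write_estimates",
    "records_to_frame",
    "DEFAULT_SYNONYMS",
    "CSV_COLUMNS",
    "MIN_N_DEFAULT",
    "YEAR_MIN",
    "YEAR_MAX",
]

MIN_N_DEFAULT = 10          # estimates on fewer observations are excluded
YEAR_MIN, YEAR_MAX = 1990.0, 2035.0   # plausibility window, not a hard model bound

GEO_PATH_SEP = ">"


class ValidationError(ValueError):
    """Raised when a record or table violates the schema invariants."""


class GeoLevel(enum.IntEnum):
    """Administrative aggregation level, 1 (smallest unit) to 5 (country)."""

    LOCALITY = 1
    DISTRICT = 2
    PROVINCE = 3
    REGION = 4
    COUNTRY = 5

    @property
    def label(self) -> str:
        return _LEVEL_LABELS[int(self)]


_LEVEL_LABELS = {
    1: "village/town/locality/traditional-authority",
    2: "district",
    3: "province/state/department/county",
    4: "region",
    5: "country",
}

#: Canonical unit-type name written back out per level (round-trip stable).
CANONICAL_UNIT_TYPE = {1: "village", 2: "district", 3: "province", 4: "region", 5: "country"}

#: Default unit-type -> level synonym map. "county" defaults to 3 (Liberia
#: usage); override per country where counties sit at level 2 (e.g. Kenya
#: post-2010) via the ``country_overrides`` argument of :func:`assign_geo_level`.
DEFAULT_SYNONYMS: dict[str, int] = {
    "village": 1,
    "town": 1,
    "locality": 1,
    "traditional authority": 1,
    "district": 2,
    "district council": 2,
    "local government area": 2,
    "upazila": 2,
    "commune": 2,
    "city": 2,
    "province": 3,
    "state": 3,
    "department": 3,
    "county": 3,
    "division": 3,
    "zone": 3,
    "region": 4,
    "country": 5,
    "national": 5,
}


def assign_geo_level(
    unit_type: str,
    country: str | None = None,
    synonyms: Mapping[str, int] | None = None,
    country_overrides: Mapping[str, Mapping[str, int]] | None = None,
) -> GeoLevel:
    """Map a free-text unit type ("district", "province", ...) to a GeoLevel.

    ``synonyms`` extends/overrides the default map; ``country_overrides``
    resolves unit types whose level differs by country (e.g. "county").
    """
    key = unit_type.strip().lower()
    if country_overrides and country:
        per_country = country_overrides.get(country, {})
        if key in {k.lower(): v for k, v in per_country.items()}:
            return GeoLevel({k.lower(): v for k, v in per_country.items()}[key])
    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    if key not in table:
        accepted = ", ".join(sorted(table))
        raise ValidationError(
            f"unknown geographic unit type {unit_type!r}; accepted synonyms: {accepted}"
        )
    return GeoLevel(table[key])


_YEAR_SINGLE = re.compile(r"^\s*(\d{4})\s*$")
_YEAR_SPAN = re.compile(r"^\s*(\d{4})\s*/\s*(\d{2}|\d{4})\s*$")


def parse_year(raw: str) -> float:
    """Decode a data-collection year label into a decimal year.

    A single year passes through ("2016" -> 2016.0). Collection spanning two
    consecutive calendar years is coded at the midpoint, first year + 0.5
    ("2013/14" -> 2013.5).
    """
    m = _YEAR_SINGLE.match(raw)
    if m:
        return float(m.group(1))
    m = _YEAR_SPAN.match(raw)
    if m:
        first = int(m.group(1))
        second_txt = m.group(2)
        second = int(second_txt) if len(second_txt) == 4 else (first // 100) * 100 + int(second_txt)
        if len(second_txt) == 2 and second < first:  # e.g. "1999/00"
            second += 100
        if second != first + 1:
            raise ValidationError(
                f"year span {raw!r} is not a pair of consecutive years"
            )
        return first + 0.5
    raise ValidationError(f"unparseable year label {raw!r}")


def render_year(year: float) -> str:
    """Inverse of :func:`parse_year` on its own output."""
    if float(year) == int(year):
        return str(int(year))
    if abs(year - (int(year) + 0.5)) < 1e-9:
        first = int(year)
        return f"{first}/{first + 1}"
    raise ValidationError(f"decimal year {year!r} is neither whole nor mid-coded (.5)")


@dataclass(frozen=True)
class SurveyEstimate:
    """One prevalence estimate from one source at one place and time."""

    source_kind: str              # "reference" or "field"
    source_name: str
    country: str
    geo_path: tuple[str, ...]     # place names, country first
    geo_level: GeoLevel
    year: float                   # decimal year, mid-coded for two-year spans
    season: str                   # free label, or "unknown"
    indicator_id: str
    n: int                        # observations behind the estimate
    estimate: float               # percent, 0-100
    sd: float | None = None       # percent, if reported
    cohort: str = ""              # tags reference extracts tailored to one field survey

    def key(self) -> tuple:
        """Uniqueness key within a validated table."""
        return (
            self.source_kind,
            self.source_name,
            self.geo_path,
            self.year,
            self.indicator_id,
            self.cohort,
        )

    def check(self) -> None:
        if self.source_kind not in ("reference", "field"):
            raise ValidationError(
                f"source_kind must be 'reference' or 'field', got {self.source_kind!r}"
            )
        if not (0.0 <= self.estimate <= 100.0):
            raise ValidationError(f"estimate {self.estimate} outside [0, 100]")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValidationError(f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")
        lvl = int(self.geo_level)
        if lvl not in (1, 2, 3, 4, 5):
            raise ValidationError(f"geo_level must be 1-5, got {self.geo_level}")
        depth = len(self.geo_path)
        if depth < 1 or any(not p for p in self.geo_path):
            raise ValidationError(f"malformed geo_path {self.geo_path!r}")
        if self.geo_path[0] != self.country:
            raise ValidationError(
                f"geo_path must start at the country: {self.geo_path!r} vs {self.country!r}"
            )
        # The path may skip intermediate tiers but cannot be deeper than the
        # hierarchy allows for the declared level.
        if lvl == 5:
            if depth != 1:
                raise ValidationError(f"country-level record must have depth-1 geo_path, got {self.geo_path!r}")
        elif not (2 <= depth <= 6 - lvl):
            raise ValidationError(
                f"geo_path depth {depth} inconsistent with level {lvl} for {self.geo_path!r}"
            )

    def render(self) -> dict:
        """One CSV row (see :data:`CSV_COLUMNS`)."""
        return {
            "source_kind": self.source_kind,
            "source_name": self.source_name,
            "country": self.country,
            "geo_path": GEO_PATH_SEP.join(self.geo_path),
            "geo_level_type": CANONICAL_UNIT_TYPE[int(self.geo_level)],
            "year_raw": render_year(self.year),
            "season": self.season,
            "indicator_id": self.indicator_id,
            "n": self.n,
            "estimate": self.estimate,
            "sd": "" if self.sd is None else self.sd,
            "cohort": self.cohort,
        }


CSV_COLUMNS = [
    "source_kind",
    "source_name",
    "country",
    "geo_path",
    "geo_level_type",
    "year_raw",
    "season",
    "indicator_id",
    "n",
    "estimate",
    "sd",
    "cohort",
]


def validate_records(records: Iterable[SurveyEstimate]) -> list[SurveyEstimate]:
    """Check every record's invariants and reject duplicate keys.

    Returns the records as a list; raises :class:`ValidationError` naming the
    offending row index on first failure.
    """
    out: list[SurveyEstimate] = []
    seen: dict[tuple, int] = {}
    for i, rec in enumerate(records):
        try:
            rec.check()
        except ValidationError as exc:
            raise ValidationError(f"record {i}: {exc}") from None
        k = rec.key()
        if k in seen:
            raise ValidationError(
                f"record {i} duplicates record {seen[k]} on key {k!r}"
            )
        seen[k] = i
        out.append(rec)
    return out


def filter_min_n(
    records: Sequence[SurveyEstimate], threshold: int = MIN_N_DEFAULT
) -> tuple[list[SurveyEstimate], list[SurveyEstimate]]:
    """Partition records into (retained, excluded) by minimum sample size.

    A record is excluded iff its n is strictly below ``threshold`` ("fewer
    than ten observations" at the default of 10; n = 10 is kept).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    retained = [r for r in records if r.n >= threshold]
    excluded = [r for r in records if r.n < threshold]
    logger.info(
        "filter_min_n: %d retained, %d excluded (n < %d)",
        len(retained), len(excluded), threshold,
    )
    return retained, excluded


def read_estimates(
    path: str | Path,
    synonyms: Mapping[str, int] | None = None,
    country_overrides: Mapping[str, Mapping[str, int]] | None = None,
    validate: bool = True,
) -> list[SurveyEstimate]:
    """Read a one-header-row CSV of estimates (columns per :data:`CSV_COLUMNS`).

    ``cohort`` and ``sd`` columns are optional; an empty or missing ``season``
    is coded "unknown".
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c not in ("sd", "cohort")]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            rec = SurveyEstimate(
                source_kind=d["source_kind"].strip(),
                source_name=d["source_name"].strip(),
                country=d["country"].strip(),
                geo_path=tuple(p.strip() for p in d["geo_path"].split(GEO_PATH_SEP)),
                geo_level=assign_geo_level(
                    d["geo_level_type"], d["country"].strip(), synonyms, country_overrides
                ),
                year=parse_year(d["year_raw"]),
                season=(d.get("season", "").strip() or "unknown"),
                indicator_id=d["indicator_id"].strip(),
                n=int(d["n"]),
                estimate=float(d["estimate"]),
                sd=float(d["sd"]) if d.get("sd", "").strip() else None,
                cohort=d.get("cohort", "").strip(),
            )
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
        records.append(rec)
    if validate:
        records = validate_records(records)
    logger.info("read %d records from %s", len(records), path)
    return records


def write_estimates(records: Sequence[SurveyEstimate], path: str | Path) -> None:
    """Write records as CSV; :func:`read_estimates` round-trips them exactly."""
    df = pd.DataFrame([r.render() for r in records], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def records_to_frame(records: Sequence[SurveyEstimate]) -> pd.DataFrame:
    """Tabular view of records for analysis (typed columns, not CSV text)."""
    return pd.DataFrame(
        {
            "source_kind": [r.source_kind for r in records],
            "source_name": [r.source_name for r in records],
            "country": [r.country for r in records],
            "geo_path": [GEO_PATH_SEP.join(r.geo_path) for r in records],
            "geo_level": [int(r.geo_level) for r in records],
            "year": [r.year for r in records],
            "season": [r.season for r in records],
            "indicator_id": [r.indicator_id for r in records],
            "n": [r.n for r in records],
            "estimate": [r.estimate for r in records],
            "sd": [r.sd for r in records],
            "cohort": [r.cohort for r in records],
        }
    )


@dataclass
class IndicatorCatalog:
    """indicator -> (subgroup, group) mapping with regrouping overrides.

    Indicators measuring the same concept (e.g. stunting in different age
    bands) share a subgroup; subgroups nest in broad groups (child
    anthropometry, WASH, ...). Overrides re-assign single indicators to their
    own subgroup when their behaviour diverges from the rest of the subgroup
    (e.g. diarrhoea at 0-5 months, car ownership among household assets).
    """

    entries: dict[str, tuple[str, str]] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        sub_to_group: dict[str, str] = {}
        for ind, (sub, grp) in self.entries.items():
            if sub in sub_to_group and sub_to_group[sub] != grp:
                raise ValidationError(
                    f"subgroup {sub!r} mapped to two groups ({sub_to_group[sub]!r}, {grp!r})"
                )
            sub_to_group[sub] = grp

    def subgroup_of(self, indicator_id: str) -> str:
        return self.entries[indicator_id][0]

    def group_of(self, indicator_id: str) -> str:
        return self.entries[indicator_id][1]

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self.entries

    def with_overrides(self, overrides: Sequence[tuple[str, str]]) -> "IndicatorCatalog":
        """Return a catalog with indicators re-assigned to new subgroups.

        The overridden indicator keeps its group.
        """
        entries = dict(self.entries)
        for ind, new_sub in overrides:
            if ind not in entries:
                raise ValidationError(f"override names unknown indicator {ind!r}")
            entries[ind] = (new_sub, entries[ind][1])
        return IndicatorCatalog(entries)

    @classmethod
    def from_csv(cls, path: str | Path, overrides_path: str | Path | None = None) -> "IndicatorCatalog":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("indicator_id", "subgroup_id", "group_id"):
            if col not in df.columns:
                raise ValidationError(f"{path}: catalog missing column {col!r}")
        cat = cls({r.indicator_id: (r.subgroup_id, r.group_id) for r in df.itertuples()})
        if overrides_path is not None:
            ov = pd.read_csv(overrides_path, dtype=str, keep_default_na=False)
            cat = cat.with_overrides(list(zip(ov["indicator_id"], ov["subgroup_id"])))
        return cat

    @classmethod
    def identity(cls, indicator_ids: Iterable[str], group_id: str = "all") -> "IndicatorCatalog":
        """Catalog in which every indicator is its own subgroup."""
        return cls({i: (i, group_id) for i in indicator_ids})
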