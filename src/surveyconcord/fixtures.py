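"""Packaged worked-example tables.

Two small fixtures ship with the package, transcribed from published survey
reports:

* ``anc_match_*`` — a cross-source matching example for the indicator
  "woman had 3+ antenatal-care visits during last pregnancy": 15 NGO-style
  field estimates from five countries and the DHS/MICS extracts they match,
  including posterior-cycle and level-up matches and composite geographies;
* ``zambia_anc_dhs`` — the same indicator from two Zambian DHS cycles
  (2013/14 and 2018) at province and national level, from which the
  same-source scenario builder derives 31 S1/S2/S3 pairs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .records import IndicatorCatalog, SurveyEstimate, read_estimates

__all__ = ["fixture_path", "anc_match_example", "zambia_scenario_example", "anc_catalog"]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    return Path(str(resources.files("surveyconcord") / "data" / name))


def anc_match_example() -> tuple[list[SurveyEstimate], list[SurveyEstimate]]:
    """(field_records, reference_records) of the cross-source matching example."""
    return (
        read_estimates(fixture_path("anc_match_field.csv")),
        read_estimates(fixture_path("anc_match_reference.csv")),
    )


def zambia_scenario_example() -> list[SurveyEstimate]:
    """Two DHS cycles of the Zambia 3+ ANC indicator (province + national)."""
    return read_estimates(fixture_path("zambia_anc_dhs.csv"))


def anc_catalog() -> IndicatorCatalog:
    return IndicatorCatalog.from_csv(fixture_path("anc_catalog.csv"))
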