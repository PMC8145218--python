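"""Pure-sampling-error model for the difference between two prevalence estimates.

Two surveys measuring the same true prevalence p with n respondents each
yield estimates p1 = B1/n and p2 = B2/n, with B1 and B2 independent
binomial(n, p) draws. The Monte-Carlo distribution of 100 x (p1 - p2)
(percentage points) quantifies how far apart two estimates can fall from
sampling error alone; its closed-form standard deviation is
100 x sqrt(2 p (1-p) / n).

Defaults follow the study conditions: a prevalence grid of
{1, 10, 20, ..., 90, 99}%, n = 500 per estimate, and 1,000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .concordance import BoxplotSummary, bin_by_reference_value, boxplot_summary

__all__ = [
    "SimulationConfig",
    "SimulatedDistribution",
    "simulate_difference_distribution",
    "analytic_sd",
    "ci_half_width",
    "compare_distributions",
    "max_upper_whisker",
    "DEFAULT_P_GRID",
]

DEFAULT_P_GRID: tuple[float, ...] = (0.01, 0.10, 0.20, 0.30, 0.40, 0.50,
                                     0.60, 0.70, 0.80, 0.90, 0.99)


@dataclass(frozen=True)
class SimulationConfig:
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    n: int = 500
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= p <= 1.0) for p in self.p_grid):
            raise ValueError("every p must lie in [0, 1]")
        if self.n < 1 or self.iterations < 1:
            raise ValueError("n and iterations must be positive")


@dataclass(frozen=True)
class SimulatedDistribution:
    """Signed differences (pp) between two simulated estimates at one p."""

    p: float
    differences: np.ndarray          # length = iterations, percentage points

    @property
    def abs_differences(self) -> np.ndarray:
        return np.abs(self.differences)

    @property
    def boxplot(self) -> BoxplotSummary:
        return boxplot_summary(self.abs_differences)


def simulate_difference_distribution(config: SimulationConfig) -> list[SimulatedDistribution]:
    """Run the two-estimate binomial simulation at every grid prevalence.

    One root seed; each p gets an independent child stream, so results for a
    given p do not depend on the rest of the grid.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.p_grid))
    out = []
    for p, child in zip(config.p_grid, children):
        rng = np.random.default_rng(child)
        b1 = rng.binomial(config.n, p, size=config.iterations)
        b2 = rng.binomial(config.n, p, size=config.iterations)
        diffs = 100.0 * (b1 - b2) / config.n
        out.append(SimulatedDistribution(p=p, differences=diffs))
    return out


def analytic_sd(p: float, n: int) -> float:
    """Closed-form SD (pp) of the difference of two independent proportions."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 100.0 * float(np.sqrt(2.0 * p * (1.0 - p) / n))


def ci_half_width(se: float, level: float = 0.95) -> float:
    """Normal-approximation confidence-interval half-width, same units as se.

    At the default 95% level this is 1.96 x se (an estimate with a standard
    error of 5 points has a CI of +/- 9.8 points).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return float(z * se)


def _summary_row(series: str, key: str, bs: BoxplotSummary) -> dict:
    return {
        "series": series,
        "band": key,
        "n": bs.n,
        "median": bs.median,
        "q1": bs.q1,
        "q3": bs.q3,
        "lower_whisker": bs.lower_whisker,
        "upper_whisker": bs.upper_whisker,
        "n_outliers": bs.n_outliers,
    }


def compare_distributions(
    sim: Sequence[SimulatedDistribution],
    observed: Mapping[str, pd.DataFrame] | None = None,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Align simulated and observed absolute-difference box summaries.

    The simulated series is keyed by each grid prevalence's reference band
    (its true prevalence on the percent scale); each observed pair table is
    binned by reference estimate with the same band rule, giving directly
    comparable rows per band and series.
    """
    rows = []
    for dist in sim:
        ref_value = 100.0 * dist.p
        lo = min(np.floor(ref_value / bin_width) * bin_width, 100.0 - bin_width)
        label = f"[{lo:g},{lo + bin_width:g})" if lo + bin_width < 100 else f"[{lo:g},100]"
        rows.append(_summary_row("simulation", label, dist.boxplot))
    for name, pairs in (observed or {}).items():
        binned = bin_by_reference_value(pairs, bin_width)
        for band, g in binned.groupby("ref_band", sort=True):
            rows.append(_summary_row(name, band, boxplot_summary(g["abs_difference"].to_numpy())))
    return pd.DataFrame(rows)


def max_upper_whisker(sim: Sequence[SimulatedDistribution]) -> float:
    """Largest Tukey upper whisker of |difference| across the grid (pp)."""
    return max(d.boxplot.upper_whisker for d in sim)
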