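"""Descriptive concordance summaries over matched estimate pairs.

All functions operate on the pair table produced by
:func:`surveyconcord.pairs.pairs_to_frame`. Conventions fixed here and used
everywhere:

* sample standard deviations (n-1 denominator), reported as missing for a
  single observation;
* quantiles by linear interpolation (numpy's default), which the median and
  IQR columns inherit;
* box plots follow the Tukey convention — whiskers at the furthest points
  within 1.5 x IQR of the quartiles, everything beyond counted as outliers;
* "within k" concordance counts pairs with |difference| <= k percentage
  points (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import IndicatorCatalog

__all__ = [
    "BoxplotSummary",
    "within_band_proportion",
    "summarize_subgroups",
    "summarize_strata",
    "boxplot_summary",
    "bin_by_reference_value",
    "reference_band_summary",
    "STRATA_SCHEMES",
]


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number Tukey box-plot summary of a value set."""

    median: float
    q1: float
    q3: float
    lower_whisker: float
    upper_whisker: float
    n_outliers: int
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def within_band_proportion(pairs: pd.DataFrame, k: float) -> float:
    """Percent of pairs whose absolute difference is at most k points."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(pairs) == 0:
        raise ValueError("within-band proportion undefined on an empty pair set")
    return 100.0 * float((pairs["abs_difference"] <= k).mean())


def _sd(x: pd.Series) -> float:
    return float(x.std(ddof=1)) if len(x) > 1 else float("nan")


def summarize_subgroups(
    pairs: pd.DataFrame,
    catalog: IndicatorCatalog,
    within_k: Sequence[float] = (5.0, 20.0),
) -> pd.DataFrame:
    """Per-subgroup difference summary (one row per subgroup present).

    Columns: pair count, mean/SD of each side's estimates, mean/SD/min/max of
    the signed difference, and percent of pairs within each ``within_k``
    threshold.
    """
    missing = sorted(set(pairs["indicator_id"]) - {i for i in pairs["indicator_id"] if i in catalog})
    if missing:
        raise KeyError(f"indicators not in catalog: {missing}")
    df = pairs.assign(subgroup=[catalog.subgroup_of(i) for i in pairs["indicator_id"]])
    rows = []
    for sub, g in df.groupby("subgroup", sort=True):
        row = {
            "subgroup_id": sub,
            "group_id": catalog.group_of(g["indicator_id"].iloc[0]),
            "n_pairs": len(g),
            "ref_mean": float(g["ref_estimate"].mean()),
            "ref_sd": _sd(g["ref_estimate"]),
            "field_mean": float(g["field_estimate"].mean()),
            "field_sd": _sd(g["field_estimate"]),
            "diff_mean": float(g["difference"].mean()),
            "diff_sd": _sd(g["difference"]),
            "diff_min": float(g["difference"].min()),
            "diff_max": float(g["difference"].max()),
        }
        for k in within_k:
            row[f"pct_within_{k:g}"] = within_band_proportion(g, k)
        rows.append(row)
    return pd.DataFrame(rows)


#: stratification schemes accepted by :func:`summarize_strata`
STRATA_SCHEMES = ("year_band", "season", "level_band", "geo_level", "size_tertile")


def _tertile_labels(n_values: np.ndarray) -> np.ndarray:
    """Rank-based thirds of the member sample sizes (stable ties)."""
    order = np.argsort(n_values, kind="stable")
    labels = np.empty(len(n_values), dtype=object)
    for t, chunk in enumerate(np.array_split(order, 3), start=1):
        labels[chunk] = f"Tertile {t}"
    return labels


def summarize_strata(
    pairs: pd.DataFrame,
    scheme: str,
    member: str = "ref",
) -> pd.DataFrame:
    """Absolute-difference summary stratified by a pair-level covariate.

    ``scheme`` is one of :data:`STRATA_SCHEMES`:

    * ``year_band`` — unsigned year gap bands <=1, 1.5-3, >=3.5;
    * ``season`` — same / different / unknown season concordance;
    * ``level_band`` — level-difference bands 0, 1, 2+;
    * ``geo_level`` — the ``member`` side's own geographic level;
    * ``size_tertile`` — rank-based thirds of the ``member`` side's n
      computed over this pair set (Tertile 1 = smallest samples).

    Returns one row per stratum with N, mean, SD, median and IQR of the
    absolute difference (percentage points). Strata with no members are
    reported with N = 0 for exhaustive categorical schemes.
    """
    if scheme not in STRATA_SCHEMES:
        raise ValueError(f"scheme must be one of {STRATA_SCHEMES}")
    if member not in ("ref", "field"):
        raise ValueError("member must be 'ref' or 'field'")
    df = pairs.copy()
    expected: list | None = None
    if scheme == "year_band":
        df["stratum"] = df["year_diff_band"]
        expected = ["<=1", "1.5-3", ">=3.5"]
    elif scheme == "season":
        df["stratum"] = df["season_concordance"]
        expected = ["same", "different", "unknown"]
    elif scheme == "level_band":
        df["stratum"] = df["level_diff_band"]
        expected = ["0", "1", "2+"]
    elif scheme == "geo_level":
        df["stratum"] = df[f"{member}_level"].astype(str)
    else:  # size_tertile
        df["stratum"] = _tertile_labels(df[f"{member}_n"].to_numpy())
    rows = []
    labels = expected if expected is not None else sorted(df["stratum"].unique())
    for label in labels:
        vals = df.loc[df["stratum"] == label, "abs_difference"]
        if len(vals):
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "scheme": scheme,
                    "stratum": label,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": _sd(vals),
                    "median": float(med),
                    "iqr": float(q3 - q1),
                }
            )
        else:
            rows.append(
                {"scheme": scheme, "stratum": label, "n": 0,
                 "mean": float("nan"), "sd": float("nan"),
                 "median": float("nan"), "iqr": float("nan")}
            )
    return pd.DataFrame(rows)


def boxplot_summary(values: Sequence[float] | np.ndarray) -> BoxplotSummary:
    """Tukey box-plot summary (linear-interpolation quartiles)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("boxplot summary undefined on empty values")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        lower_whisker=float(inside.min()),
        upper_whisker=float(inside.max()),
        n_outliers=int(((x < lo_fence) | (x > hi_fence)).sum()),
        n=int(x.size),
    )


def bin_by_reference_value(pairs: pd.DataFrame, width: float = 10.0) -> pd.DataFrame:
    """Assign each pair to the reference-estimate band containing it.

    Bands are half-open ``[lo, lo + width)`` except the top band, which is
    closed at 100. Returns the pair table with added ``ref_band`` (label) and
    ``ref_band_lo`` columns.
    """
    if not np.isclose(100.0 / width, round(100.0 / width)):
        raise ValueError("bin width must divide 100")
    lo = np.minimum(np.floor(pairs["ref_estimate"] / width) * width, 100.0 - width)
    labels = [f"[{a:g},{a + width:g})" if a + width < 100 else f"[{a:g},100]" for a in lo]
    return pairs.assign(ref_band_lo=lo, ref_band=labels)


def reference_band_summary(pairs: pd.DataFrame, width: float = 10.0) -> pd.DataFrame:
    """Box-plot summary of absolute differences per reference-value band."""
    binned = bin_by_reference_value(pairs, width)
    rows = []
    for (lo, label), g in binned.groupby(["ref_band_lo", "ref_band"], sort=True):
        bs = boxplot_summary(g["abs_difference"].to_numpy())
        rows.append(
            {
                "ref_band": label,
                "ref_band_lo": lo,
                "n": bs.n,
                "median": bs.median,
                "q1": bs.q1,
                "q3": bs.q3,
                "lower_whisker": bs.lower_whisker,
                "upper_whisker": bs.upper_whisker,
                "n_outliers": bs.n_outliers,
            }
        )
    return pd.DataFrame(rows)


def plot_reference_bands(summaries: dict[str, pd.DataFrame], path: str) -> None:
    """Write a side-by-side box-plot figure of abs differences by reference band.

    ``summaries`` maps a series label (e.g. "simulation", "cross-source") to a
    :func:`reference_band_summary` table. Matplotlib is imported lazily; the
    analysis core does not require it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 5))
    series = list(summaries)
    n_series = len(series)
    for si, name in enumerate(series):
        tab = summaries[name]
        for _, row in tab.iterrows():
            x = row["ref_band_lo"] + 10.0 * (si + 1) / (n_series + 1)
            stats = {
                "med": row["median"], "q1": row["q1"], "q3": row["q3"],
                "whislo": row["lower_whisker"], "whishi": row["upper_whisker"],
                "fliers": [],
            }
            ax.bxp([stats], positions=[x], widths=8.0 / (n_series + 1),
                   showfliers=False, boxprops={"color": f"C{si}"},
                   whiskerprops={"color": f"C{si}"}, capprops={"color": f"C{si}"},
                   medianprops={"color": f"C{si}"})
        ax.plot([], [], color=f"C{si}", label=name)
    ax.set_xlabel("reference estimate band (%)")
    ax.set_ylabel("absolute difference (pp)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
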