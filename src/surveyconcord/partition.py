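"""Sequential (Type I) variance partition of pair differences.

The variance of the (signed or absolute) difference between matched estimates
is decomposed into shares attributable to a fixed, ordered list of factors —
by default indicator, geographic-level-difference band, year difference
(linear, continuous) and season concordance — plus an unattributed residual.

Each factor's share is the increase in explained (regression) sum of squares
when its columns are appended to the design matrix, divided by the total
corrected sum of squares. Because Type I contributions are squared norms of
orthogonal projections, shares are non-negative and sum with the residual to
exactly 100. The decomposition depends on the entry order unless the factors
are mutually orthogonal; the order is therefore recorded in the result.

Rank-deficient augmentations (a factor collinear with those already entered,
including single-level categorical factors) contribute a share of exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariancePartition",
    "partition_variance",
    "one_way_oracle",
    "CROSS_SOURCE_FACTORS",
    "SAME_SOURCE_FACTORS",
]

#: default factor order for cross-source (field vs reference) partitions
CROSS_SOURCE_FACTORS: tuple[tuple[str, str], ...] = (
    ("indicator_id", "categorical"),
    ("level_diff_band", "categorical"),
    ("year_difference", "continuous"),
    ("season_concordance", "categorical"),
)

#: same-source (scenario) partitions omit season: within one country a single
#: public survey programme collects in essentially one season, so the factor
#: is degenerate there.
SAME_SOURCE_FACTORS: tuple[tuple[str, str], ...] = (
    ("indicator_id", "categorical"),
    ("level_diff_band", "categorical"),
    ("year_difference", "continuous"),
)


@dataclass(frozen=True)
class VariancePartition:
    """Percent of difference variance attributed to each factor, in order."""

    response: str
    factors: tuple[tuple[str, str], ...]     # (name, "categorical" | "continuous")
    shares: dict[str, float]                 # percent of total corrected SS
    residual_share: float                    # percent unattributed ("Other")
    n: int

    def to_frame(self) -> pd.DataFrame:
        row = {"response": self.response, "n": self.n}
        row.update({name: self.shares[name] for name, _ in self.factors})
        row["other"] = self.residual_share
        return pd.DataFrame([row])


def _encode(col: pd.Series, kind: str) -> np.ndarray:
    """Design-matrix columns for one factor (intercept excluded).

    Categorical factors use full-rank treatment contrasts with the first
    (sorted) level as reference; shares are invariant to the encoding since
    only the column span matters.
    """
    if kind == "continuous":
        return col.to_numpy(dtype=float).reshape(-1, 1)
    if kind == "categorical":
        dummies = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
        return dummies.to_numpy() if dummies.shape[1] else np.empty((len(col), 0))
    raise ValueError(f"factor kind must be 'categorical' or 'continuous', got {kind!r}")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def partition_variance(
    pairs: pd.DataFrame,
    response: str = "difference",
    factors: Sequence[tuple[str, str]] = CROSS_SOURCE_FACTORS,
) -> VariancePartition:
    """Sequential ANOVA partition of ``response`` over the ordered factors.

    ``pairs`` is a pair table (see :func:`surveyconcord.pairs.pairs_to_frame`);
    ``response`` is typically "difference" or "abs_difference". Raises
    ``ValueError`` if fewer than two pairs are given or the response is
    constant (zero total sum of squares).
    """
    if len(pairs) < 2:
        raise ValueError("variance partition requires at least two pairs")
    y = pairs[response].to_numpy(dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0.0:
        raise ValueError("response is constant: total sum of squares is zero")
    X = np.ones((len(y), 1))
    rss_prev = _rss(X, y)   # == tss
    shares: dict[str, float] = {}
    for name, kind in factors:
        if name not in pairs.columns:
            raise KeyError(f"factor column {name!r} not in pair table")
        X = np.hstack([X, _encode(pairs[name], kind)])
        rss_new = _rss(X, y)
        shares[name] = max(0.0, (rss_prev - rss_new) / tss * 100.0)
        rss_prev = rss_new
    residual = rss_prev / tss * 100.0
    # projections guarantee additivity; renormalise away float dust only
    total = sum(shares.values()) + residual
    residual += 100.0 - total
    return VariancePartition(
        response=response,
        factors=tuple(factors),
        shares=shares,
        residual_share=residual,
        n=len(y),
    )


def one_way_oracle(values: Sequence[float], labels: Sequence) -> float:
    """Brute-force one-way between-group share: SS_between / SS_total x 100.

    Computed directly from group means; used as an independent check that a
    single-categorical-factor partition equals the classical one-way ANOVA
    decomposition.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two values")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0.0:
        raise ValueError("values are constant: total sum of squares is zero")
    labels = np.asarray(labels)
    ss_between = 0.0
    for lab in np.unique(labels):
        g = y[labels == lab]
        ss_between += g.size * (g.mean() - y.mean()) ** 2
    return ss_between / tss * 100.0
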