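"""Descriptive and post-fit statistics for small-area suicide mapping.

Standardized mortality/hospitalization ratios, predicted relative risks
at construct-score percentiles (with high/low ratios computed from
unrounded values), SHR profiles over equal-count score categories,
decile cross-tabulations of fitted risks between outcomes, and simple
rate-ratio arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constructs import ConstructScore

__all__ = [
    "PercentileRiskTable",
    "smr",
    "rr_at_percentiles",
    "shr_by_score_categories",
    "decile_crosstab",
    "rate_ratio_summary",
    "overall_smr",
]


def smr(observed: float, expected: float) -> float:
    """Standardized mortality (or hospitalization) ratio, 100 x O/E."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    return 100.0 * observed / expected


def overall_smr(observed: np.ndarray, expected: np.ndarray) -> float:
    """Whole-region SMR: 100 x sum(observed) / sum(expected)."""
    return smr(float(np.sum(observed)), float(np.sum(expected)))


@dataclass(frozen=True)
class PercentileRiskTable:
    """Relative risks at score percentiles for one covariate effect.

    ``ratio`` divides the RR at the highest requested percentile by the
    RR at the lowest, computed from unrounded values (printed tables
    round only at display).
    """

    percentiles: tuple[float, ...]
    relative_risks: np.ndarray
    ratio: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"percentile": self.percentiles, "relative_risk": self.relative_risks}
        )


def _empirical_percentile(score: np.ndarray, q: float) -> float:
    """Nearest-rank empirical inverse CDF."""
    return float(np.percentile(score, q, method="inverted_cdf"))


def rr_at_percentiles(
    effect: float | Callable[[np.ndarray], np.ndarray],
    score: ConstructScore | np.ndarray,
    percentiles: Sequence[float] = (5.0, 95.0),
) -> PercentileRiskTable:
    """Predicted relative risk at empirical percentiles of a score.

    A scalar ``effect`` is a linear log-risk slope: RR(q) = exp(beta *
    x_q).  A callable is a fitted nonlinear curve f; its population-mean
    log-risk contribution is removed first, so RR(q) = exp(f(x_q) -
    mean f(x)), making the table invariant to the curve's centering
    constant.
    """
    ps = tuple(float(p) for p in percentiles)
    if any(not 0.0 < p < 100.0 for p in ps):
        raise ValueError("percentiles must lie strictly inside (0, 100)")
    if list(ps) != sorted(ps):
        raise ValueError("percentiles must be ascending")
    x = score.score if isinstance(score, ConstructScore) else np.asarray(score, float)
    xq = np.array([_empirical_percentile(x, p) for p in ps])
    if callable(effect):
        f_pop = np.asarray(effect(x), dtype=np.float64)
        log_rr = np.asarray(effect(xq), dtype=np.float64) - f_pop.mean()
    else:
        log_rr = float(effect) * xq
    rr = np.exp(log_rr)
    return PercentileRiskTable(ps, rr, float(rr[-1] / rr[0]))


def shr_by_score_categories(
    observed: np.ndarray,
    expected: np.ndarray,
    score: ConstructScore | np.ndarray,
    n_categories: int = 20,
) -> pd.DataFrame:
    """Observed SHR profile over equal-count score categories.

    Areas are ranked by score and split into ``n_categories`` groups of
    equal size (any remainder spread one area at a time over the lowest
    categories); category 1 holds the lowest scores.  Each category's
    SHR is 100 x sum(observed) / sum(expected), so the expected-count
    weighted average over categories reproduces the overall SHR exactly.
    """
    y = np.asarray(observed, dtype=np.float64)
    e = np.asarray(expected, dtype=np.float64)
    x = score.score if isinstance(score, ConstructScore) else np.asarray(score, float)
    n = y.size
    if n_categories < 2:
        raise ValueError("need at least two categories")
    if n < n_categories:
        raise ValueError("fewer areas than categories")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, n_categories)
    sizes = np.full(n_categories, base, dtype=np.int64)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rows = []
    for c in range(n_categories):
        idx = order[bounds[c] : bounds[c + 1]]
        rows.append(
            dict(
                category=c + 1,
                n_areas=idx.size,
                observed=float(y[idx].sum()),
                expected=float(e[idx].sum()),
                shr=smr(float(y[idx].sum()), float(e[idx].sum())),
            )
        )
    return pd.DataFrame(rows).set_index("category")


def _decile_labels(values: np.ndarray) -> np.ndarray:
    """Rank into deciles 0..9, ties broken by stable original order.

    The first ``n - 9 * floor(n/10) - ...`` sizing follows equal splits:
    with n = 10q + r, the first 10 - r deciles get q areas and the last
    r deciles get q + 1 (so for n = 6781 the margins are nine 678s and
    one 679, the published layout).
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    q, r = divmod(n, 10)
    sizes = np.full(10, q, dtype=np.int64)
    sizes[10 - r :] += 1
    labels = np.empty(n, dtype=np.int64)
    labels[order] = np.repeat(np.arange(10), sizes)
    return labels


def decile_crosstab(risk_a: np.ndarray, risk_b: np.ndarray) -> pd.DataFrame:
    """10 x 10 overlap table of risk deciles between two outcomes.

    Cell (i, j) counts areas in decile i of ``risk_a`` and decile j of
    ``risk_b``; decile 1 is lowest risk.  Margins reproduce the decile
    sizes exactly.
    """
    a = np.asarray(risk_a, dtype=np.float64)
    b = np.asarray(risk_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("risk vectors must be equal-length 1-D arrays")
    if a.size < 10:
        raise ValueError("need at least 10 areas for deciles")
    la, lb = _decile_labels(a), _decile_labels(b)
    table = np.zeros((10, 10), dtype=np.int64)
    np.add.at(table, (la, lb), 1)
    idx = [f"decile_{i + 1}" for i in range(10)]
    return pd.DataFrame(table, index=idx, columns=idx)


def rate_ratio_summary(rate_a: float, rate_b: float) -> float:
    """Ratio of event rate b to event rate a (e.g. self-harm : suicide)."""
    if rate_a <= 0 or rate_b <= 0:
        raise ValueError("rates must be positive")
    return rate_b / rate_a
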