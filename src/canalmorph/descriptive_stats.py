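"""Linear summary statistics for replicated measurement panels.

Means, sample standard deviations and two-sided t confidence intervals for
replicated lumen-diameter measurements, plus cross-specimen ranges of the
per-specimen means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import CanalmorphError, InsufficientDataError


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD, SE and a t-based confidence interval."""

    n: int
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def summarize(values: Sequence[float], alpha: float = 0.05) -> SummaryStats:
    """Mean, Bessel-corrected SD, SE = sd/sqrt(n), and the two-sided
    t-distribution CI with n-1 degrees of freedom.

    Rounding is left to report time; all fields are full precision.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {x.size}")
    if not (0.0 < alpha < 1.0):
        raise CanalmorphError(f"alpha must be in (0, 1), got {alpha}")
    n = int(x.size)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(n)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    return SummaryStats(
        n=n,
        mean=mean,
        sd=sd,
        se=float(se),
        ci_low=mean - t_crit * se,
        ci_high=mean + t_crit * se,
        alpha=alpha,
    )


def cross_specimen_range(
    per_specimen_means: Sequence[float],
) -> tuple[float, float, float]:
    """(min, max, grand mean) of per-specimen means, each specimen weighted once."""
    x = np.asarray(per_specimen_means, dtype=float)
    if x.size == 0:
        raise CanalmorphError("need at least one per-specimen mean")
    return float(x.min()), float(x.max()), float(x.mean())
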