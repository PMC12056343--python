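"""Active/inactive classification of 3-min slots and window activity levels.

A slot is 'active' when the site-averaged signal differential exceeds the
10 dB movement threshold, 'inactive' when it is at or below it (equality is
resolved to inactive as the conservative completion of the two strict
published clauses), and 'unscored' when the differential is missing.
Activity levels are the proportion of scored slots classified active in the
fixed diurnal (10:00-16:00) and nocturnal (22:00-02:00) windows; a bird-day
window is retained only when at least 50% of its slots were scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import DifferentialSeries

__all__ = ["ACTIVE_THRESHOLD_DB", "ActivityLevel", "classify_active", "activity_proportion"]

#: Signal-differential movement threshold (dB).
ACTIVE_THRESHOLD_DB = 10.0

#: Minimum scored fraction of the window (inclusive).
LEVEL_COVERAGE = 0.5


@dataclass
class ActivityLevel:
    """Activity-level counts for one bird-day window."""

    bird_id: str
    date: object
    window: str                 # 'diurnal' | 'nocturnal'
    n_scored: int
    n_active: int
    window_coverage: float
    status: str = "scored"      # 'scored' | 'low_coverage'

    @property
    def proportion(self) -> Optional[float]:
        return self.n_active / self.n_scored if self.n_scored else None


def classify_active(d_t: float, threshold: float = ACTIVE_THRESHOLD_DB) -> str:
    """'active' iff d_t > threshold; 'inactive' iff d_t <= threshold; NaN -> 'unscored'."""
    if d_t is None or (isinstance(d_t, float) and math.isnan(d_t)):
        return "unscored"
    return "active" if d_t > threshold else "inactive"


def activity_proportion(
    series: DifferentialSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    window_name: str,
    date,
    *,
    threshold: float = ACTIVE_THRESHOLD_DB,
    interval_s: int = 180,
) -> ActivityLevel:
    """Counts of active vs scored slots in one window for one bird-day.

    The record is marked ``low_coverage`` (and should be excluded from
    modelling) when fewer than 50% of the window's slots were scored.
    Proportions are computed over scored slots only, so missingness never
    masquerades as inactivity; the raw counts are retained because the
    binomial models consume counts, not ratios.
    """
    start, end = window
    n_total = int(round((end - start).total_seconds() / interval_s))
    if n_total <= 0:
        raise ValueError("window is empty")
    sel = series.data.loc[(series.grid >= start) & (series.grid < end), "d_site"]
    scored = sel.dropna()
    n_scored = int(scored.size)
    n_active = int((scored.to_numpy() > threshold).sum())
    coverage = n_scored / n_total
    return ActivityLevel(
        bird_id=series.bird_id,
        date=date,
        window=window_name,
        n_scored=n_scored,
        n_active=n_active,
        window_coverage=coverage,
        status="scored" if coverage >= LEVEL_COVERAGE else "low_coverage",
    )
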