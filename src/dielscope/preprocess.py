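"""Raw detections -> per-bird 3-min signal-differential series.

The signal differential d_t = |s_t - s_{t-1}| is computed per receiver, only
when both slots of the pair were detected on that receiver (gaps are never
differenced across), and then averaged across the receivers of the bird's
site that have a defined pair at t.  Slots with no defined pair on any
receiver are missing, not zero: imputing zeros would fabricate inactivity.

Timestamps are snapped to the scan grid by flooring to the 180-s boundary
(receivers scan tags sequentially, so raw stamps jitter within a slot).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DetectionFormatError",
    "DifferentialSeries",
    "read_detections",
    "compute_signal_differential",
    "window_coverage",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("tag_id", "receiver_id", "timestamp", "signal_dB")


class DetectionFormatError(ValueError):
    """The detections table is structurally unusable (e.g. missing columns)."""


def snap_to_grid(ts: pd.Series, interval_s: int = 180) -> pd.Series:
    """Floor timezone-aware timestamps to the scan-interval boundary (in UTC)."""
    epoch = ts.astype("int64") // 10**9
    snapped = (epoch // interval_s) * interval_s
    out = pd.to_datetime(snapped, unit="s", utc=True)
    if isinstance(ts.dtype, pd.DatetimeTZDtype):
        out = out.dt.tz_convert(ts.dt.tz)
    return out


def read_detections(path: str | Path, interval_s: int = 180) -> pd.DataFrame:
    """Read and normalise a raw detections CSV.

    Returns records sorted by (tag, receiver, time) with timestamps snapped
    to the scan grid.  Duplicate (tag, receiver, slot) rows collapse to the
    strongest (largest) signal.  Malformed rows (unparseable timestamp or
    non-numeric/missing signal) are dropped, counted and logged.

    Raises
    ------
    DetectionFormatError
        if a required column is absent.
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "receiver_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DetectionFormatError(f"detections file {path} missing columns {missing}")
    n_raw = len(df)
    if n_raw == 0:
        log.warning("detections file %s is empty", path)
        return df.assign(slot=pd.Series([], dtype="datetime64[ns, UTC]"))

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    sig = pd.to_numeric(df["signal_dB"], errors="coerce")
    bad = ts.isna() | ~np.isfinite(sig)
    if bad.any():
        log.warning("dropped %d malformed detection rows from %s", int(bad.sum()), path)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["signal_dB"] = sig[~bad]
    df["slot"] = snap_to_grid(df["timestamp"], interval_s)
    # duplicate (tag, receiver, slot): keep the strongest signal
    df = (
        df.sort_values("signal_dB")
        .drop_duplicates(["tag_id", "receiver_id", "slot"], keep="last")
        .sort_values(["tag_id", "receiver_id", "timestamp"])
        .reset_index(drop=True)
    )
    return df


@dataclass
class DifferentialSeries:
    """Site-averaged absolute signal differentials for one bird.

    ``data`` is indexed by the strict 3-min slot grid spanning the bird's
    detection range, with columns ``d_site`` (mean over receivers with a
    defined consecutive pair; NaN when none), ``n_receivers`` (count of
    contributing receivers) and one column per receiver with that
    receiver's own differential.
    """

    bird_id: str
    site_id: str
    data: pd.DataFrame
    receivers: list[str]

    @property
    def grid(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def d_site(self) -> pd.Series:
        return self.data["d_site"]


def compute_signal_differential(
    records: pd.DataFrame,
    bird_id: str,
    site_id: str,
    *,
    interval_s: int = 180,
    tz: str | None = None,
) -> DifferentialSeries:
    """Per-receiver and site-averaged |signal differential| series for one bird.

    ``records`` must carry a ``slot`` column (from :func:`read_detections`).
    Per receiver r, d_t^r is defined only when slots t and t-1 were both
    detected on r; the site value is the mean over receivers with a defined
    d_t^r and missing when there is none.
    """
    sub = records.loc[records["tag_id"] == bird_id]
    if sub.empty:
        raise KeyError(f"no detections for bird {bird_id!r}")

    pivot = sub.pivot_table(index="slot", columns="receiver_id", values="signal_dB",
                            aggfunc="max")
    if tz is not None:
        pivot.index = pivot.index.tz_convert(tz)
    step = pd.Timedelta(seconds=interval_s)
    grid = pd.date_range(pivot.index.min(), pivot.index.max(), freq=step)
    pivot = pivot.reindex(grid)

    # adjacent-slot differences only; a gap (NaN on either side) breaks the pair
    diffs = pivot.diff().abs()
    diffs.iloc[0] = np.nan
    receivers = list(pivot.columns)
    out = pd.DataFrame(index=grid)
    for r in receivers:
        out[f"d_{r}"] = diffs[r]
    out["d_site"] = diffs.mean(axis=1, skipna=True)
    out["n_receivers"] = diffs.notna().sum(axis=1)
    return DifferentialSeries(bird_id=bird_id, site_id=site_id, data=out, receivers=receivers)


def window_coverage(
    series: DifferentialSeries,
    window: tuple[pd.Timestamp, pd.Timestamp],
    *,
    interval_s: int = 180,
) -> float:
    """Fraction of grid slots in [start, end) with a non-missing site differential.

    Slots outside the series' observed span count as missing; the
    denominator is always the full window length in slots.
    """
    start, end = window
    n_total = int(round((end - start).total_seconds() / interval_s))
    if n_total <= 0:
        raise ValueError("window is empty")
    sel = series.data.loc[(series.grid >= start) & (series.grid < end), "d_site"]
    return float(sel.notna().sum()) / n_total
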