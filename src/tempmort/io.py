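"""Reading, writing and validation of daily mortality/temperature series.

Input tables are delimited text (CSV, UTF-8) with a header row
``date,deaths,tmean``.  Death counts suppressed for data protection
(observed counts below three individuals are withheld at source) appear as
empty cells and are carried through as an explicit missing marker (NaN) —
never as zero, since zero is a legal observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionRegistry

log = logging.getLogger(__name__)


@dataclass
class DailySeries:
    """One region's daily all-cause death counts and mean temperatures.

    ``deaths`` is a float array where NaN marks a suppressed (missing)
    count; all non-missing values are non-negative integers.  Dates are
    consecutive calendar days with no gaps.
    """

    region_id: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    tmean: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.tmean = np.asarray(self.tmean, dtype=float)
        n = len(self.dates)
        if len(self.deaths) != n or len(self.tmean) != n:
            raise ValueError("dates, deaths and tmean must have equal length")
        if n == 0:
            raise ValueError("empty series")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        bad = np.nonzero(deltas != 1)[0]
        if bad.size:
            offending = self.dates[bad[0] + 1].date()
            kind = "duplicate or out-of-order" if deltas[bad[0]] <= 0 else "gap before"
            raise ValueError(f"dates must be consecutive calendar days: {kind} date {offending}")
        obs = self.deaths[np.isfinite(self.deaths)]
        if np.any(obs < 0):
            raise ValueError("death counts must be non-negative")
        if np.any(obs != np.round(obs)):
            raise ValueError("death counts must be integers")
        if not np.all(np.isfinite(self.tmean)):
            raise ValueError("tmean must be finite for all days")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.deaths)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "deaths": self.deaths, "tmean": self.tmean})


def read_daily_series(path, region_id: str) -> DailySeries:
    """Read and validate a daily series table.

    Suppressed counts (empty ``deaths`` cells) become NaN, never 0.
    Duplicate or non-consecutive dates and non-numeric temperatures are
    hard errors naming the first offending value.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "deaths", "tmean"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    dates = pd.to_datetime(df["date"], format="ISO8601")
    dup = dates[dates.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate date {dup.iloc[0].date()}")
    tmean = pd.to_numeric(df["tmean"], errors="coerce")
    if tmean.isna().any():
        i = int(tmean.isna().idxmax())
        raise ValueError(f"{path}: non-numeric tmean {df['tmean'].iloc[i]!r} on {dates.iloc[i].date()}")
    deaths = pd.to_numeric(df["deaths"], errors="coerce").to_numpy(dtype=float)
    n_missing = int(np.sum(~np.isfinite(deaths)))
    if n_missing:
        log.info("%s: %d suppressed death count(s) read as missing", region_id, n_missing)
    return DailySeries(
        region_id=region_id,
        dates=pd.DatetimeIndex(dates),
        deaths=deaths,
        tmean=tmean.to_numpy(dtype=float),
    )


def write_daily_series(series: DailySeries, path) -> None:
    """Write a series back to CSV; missing counts become empty cells so a
    write/read round trip is exact."""
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    # keep integer formatting for observed counts, empty cell for missing
    df["deaths"] = [("" if not np.isfinite(d) else str(int(d))) for d in series.deaths]
    # shortest round-trip repr so write->read is bit-identical
    df["tmean"] = [repr(float(v)) for v in series.tmean]
    df.to_csv(path, index=False)


def apply_inclusion_rule(registry: dict[str, RegionRegistry], threshold: float = 0.5) -> dict[str, RegionRegistry]:
    """Mark regions as included iff their missing-data fraction does not
    exceed the threshold (strict ``>`` excludes; exactly at the threshold
    is included).  Default threshold 0.5."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out = {}
    for rid, reg in registry.items():
        included = reg.missing_fraction <= threshold
        if not included:
            log.info("region %s excluded: missing fraction %.3f > %.2f", rid, reg.missing_fraction, threshold)
        out[rid] = RegionRegistry(
            region_id=reg.region_id,
            mmt=reg.mmt,
            missing_fraction=reg.missing_fraction,
            included=included,
        )
    return out
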