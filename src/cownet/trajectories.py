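"""Per-second cow trajectories: reading, gap filling, area assignment.

The positioning system emits one (x, y) fix per cow per second.  Fixes are
missing for roughly a third of the day on commercial installations, mostly as
isolated single seconds.  This module reads raw fix files into fixed-length
per-day series (one slot per second, NaN marking a gap), fills the gaps with
modified Akima (makima) interpolation applied independently to x(t) and y(t),
and delegates functional-area lookup to :mod:`cownet.geometry`.

Design choices: leading and trailing gaps are filled by nearest-observed-value
extension (spline extrapolation can leave the barn); cow-days with fewer than
two observed fixes cannot be interpolated and are excluded with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from datetime import date, datetime, timezone
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator

from .geometry import BarnGeometry

logger = logging.getLogger(__name__)

#: Seconds in one civil day; series are indexed 0 .. DAY_SECONDS-1.
DAY_SECONDS = 86_400


class PositionParseError(ValueError):
    """A position file row could not be parsed (message names the line)."""


class InterpolationError(ValueError):
    """A series has too few observed fixes to interpolate."""


@dataclass(frozen=True)
class PositionSeries:
    """One cow-day of per-second positions; NaN entries are gaps."""

    cow_id: object
    day: object
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if xs.shape != ys.shape or xs.ndim != 1:
            raise ValueError("xs and ys must be 1-d arrays of equal length")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    @property
    def day_seconds(self) -> int:
        return self.xs.size

    @property
    def gap_mask(self) -> np.ndarray:
        return np.isnan(self.xs) | np.isnan(self.ys)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())

    @property
    def n_observed(self) -> int:
        return self.day_seconds - self.n_gaps


def _parse_timestamps(raw: pd.Series, day) -> np.ndarray:
    """Seconds-within-day for ISO-8601 or epoch-second timestamps (auto)."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        day_start = datetime.combine(day, datetime.min.time(), tzinfo=timezone.utc).timestamp()
        return (numeric.to_numpy(dtype=float) - day_start).astype(np.int64)
    ts = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise PositionParseError(f"unparseable timestamp at line {bad + 2}")
    day_start = pd.Timestamp(day, tz="UTC")
    return ((ts - day_start) // pd.Timedelta(seconds=1)).to_numpy(dtype=np.int64)


def read_positions(
    path, day: date, day_seconds: int = DAY_SECONDS
) -> dict[object, PositionSeries]:
    """Read a delimited fix file into one gap-marked series per cow.

    The file has columns ``cow_id,timestamp,x,y`` (header optional but
    recommended), timestamps ISO-8601 or epoch seconds.  Seconds with no row
    become gaps; duplicate (cow, second) rows keep the last occurrence, with a
    warning.  Rows outside the requested day are dropped with a warning.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    expected = ["cow_id", "timestamp", "x", "y"]
    if list(df.columns[:4]) != expected:
        # headerless file: re-read with assigned names
        df = pd.read_csv(path, dtype=str, header=None, names=expected, skip_blank_lines=True)
    if df.empty:
        warnings.warn(f"position file {path} is empty", stacklevel=2)
        return {}
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise PositionParseError(f"malformed {col} value at line {bad + 2}")
        df[col] = vals
    t = _parse_timestamps(df["timestamp"], day)
    in_day = (t >= 0) & (t < day_seconds)
    if not in_day.all():
        warnings.warn(
            f"dropped {int((~in_day).sum())} fixes outside the requested day", stacklevel=2
        )
    df = df.loc[in_day].assign(t=t[in_day])
    out: dict[object, PositionSeries] = {}
    for cow_id, sub in df.groupby("cow_id", sort=True):
        if sub["t"].duplicated().any():
            ndup = int(sub["t"].duplicated().sum())
            logger.warning("cow %s: %d duplicate seconds, keeping last record", cow_id, ndup)
            sub = sub.drop_duplicates(subset="t", keep="last")
        xs = np.full(day_seconds, np.nan)
        ys = np.full(day_seconds, np.nan)
        xs[sub["t"].to_numpy()] = sub["x"].to_numpy()
        ys[sub["t"].to_numpy()] = sub["y"].to_numpy()
        out[cow_id] = PositionSeries(cow_id=cow_id, day=day, xs=xs, ys=ys)
    return out


def write_positions(series: Iterable[PositionSeries], path, timestamps: str = "epoch") -> None:
    """Write series to the delimited format :func:`read_positions` consumes.

    Gap seconds are simply absent from the file.  ``timestamps`` selects epoch
    seconds (default) or ISO-8601 strings.
    """
    frames = []
    for s in series:
        obs = ~s.gap_mask
        t = np.flatnonzero(obs)
        day_start = datetime.combine(s.day, datetime.min.time(), tzinfo=timezone.utc)
        if timestamps == "epoch":
            stamp = (day_start.timestamp() + t).astype(np.int64)
        else:
            stamp = (pd.Timestamp(day_start) + pd.to_timedelta(t, unit="s")).strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            )
        frames.append(
            pd.DataFrame(
                {
                    "cow_id": s.cow_id,
                    "timestamp": stamp,
                    "x": np.round(s.xs[obs], 3),
                    "y": np.round(s.ys[obs], 3),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _makima_fill(values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    t_obs = np.flatnonzero(observed)
    out = values.copy()
    gaps = np.flatnonzero(~observed)
    if gaps.size == 0:
        return out
    interior = gaps[(gaps > t_obs[0]) & (gaps < t_obs[-1])]
    if interior.size:
        spline = Akima1DInterpolator(t_obs, values[t_obs], method="makima")
        out[interior] = spline(interior)
    out[: t_obs[0]] = values[t_obs[0]]
    out[t_obs[-1] + 1 :] = values[t_obs[-1]]
    return out


def interpolate_gaps(series: PositionSeries) -> PositionSeries:
    """Fill every gap of a series; observed fixes are returned unchanged.

    Interior gaps get modified Akima (makima) interpolation per coordinate;
    gaps before the first / after the last observation take the nearest
    observed value.  Raises :class:`InterpolationError` if fewer than two
    fixes were observed.
    """
    observed = ~series.gap_mask
    if observed.sum() < 2:
        raise InterpolationError(
            f"cow {series.cow_id}, day {series.day}: "
            f"{int(observed.sum())} observed fixes, need >= 2"
        )
    return replace(
        series,
        xs=_makima_fill(series.xs, observed),
        ys=_makima_fill(series.ys, observed),
    )


def interpolate_all(
    series: Mapping[object, PositionSeries],
) -> tuple[dict[object, PositionSeries], list]:
    """Interpolate a collection; returns (filled, excluded cow ids)."""
    filled: dict[object, PositionSeries] = {}
    excluded: list = []
    for cow_id, s in series.items():
        try:
            filled[cow_id] = interpolate_gaps(s)
        except InterpolationError as err:
            logger.warning("excluding cow-day: %s", err)
            excluded.append(cow_id)
    return filled, excluded


def assign_functional_area(x: float, y: float, barn: BarnGeometry) -> str:
    """Label one fix as resting / feeding / excluded (total function)."""
    return barn.assign_area(x, y)
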