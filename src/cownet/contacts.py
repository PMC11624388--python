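"""Proximity contacts: per-dyad contact seconds and daily binary networks.

A contact-second is counted for a dyad when, at a given second, the two cows
are within ``radius`` meters (default 2.5 m, the span of two adjacent 1.25 m
cubicles) *and* both are assigned to the same functional area.  Seconds spent
in the excluded area never count.  Daily tallies are thresholded at
``min_seconds`` (default 600 s = 10 min; contacts of *less* than 600 s are
discarded, so a dyad at exactly 600 s keeps its edge) to form one binary
network per functional area per day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import BarnGeometry, EXCLUDED_CODE, FEEDING_CODE, RESTING_CODE
from .network import DailyNetwork, RosterError
from .trajectories import PositionSeries, interpolate_all, read_positions

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2.5  # meters; = 2 * geometry.CUBICLE_WIDTH
DEFAULT_MIN_SECONDS = 600  # contacts shorter than 10 min are discarded


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class ContactTally:
    """Symmetric per-dyad contact seconds for one day and functional area."""

    day: object
    area: str
    roster: tuple
    seconds: np.ndarray  # (n, n) int, zero diagonal

    def __post_init__(self) -> None:
        sec = np.asarray(self.seconds)
        n = len(self.roster)
        if sec.shape != (n, n):
            raise RosterError("tally matrix must match roster size")
        if not np.array_equal(sec, sec.T) or np.any(np.diag(sec) != 0) or np.any(sec < 0):
            raise ValueError("tally must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "seconds", sec.astype(np.int64))
        object.__setattr__(self, "roster", tuple(self.roster))


def tally_contact_seconds(
    series: Mapping[object, PositionSeries] | Sequence[PositionSeries],
    barn: BarnGeometry,
    radius: float = DEFAULT_RADIUS,
    chunk: int = 3600,
) -> tuple[ContactTally, ContactTally]:
    """Count same-area contact seconds for every dyad.

    ``series`` must be gap-free (run :func:`cownet.trajectories.interpolate_gaps`
    first).  Returns the (resting, feeding) tallies.  ``chunk`` controls the
    time-block size of the vectorized distance computation only.
    """
    if isinstance(series, Mapping):
        series = list(series.values())
    roster = tuple(s.cow_id for s in series)
    if len(set(roster)) != len(roster):
        raise RosterError("duplicate cow ids in series collection")
    T = {s.day_seconds for s in series}
    if len(T) != 1:
        raise RosterError("series have mismatched day lengths")
    T = T.pop()
    for s in series:
        if s.n_gaps:
            raise ValueError(f"series for cow {s.cow_id} still has gaps; interpolate first")
    n = len(roster)
    xs = np.stack([s.xs for s in series])  # (n, T)
    ys = np.stack([s.ys for s in series])
    codes = np.stack([barn.area_codes(s.xs, s.ys) for s in series])  # (n, T) int8
    out = {
        RESTING_CODE: np.zeros((n, n), dtype=np.int64),
        FEEDING_CODE: np.zeros((n, n), dtype=np.int64),
    }
    r2 = float(radius) ** 2
    for t0 in range(0, T, chunk):
        sl = slice(t0, min(t0 + chunk, T))
        dx = xs[:, None, sl] - xs[None, :, sl]
        dy = ys[:, None, sl] - ys[None, :, sl]
        near = (dx * dx + dy * dy) <= r2  # (n, n, tc)
        c = codes[:, sl]
        same = c[:, None, :] == c[None, :, :]
        for code, acc in out.items():
            in_area = c == code
            acc += (near & same & in_area[:, None, :]).sum(axis=2)
    day = series[0].day
    tallies = []
    for code, label in ((RESTING_CODE, "resting"), (FEEDING_CODE, "feeding")):
        sec = out[code]
        np.fill_diagonal(sec, 0)
        tallies.append(ContactTally(day=day, area=label, roster=roster, seconds=sec))
    return tallies[0], tallies[1]


def build_daily_network(tally: ContactTally, min_seconds: int = DEFAULT_MIN_SECONDS) -> DailyNetwork:
    """Threshold a tally into a binary network: edge iff seconds >= min_seconds."""
    adj = (tally.seconds >= min_seconds).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return DailyNetwork(adjacency=adj, roster=tally.roster, day=tally.day, area=tally.area)


def network_series(
    position_files: Sequence,
    days: Sequence,
    barn: BarnGeometry,
    roster: Sequence,
    radius: float = DEFAULT_RADIUS,
    min_seconds: int = DEFAULT_MIN_SECONDS,
    day_seconds: int = 86_400,
) -> dict[str, list[DailyNetwork]]:
    """Full extraction over consecutive days: files -> networks per area.

    The roster is fixed in advance (cows present every day); cows excluded by
    the interpolation stage (or absent from a file) become isolated nodes for
    that day, with a warning.  Returns ``{"resting": [...], "feeding": [...]}``
    with one network per day per area, all over the identical roster.
    """
    if len(position_files) != len(days):
        raise PipelineError("need one position file per day")
    roster = tuple(roster)
    idx = {c: k for k, c in enumerate(roster)}
    out: dict[str, list[DailyNetwork]] = {"resting": [], "feeding": []}
    for path, day in zip(position_files, days):
        raw = read_positions(path, day, day_seconds=day_seconds)
        raw = {c: s for c, s in raw.items() if c in idx}
        filled, dropped = interpolate_all(raw)
        absent = [c for c in roster if c not in filled]
        if absent:
            logger.warning(
                "day %s: %d roster cows without usable tracks -> isolated nodes", day, len(absent)
            )
        if not filled:
            raise PipelineError(f"day {day}: no usable cows")
        sub = [filled[c] for c in roster if c in filled]
        rest, feed = tally_contact_seconds(sub, barn, radius=radius)
        for tally in (rest, feed):
            full = np.zeros((len(roster), len(roster)), dtype=np.int64)
            rows = [idx[c] for c in tally.roster]
            full[np.ix_(rows, rows)] = tally.seconds
            full_tally = ContactTally(day=day, area=tally.area, roster=roster, seconds=full)
            out[tally.area].append(build_daily_network(full_tally, min_seconds=min_seconds))
    return out


# -- text output --------------------------------------------------------------

def write_edge_list(tally: ContactTally, path) -> None:
    """Weighted undirected edge list ``cow_a,cow_b,weight_seconds`` (nonzero dyads)."""
    iu, ju = np.triu_indices(len(tally.roster), k=1)
    w = tally.seconds[iu, ju]
    keep = w > 0
    pd.DataFrame(
        {
            "cow_a": np.asarray(tally.roster, dtype=object)[iu[keep]],
            "cow_b": np.asarray(tally.roster, dtype=object)[ju[keep]],
            "weight_seconds": w[keep],
        }
    ).to_csv(path, index=False)


def write_adjacency(net: DailyNetwork, path) -> None:
    """Binary adjacency dump, roster ids as header and index column."""
    pd.DataFrame(net.adjacency, index=net.roster, columns=net.roster).to_csv(path)


def read_adjacency(path, day=None, area=None) -> DailyNetwork:
    df = pd.read_csv(path, index_col=0)
    return DailyNetwork(
        adjacency=df.to_numpy(dtype=np.int8), roster=tuple(map(str, df.columns)), day=day, area=area
    )


def write_roster(roster: Sequence, path) -> None:
    pd.Series(list(roster), name="cow_id").to_csv(path, index=False)


def read_roster(path) -> tuple:
    return tuple(pd.read_csv(path, dtype=str)["cow_id"])
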