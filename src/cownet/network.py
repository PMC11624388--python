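"""Daily binary contact networks over a fixed cow roster.

A :class:`DailyNetwork` is an undirected, unweighted graph stored as a dense
symmetric 0/1 adjacency matrix, tagged with the day it was observed on and the
functional barn area (resting or feeding) it belongs to.  All networks of a
herd group share one ordered roster, so adjacency matrices are comparable
elementwise across days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

RESTING = "resting"
FEEDING = "feeding"
AREAS = (RESTING, FEEDING)


class RosterError(ValueError):
    """Rosters of two networks (or a network and covariates) do not match."""


@dataclass(frozen=True)
class DailyNetwork:
    """One day's binary proximity network for one functional area.

    Parameters
    ----------
    adjacency
        ``(n, n)`` symmetric 0/1 matrix with zero diagonal.
    roster
        Ordered cow identifiers; ``roster[i]`` labels row/column ``i``.
    day
        Day index (0-based within the study period) or calendar tag.
    area
        ``"resting"`` or ``"feeding"`` (optional for synthetic graphs).
    """

    adjacency: np.ndarray
    roster: tuple
    day: Optional[int] = None
    area: Optional[str] = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if adj.shape[0] != len(self.roster):
            raise RosterError(
                f"adjacency is {adj.shape[0]}x{adj.shape[0]} but roster has "
                f"{len(self.roster)} cows"
            )
        if len(set(self.roster)) != len(self.roster):
            raise RosterError("roster contains duplicate cow ids")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))
        object.__setattr__(self, "roster", tuple(self.roster))

    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def n_dyads(self) -> int:
        return self.n * (self.n - 1) // 2

    def dyad_vector(self) -> np.ndarray:
        """Strict-upper-triangle 0/1 vector, one entry per dyad."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.adjacency[iu, ju]

    @property
    def edge_count(self) -> int:
        return int(self.dyad_vector().sum())

    @property
    def density(self) -> float:
        return self.edge_count / self.n_dyads if self.n_dyads else 0.0

    def with_adjacency(self, adjacency: np.ndarray, day: Optional[int] = None) -> "DailyNetwork":
        return dataclasses.replace(
            self, adjacency=adjacency, day=self.day if day is None else day
        )

    def same_roster(self, other: "DailyNetwork") -> bool:
        return self.roster == other.roster

    def require_same_roster(self, other: "DailyNetwork") -> None:
        if not self.same_roster(other):
            raise RosterError("networks are defined over different rosters")

    def permuted(self, perm: np.ndarray) -> "DailyNetwork":
        """Relabel nodes: node ``i`` of the result is node ``perm[i]`` here.

        The roster ordering is kept, so this scrambles which cow carries which
        tie pattern — the naive-baseline operation.
        """
        perm = np.asarray(perm)
        adj = self.adjacency[np.ix_(perm, perm)]
        return self.with_adjacency(adj)


def dyads(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle (the dyad order)."""
    return np.triu_indices(n, k=1)


def from_dyad_vector(
    vec: np.ndarray, roster: Sequence, day: Optional[int] = None, area: Optional[str] = None
) -> DailyNetwork:
    n = len(roster)
    adj = np.zeros((n, n), dtype=np.int8)
    iu, ju = dyads(n)
    adj[iu, ju] = vec
    adj[ju, iu] = vec
    return DailyNetwork(adj, tuple(roster), day=day, area=area)


def random_network(
    roster: Sequence,
    density: float,
    rng: np.random.Generator,
    day: Optional[int] = None,
    area: Optional[str] = None,
) -> DailyNetwork:
    """Erdős–Rényi G(n, p) graph over the roster, p = ``density``."""
    n = len(roster)
    vec = (rng.random(n * (n - 1) // 2) < density).astype(np.int8)
    return from_dyad_vector(vec, roster, day=day, area=area)


def complement(net: DailyNetwork) -> DailyNetwork:
    adj = 1 - net.adjacency
    np.fill_diagonal(adj, 0)
    return net.with_adjacency(adj)
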