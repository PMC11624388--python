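"""Exogenous dyadic covariates: pedigree kinship, kindergarten, parity.

Three cow-level / dyad-level variables enter the network models:

* the additive genetic relationship ``a(i, j)`` from the pedigree, computed by
  the tabular method (parent-offspring and full sibs 0.5; diagonal 1 plus the
  inbreeding coefficient, so values can exceed 1);
* the *kindergarten* indicator: 1 when two cows were born at most 7 days apart
  on the same farm (they were likely reared together as calves);
* parity categorized into classes 1, 2 and 3+.

Herd and pedigree records travel as pandas DataFrames with the delimited-file
schema ``animal_id,sire_id,dam_id,birth_date,birth_farm,parity`` (empty
sire/dam for unknown parents; ancestors may omit birth data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARITY_CLASSES = ("1", "2", "3+")


class PedigreeError(ValueError):
    pass


class CovariateError(ValueError):
    pass


def parity_class(parity) -> str:
    """Map a raw parity count to the class in {"1", "2", "3+"}."""
    p = int(parity)
    if p < 1:
        raise CovariateError(f"parity must be >= 1, got {p}")
    return "3+" if p >= 3 else str(p)


def _normalize_parent(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return None if s in ("", "0", "nan", "NA") else s


def _topological_order(records: dict) -> list:
    """Parents-before-offspring order; raises naming a cycle if one exists."""
    order: list = []
    state: dict = {}  # 1 = visiting, 2 = done

    for root in records:
        if state.get(root):
            continue
        stack = [(root, False)]
        path = []
        while stack:
            node, processed = stack.pop()
            if processed:
                path.pop()
                state[node] = 2
                order.append(node)
                continue
            if state.get(node) == 2:
                continue
            if state.get(node) == 1:
                cyc = path[path.index(node):] + [node]
                raise PedigreeError("pedigree cycle: " + " -> ".join(map(str, cyc)))
            state[node] = 1
            path.append(node)
            stack.append((node, True))
            for parent in records[node]:
                if parent is not None and parent in records and state.get(parent) != 2:
                    if state.get(parent) == 1:
                        cyc = path[path.index(parent):] + [parent]
                        raise PedigreeError(
                            "pedigree cycle: " + " -> ".join(map(str, cyc))
                        )
                    stack.append((parent, False))
        assert not path
    return order


def additive_relationship_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Tabular-method additive relationship matrix A over all pedigree animals.

    ``pedigree`` has columns ``animal_id, sire_id, dam_id`` (empty/0/NA for
    unknown).  Parents referenced but not listed are treated as founders with a
    warning.  Returns A as a DataFrame indexed by animal id, processed in
    topological (parents-first) order:

    * ``a(i, i) = 1 + 0.5 * a(sire_i, dam_i)`` (0 if either parent unknown);
    * ``a(i, j) = 0.5 * (a(j, sire_i) + a(j, dam_i))`` for earlier ``j``.
    """
    import warnings

    records: dict = {}
    for row in pedigree.itertuples(index=False):
        aid = str(row.animal_id)
        if aid in records:
            raise PedigreeError(f"duplicate pedigree entry for {aid}")
        records[aid] = (_normalize_parent(row.sire_id), _normalize_parent(row.dam_id))
    for aid, parents in list(records.items()):
        for p in parents:
            if p is not None and p not in records:
                warnings.warn(
                    f"parent {p} of {aid} not in pedigree; treated as founder",
                    stacklevel=2,
                )
    order = _topological_order(records)
    pos = {aid: k for k, aid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, aid in enumerate(order):
        sire, dam = records[aid]
        si = pos.get(sire) if sire is not None else None
        di = pos.get(dam) if dam is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return pd.DataFrame(A, index=order, columns=order)


def kindergarten_matrix(herd: pd.DataFrame, window_days: int = 7) -> pd.DataFrame:
    """Symmetric 0/1 matrix: born within ``window_days`` (inclusive) on the same farm.

    ``herd`` needs columns ``cow_id, birth_date, birth_farm``; missing birth
    data raises :class:`CovariateError` listing the offending cows.  Diagonal
    is defined as 0.
    """
    ids = [str(c) for c in herd["cow_id"]]
    dates = pd.to_datetime(herd["birth_date"], errors="coerce")
    farms = herd["birth_farm"].astype(str)
    missing = [
        cid
        for cid, d, f in zip(ids, dates, herd["birth_farm"])
        if pd.isna(d) or pd.isna(f) or str(f).strip() == ""
    ]
    if missing:
        raise CovariateError(f"missing birth date/farm for cows: {', '.join(missing)}")
    days = dates.to_numpy(dtype="datetime64[D]").astype(np.int64)
    close = np.abs(days[:, None] - days[None, :]) <= window_days
    same_farm = farms.to_numpy()[:, None] == farms.to_numpy()[None, :]
    kg = (close & same_farm).astype(np.int8)
    np.fill_diagonal(kg, 0)
    return pd.DataFrame(kg, index=ids, columns=ids)


@dataclass(frozen=True)
class DyadCovariateSet:
    """Per-dyad exogenous covariates aligned to an ordered roster."""

    roster: tuple
    kinship: np.ndarray  # (n, n) float, diagonal >= 1
    kindergarten: np.ndarray  # (n, n) 0/1, diagonal 0
    parity: tuple  # per-cow class in PARITY_CLASSES

    def __post_init__(self) -> None:
        n = len(self.roster)
        kin = np.asarray(self.kinship, dtype=float)
        kg = np.asarray(self.kindergarten, dtype=np.int8)
        if kin.shape != (n, n) or kg.shape != (n, n):
            raise CovariateError("covariate matrices must match the roster size")
        if not np.allclose(kin, kin.T):
            raise CovariateError("kinship matrix must be symmetric")
        if np.any(np.diag(kin) < 1.0 - 1e-9):
            raise CovariateError("kinship diagonal must be >= 1")
        if not np.array_equal(kg, kg.T) or np.any(np.diag(kg) != 0):
            raise CovariateError("kindergarten matrix must be symmetric with zero diagonal")
        bad = [c for c in self.parity if c not in PARITY_CLASSES]
        if bad:
            raise CovariateError(f"unknown parity classes: {bad}")
        object.__setattr__(self, "roster", tuple(self.roster))
        object.__setattr__(self, "kinship", kin)
        object.__setattr__(self, "kindergarten", kg)
        object.__setattr__(self, "parity", tuple(self.parity))

    @property
    def n(self) -> int:
        return len(self.roster)


def build_dyad_covariates(
    pedigree: pd.DataFrame,
    herd: pd.DataFrame,
    roster,
    kindergarten_window_days: int = 7,
) -> DyadCovariateSet:
    """Assemble the model's exogenous covariates for an ordered roster."""
    roster = tuple(str(c) for c in roster)
    herd = herd.assign(cow_id=herd["cow_id"].astype(str)).set_index("cow_id", drop=False)
    missing = [c for c in roster if c not in herd.index]
    if missing:
        raise CovariateError(f"roster cows absent from herd records: {', '.join(missing)}")
    A = additive_relationship_matrix(pedigree)
    missing = [c for c in roster if c not in A.index]
    if missing:
        raise CovariateError(f"roster cows absent from pedigree: {', '.join(missing)}")
    if not roster:
        raise CovariateError("empty roster")
    sub = herd.loc[list(roster)]
    kg = kindergarten_matrix(sub, window_days=kindergarten_window_days)
    return DyadCovariateSet(
        roster=roster,
        kinship=A.loc[list(roster), list(roster)].to_numpy(),
        kindergarten=kg.to_numpy(),
        parity=tuple(parity_class(p) for p in sub["parity"]),
    )


HERD_COLUMNS = ["animal_id", "sire_id", "dam_id", "birth_date", "birth_farm", "parity"]


def read_herd_file(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the combined pedigree/herd file.

    Returns ``(herd, pedigree)``: ``herd`` holds the rows with birth and
    parity data (columns renamed to ``cow_id, ...``), ``pedigree`` holds every
    row's ``animal_id, sire_id, dam_id``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != HERD_COLUMNS:
        raise CovariateError(f"herd file must have columns {','.join(HERD_COLUMNS)}")
    pedigree = df[["animal_id", "sire_id", "dam_id"]].copy()
    has_data = (df["birth_date"] != "") & (df["parity"] != "")
    herd = df.loc[has_data].rename(columns={"animal_id": "cow_id"}).copy()
    herd["parity"] = herd["parity"].astype(int)
    return herd, pedigree


def write_herd_file(herd: pd.DataFrame, pedigree: pd.DataFrame, path) -> None:
    """Write the format :func:`read_herd_file` consumes (ancestors first)."""
    ped = pedigree.copy()
    ped["animal_id"] = ped["animal_id"].astype(str)
    herd = herd.copy()
    herd["cow_id"] = herd["cow_id"].astype(str)
    herd = herd.set_index("cow_id")
    rows = []
    for row in ped.itertuples(index=False):
        aid = str(row.animal_id)
        sire = _normalize_parent(row.sire_id) or ""
        dam = _normalize_parent(row.dam_id) or ""
        if aid in herd.index:
            h = herd.loc[aid]
            rows.append([aid, sire, dam, str(h["birth_date"]), str(h["birth_farm"]), int(h["parity"])])
        else:
            rows.append([aid, sire, dam, "", "", ""])
    pd.DataFrame(rows, columns=HERD_COLUMNS).to_csv(path, index=False)
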