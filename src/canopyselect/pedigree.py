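"""Numerator (additive) relationship matrix from pedigree records.

The A-matrix is built with the tabular method: founders are assumed
non-inbred and mutually unrelated, each offspring row is the average of its
parents' rows, and the diagonal is ``1 + A(sire, dam)/2``.  Selfing is
encoded as ``sire == dam``, which makes inbreeding accumulate without any
special casing (a chain of t selfing generations from a non-inbred
individual gives a diagonal of ``2 - (1/2)^t``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "AMatrix",
    "read_pedigree",
    "write_pedigree",
    "topological_order",
    "build_a_matrix",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown parent id, ...)."""


PEDIGREE_COLUMNS = ["id", "sire", "dam", "generation"]


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree CSV with columns id, sire, dam, generation.

    Empty sire/dam fields mark founders (or a single unknown parent).
    """
    ped = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {missing}")
    return ped[PEDIGREE_COLUMNS]


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped[PEDIGREE_COLUMNS].to_csv(path, index=False)


def _normalize(ped: pd.DataFrame) -> pd.DataFrame:
    ped = ped.copy()
    for col in ("id", "sire", "dam"):
        ped[col] = ped[col].astype(object).where(~pd.isna(ped[col]), "")
        ped[col] = ped[col].astype(str).str.strip()
    dup = ped["id"].duplicated()
    if dup.any():
        raise PedigreeError(f"duplicate ids: {sorted(ped.loc[dup, 'id'])[:5]}")
    known = set(ped["id"])
    for col in ("sire", "dam"):
        bad = set(ped.loc[ped[col] != "", col]) - known
        if bad:
            raise PedigreeError(f"unknown {col} id(s) referenced: {sorted(bad)[:5]}")
    return ped


def topological_order(ped: pd.DataFrame) -> list[str]:
    """Order ids so parents precede offspring; ties keep input order.

    Raises :class:`PedigreeError` on a cycle (an individual that is its own
    ancestor).
    """
    ped = _normalize(ped)
    parents = {
        r.id: [p for p in (r.sire, r.dam) if p] for r in ped.itertuples(index=False)
    }
    order: list[str] = []
    placed: set[str] = set()
    remaining = list(ped["id"])
    while remaining:
        progressed = []
        for ind in remaining:
            if all(p in placed for p in parents[ind]):
                order.append(ind)
                placed.add(ind)
            else:
                progressed.append(ind)
        if len(progressed) == len(remaining):
            raise PedigreeError(f"cycle detected in pedigree near {progressed[:5]}")
        remaining = progressed
    return order


@dataclass
class AMatrix:
    """Additive relationship matrix with its id index."""

    ids: list[str]
    values: np.ndarray
    _pos: dict = field(repr=False, default=None)

    def __post_init__(self):
        self._pos = {i: k for k, i in enumerate(self.ids)}

    def loc(self, ids) -> np.ndarray:
        """Submatrix for the given ids, in the given order."""
        idx = [self._pos[i] for i in ids]
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_a_matrix(ped: pd.DataFrame) -> AMatrix:
    """Tabular-method A-matrix; handles unknown parents as unrelated founders."""
    ped = _normalize(ped)
    order = topological_order(ped)
    pos = {i: k for k, i in enumerate(order)}
    sire = ped.set_index("id")["sire"].to_dict()
    dam = ped.set_index("id")["dam"].to_dict()

    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = sire[ind], dam[ind]
        si = pos[s] if s else None
        di = pos[d] if d else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * a[si, :i]
        if di is not None:
            row += 0.5 * a[di, :i]
        a[i, :i] = row
        a[:i, i] = row
        if si is not None and di is not None:
            a[i, i] = 1.0 + 0.5 * a[si, di]
        else:
            a[i, i] = 1.0
    return AMatrix(ids=order, values=a)
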