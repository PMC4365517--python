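"""Pedigrees: parsing, the tabular additive relationship matrix, inbreeding
coefficients and complete-generation (pedigree depth) groups.

The additive (numerator) relationship matrix A is built by the tabular
recursion over a parents-before-offspring ordering:

    A[x, y] = (A[sire(x), y] + A[dam(x), y]) / 2     for y ordered before x
    A[x, x] = 1 + A[sire(x), dam(x)] / 2

with unknown parents contributing 0 — founders and individuals of unknown
ancestry are taken to be unrelated and non-inbred (the usual identity-by-
descent base population). Wright's inbreeding coefficient is F(x) =
coancestry(sire(x), dam(x)), computed by a memoised kinship recursion that
never materialises the full matrix, and equal to the tabular diagonal
minus one exactly.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)

_UNKNOWN_TOKENS = {"0", "", ".", "na", "nan", "none", "unknown"}


def _norm_parent(token) -> str | None:
    s = str(token).strip()
    return None if s.lower() in _UNKNOWN_TOKENS else s


@dataclass
class Pedigree:
    """Directed acyclic parentage records.

    parents maps id -> (sire, dam) with None for an unknown parent;
    order preserves the input record order (auto-added founders first
    appear where first referenced). birth_year is optional metadata.
    """

    parents: dict[str, tuple[str | None, str | None]]
    order: list[str] = field(default_factory=list)
    birth_year: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.order:
            self.order = list(self.parents)
        auto = []
        for iid, (sire, dam) in list(self.parents.items()):
            if iid in (sire, dam):
                raise ValueError(f"individual {iid!r} is its own parent")
            for par in (sire, dam):
                if par is not None and par not in self.parents:
                    auto.append(par)
        for par in auto:
            if par not in self.parents:
                self.parents[par] = (None, None)
                self.order.append(par)
        if auto:
            logger.info(
                "auto-added %d named-but-unlisted parents as founders", len(auto)
            )

    @classmethod
    def from_records(
        cls, records, birth_year: dict[str, int] | None = None
    ) -> "Pedigree":
        parents: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for rec in records:
            iid, sire, dam = str(rec[0]), _norm_parent(rec[1]), _norm_parent(rec[2])
            if iid in parents:
                raise ValueError(f"duplicate pedigree id {iid!r}")
            parents[iid] = (sire, dam)
            order.append(iid)
        return cls(parents=parents, order=order, birth_year=birth_year or {})

    def __len__(self) -> int:
        return len(self.parents)

    def __contains__(self, iid: str) -> bool:
        return iid in self.parents

    @property
    def ids(self) -> list[str]:
        return list(self.order)

    def founders(self) -> list[str]:
        return [i for i in self.order if self.parents[i] == (None, None)]


def read_pedigree(path: str | Path, sep: str | None = None) -> Pedigree:
    """Read a delimited pedigree file: id, sire, dam[, birth_year].

    Unknown parents are coded 0, empty, '.' or NA. Named-but-unlisted
    parents are auto-added as founders (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python",
                     dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"pedigree file {path} needs >= 3 columns (id, sire, dam)")
    birth_year: dict[str, int] = {}
    if df.shape[1] >= 4:
        for _, row in df.iterrows():
            y = str(row.iloc[3]).strip()
            if y and y not in _UNKNOWN_TOKENS:
                birth_year[str(row.iloc[0])] = int(float(y))
    return Pedigree.from_records(
        df.iloc[:, :3].itertuples(index=False), birth_year=birth_year
    )


def topological_order(p: Pedigree) -> list[str]:
    """Parents-before-offspring ordering, ties broken by input order.

    Raises on a cycle, naming one individual in it.
    """
    index = {iid: i for i, iid in enumerate(p.order)}
    children: dict[str, list[str]] = {iid: [] for iid in p.order}
    n_parents: dict[str, int] = {}
    for iid, (sire, dam) in p.parents.items():
        known = [q for q in (sire, dam) if q is not None]
        n_parents[iid] = len(known)
        for q in known:
            children[q].append(iid)
    heap = [index[iid] for iid in p.order if n_parents[iid] == 0]
    heapq.heapify(heap)
    out: list[str] = []
    while heap:
        iid = p.order[heapq.heappop(heap)]
        out.append(iid)
        for child in children[iid]:
            n_parents[child] -= 1
            if n_parents[child] == 0:
                heapq.heappush(heap, index[child])
    if len(out) != len(p.parents):
        stuck = next(i for i in p.order if i not in set(out))
        raise ValueError(f"pedigree contains a cycle involving {stuck!r}")
    return out


def a_matrix(p: Pedigree, ids: list[str] | None = None) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular recursion, subset to ids."""
    order = topological_order(p)
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, iid in enumerate(order):
        sire, dam = p.parents[iid]
        si = pos[sire] if sire is not None else None
        di = pos[dam] if dam is not None else None
        row = np.zeros(k)
        if si is not None:
            row += 0.5 * A[si, :k]
        if di is not None:
            row += 0.5 * A[di, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    if ids is None:
        ids = p.ids
    idx = []
    for iid in ids:
        if iid not in pos:
            raise KeyError(f"id {iid!r} not in pedigree")
        idx.append(pos[iid])
    idx = np.asarray(idx, dtype=np.intp)
    return RelationshipMatrix(
        ids=list(ids), values=A[np.ix_(idx, idx)], method="A_ped"
    )


class _KinshipCalculator:
    """Memoised coancestry recursion over a topological ranking."""

    def __init__(self, p: Pedigree) -> None:
        self.parents = p.parents
        self.rank = {iid: k for k, iid in enumerate(topological_order(p))}
        self.cache: dict[tuple[str, str], float] = {}

    def coancestry(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if self.rank[a] < self.rank[b]:
            a, b = b, a
        key = (a, b)
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        if a == b:
            sire, dam = self.parents[a]
            val = 0.5 * (1.0 + self.coancestry(sire, dam))
        else:
            # a ranks after b, so a cannot be an ancestor of b
            sire, dam = self.parents[a]
            val = 0.5 * (self.coancestry(sire, b) + self.coancestry(dam, b))
        self.cache[key] = val
        return val


def pedigree_inbreeding(p: Pedigree) -> pd.Series:
    """Wright's F per individual: the coancestry of its parents.

    Founders (and anyone with an unknown parent) get F = 0. Equals the
    tabular A diagonal minus one exactly; computed without building A.
    """
    calc = _KinshipCalculator(p)
    out = {}
    for iid in p.order:
        sire, dam = p.parents[iid]
        out[iid] = calc.coancestry(sire, dam)
    return pd.Series(out, name="F").reindex(p.ids)


def complete_generations(p: Pedigree, iid: str) -> int:
    """Largest g such that every ancestor up to generation g is recorded.

    0 if either parent is unknown; a single missing grandparent caps the
    depth at 1 even if deeper records exist on the other side.
    """
    if iid not in p:
        raise KeyError(f"id {iid!r} not in pedigree")
    memo: dict[str, int] = {}

    def cg(x: str) -> int:
        if x in memo:
            return memo[x]
        sire, dam = p.parents[x]
        if sire is None or dam is None:
            memo[x] = 0
        else:
            memo[x] = 1 + min(cg(sire), cg(dam))
        return memo[x]

    return cg(iid)


def depth_groups(
    p: Pedigree, ids: list[str], thresholds: tuple[int, ...] = (1, 2, 4)
) -> dict[int, list[str]]:
    """Nested groups {t: ids with complete_generations >= t} per threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    depths = {iid: complete_generations(p, iid) for iid in ids}
    return {t: [iid for iid in ids if depths[iid] >= t] for t in thresholds}
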