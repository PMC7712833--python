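"""Pedigree container and the numerator relationship matrix A.

A is built by the tabular (recursive) method with inbreeding; its sparse
inverse is assembled directly by Henderson's rules, with per-individual
Mendelian-sampling variances computed from inbreeding coefficients
(Meuwissen & Luo style recursion on the pedigree, no dense A needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Pedigree", "RelationshipMatrix", "build_relationship", "inbreeding_coefficients"]

MISSING = -1


@dataclass
class Pedigree:
    """Ordered pedigree: parents precede offspring.

    ``sires``/``dams`` hold positional indices into ``ids`` (or -1 for an
    unknown parent, treated as an unrelated founder of its population).
    """

    ids: list[str]
    sires: np.ndarray
    dams: np.ndarray
    populations: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.sires = np.asarray(self.sires, dtype=np.int64)
        self.dams = np.asarray(self.dams, dtype=np.int64)
        if len(self.sires) != n or len(self.dams) != n:
            raise ValueError("ids, sires and dams must have equal length")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids in pedigree")
        for i in range(n):
            for par in (self.sires[i], self.dams[i]):
                if par != MISSING and not (0 <= par < i):
                    raise ValueError(
                        f"individual {self.ids[i]!r}: parent index {par} does not "
                        "precede it (pedigree must be sorted parents-first, acyclic)"
                    )
        if not self.populations:
            self.populations = [None] * n

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {ind: i for i, ind in enumerate(self.ids)}

    @classmethod
    def from_tuples(cls, rows: list[tuple]) -> "Pedigree":
        """Build from (id, sire_id, dam_id[, population]) tuples.

        ``None``, ``""`` or ``"0"`` denote an unknown parent.  Rows may be in
        any order; they are topologically sorted parents-first.
        """
        ids = [str(r[0]) for r in rows]
        byid = {ind: r for ind, r in zip(ids, rows)}
        if len(byid) != len(rows):
            raise ValueError("duplicate individual ids in pedigree")

        def norm(x):
            return None if x in (None, "", "0", 0) else str(x)

        order: list[str] = []
        state: dict[str, int] = {}

        def visit(ind: str, stack: tuple = ()) -> None:
            st = state.get(ind)
            if st == 2:
                return
            if st == 1 or ind in stack:
                raise ValueError(f"pedigree cycle involving {ind!r}")
            state[ind] = 1
            row = byid.get(ind)
            if row is not None:
                for par in (norm(row[1]), norm(row[2])):
                    if par is not None and par in byid:
                        visit(par, stack + (ind,))
            state[ind] = 2
            order.append(ind)

        for ind in ids:
            visit(ind)
        pos = {ind: i for i, ind in enumerate(order)}
        sires = np.full(len(order), MISSING, dtype=np.int64)
        dams = np.full(len(order), MISSING, dtype=np.int64)
        pops: list[str | None] = [None] * len(order)
        for ind in order:
            row = byid[ind]
            i = pos[ind]
            s, d = norm(row[1]), norm(row[2])
            if s is not None:
                if s not in pos:
                    raise ValueError(f"sire {s!r} of {ind!r} not in pedigree")
                sires[i] = pos[s]
            if d is not None:
                if d not in pos:
                    raise ValueError(f"dam {d!r} of {ind!r} not in pedigree")
                dams[i] = pos[d]
            if len(row) > 3 and row[3] not in (None, ""):
                pops[i] = str(row[3])
        return cls(ids=order, sires=sires, dams=dams, populations=pops)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F_i = f(sire_i, dam_i) for every individual.

    Computed without forming A, from memoised coancestry recursions on the
    pedigree graph; unknown parents contribute 0.
    """
    n = len(ped)
    F = np.zeros(n)
    cache: dict = {}
    for i in range(n):
        s, d = int(ped.sires[i]), int(ped.dams[i])
        F[i] = 0.0 if (s == MISSING or d == MISSING) else _kinship(ped, s, d, cache)
    return F


def _kinship(ped: Pedigree, i: int, j: int, cache: dict | None = None) -> float:
    """Coancestry f(i, j) = A_ij / 2, by the standard recursion (memoised)."""
    if cache is None:
        cache = {}

    def fval(i: int, j: int) -> float:
        if i == MISSING or j == MISSING:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        if i == j:
            s, d = ped.sires[i], ped.dams[i]
            val = 0.5 * (1.0 + fval(s, d))
        else:
            s, d = ped.sires[j], ped.dams[j]
            val = 0.5 * (fval(i, s) + fval(i, d))
        cache[key] = val
        return val

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(ped) + 1000))
    try:
        return fval(i, j)
    finally:
        sys.setrecursionlimit(old)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A over pedigree individuals.

    ``A_inv`` (sparse CSR) is what the sampler uses; the dense ``A`` is
    built lazily by the tabular method for inspection and testing.
    """

    pedigree: Pedigree
    A_inv: sp.csr_matrix
    inbreeding: np.ndarray
    _A: np.ndarray | None = None

    @property
    def A(self) -> np.ndarray:
        if self._A is None:
            self._A = tabular_A(self.pedigree)
        return self._A


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (O(n^2) memory; fine at pedigree scale here)."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sires[i], ped.dams[i]
        a_sd = A[s, d] if (s != MISSING and d != MISSING) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if s != MISSING:
                val += 0.5 * A[j, s]
            if d != MISSING:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def build_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Assemble A^-1 by Henderson's rules with inbreeding.

    For individual i with parents s, d the Mendelian-sampling variance is
    ``delta_i = 0.5 - 0.25 (F_s + F_d)`` (one parent unknown: 0.75 - 0.25 F;
    both unknown: 1) and 1/delta_i is scattered over (i, s, d) with the
    usual (1, -0.5, 0.25) pattern.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        s, d = int(ped.sires[i]), int(ped.dams[i])
        known = [p for p in (s, d) if p != MISSING]
        if len(known) == 2:
            delta = 0.5 - 0.25 * (F[s] + F[d])
        elif len(known) == 1:
            delta = 0.75 - 0.25 * F[known[0]]
        else:
            delta = 1.0
        w = 1.0 / delta
        rows.append(i); cols.append(i); vals.append(w)
        for p in known:
            rows.extend((i, p)); cols.extend((p, i)); vals.extend((-0.5 * w, -0.5 * w))
        for p in known:
            for q in known:
                rows.append(p); cols.append(q); vals.append(0.25 * w)
    A_inv = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return RelationshipMatrix(pedigree=ped, A_inv=A_inv, inbreeding=F)
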