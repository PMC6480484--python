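"""Exact model of the folding loop nest's iteration space and dependences.

The triply nested folding loop (see :mod:`nusstile.fold`) executes, for a
strand of length ``N``::

    for i = N-2 .. 0:                 # descending
      for j = i+1 .. N-1:
        for k = 0 .. j-i-1:
          S1(i,j,k):  S[i][j] = max(S[i][j], S[i][i+k] + S[i+k+1][j])
        S2(i,j):      S[i][j] = max(S[i][j], S[i+1][j-1] + sigma(x_i, x_j))

This module enumerates every statement instance in original execution
order, derives each instance's memory accesses, and extracts *all* data
dependences (flow, anti and output) by inspecting, cell by cell, which
instances touch the same matrix element.  The dependence set is the
brute-force oracle against which every candidate execution schedule is
validated (:mod:`nusstile.tiling`): a schedule is legal iff it orders the
source of every dependence before its destination.

The original execution order is encoded by a 4-component *global stamp*
``(i, j, s, k)`` with ``s = 0`` for S1 and ``s = 1`` for S2, compared
lexicographically with the ``i`` component DESCENDING (the outer loop
decrements) and the others ascending.  This is the single place where the
sign convention of the decremented loop lives; distance vectors are plain
componentwise differences ``stamp(dst) - stamp(src)``, so a "forward" step
of the outer loop appears as a non-positive first component.

A closed-form affine description of the same dependences (seven clauses,
:func:`in_dependence_relation`) is provided for cross-checking; the
brute-force extractor remains the authority.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, NamedTuple, Optional

import numpy as np

__all__ = [
    "Stmt",
    "StatementInstance",
    "S1",
    "S2",
    "Dependence",
    "EmptyDomainError",
    "DomainCapError",
    "DEFAULT_CAP",
    "global_stamp",
    "stamp_key",
    "enumerate_domain",
    "domain_size",
    "domain_arrays",
    "instance_indices",
    "accesses_of",
    "extract_deps",
    "dependence_pairs",
    "in_dependence_relation",
    "distance_vectors",
    "deps_to_tsv",
]

#: Brute-force dependence extraction is refused above this N by default.
DEFAULT_CAP = 80


class EmptyDomainError(ValueError):
    """The loop nest has no iterations (N < 2)."""


class DomainCapError(ValueError):
    """Requested N exceeds the brute-force extraction cap."""


class Stmt(IntEnum):
    S1 = 0
    S2 = 1


class StatementInstance(NamedTuple):
    """One dynamic execution of S1(i,j,k) or S2(i,j); ``k`` is None for S2."""

    stmt: Stmt
    i: int
    j: int
    k: Optional[int] = None


def S1(i: int, j: int, k: int) -> StatementInstance:
    return StatementInstance(Stmt.S1, i, j, k)


def S2(i: int, j: int) -> StatementInstance:
    return StatementInstance(Stmt.S2, i, j)


def global_stamp(inst: StatementInstance) -> tuple:
    """The 4-tuple (i, j, s, k) locating ``inst`` in the common space."""
    return (inst.i, inst.j, int(inst.stmt), inst.k if inst.k is not None else 0)


def stamp_key(inst: StatementInstance) -> tuple:
    """Sort key realizing original execution order (i descending)."""
    i, j, s, k = global_stamp(inst)
    return (-i, j, s, k)


def in_domain(inst: StatementInstance, n: int) -> bool:
    if not (0 <= inst.i <= n - 2 and inst.i + 1 <= inst.j <= n - 1):
        return False
    if inst.stmt == Stmt.S1:
        return inst.k is not None and 0 <= inst.k <= inst.j - inst.i - 1
    return inst.k is None


def enumerate_domain(n: int) -> list:
    """All statement instances, in original execution order."""
    if n < 2:
        raise EmptyDomainError(f"loop nest is empty for N = {n}")
    out = []
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            for k in range(j - i):
                out.append(S1(i, j, k))
            out.append(S2(i, j))
    return out


def domain_size(n: int) -> int:
    """Closed-form instance count: sum over diagonals d of (N-d)(d+1)."""
    return sum((n - d) * (d + 1) for d in range(1, n))


def domain_arrays(n: int):
    """Vectorized domain: (s, i, j, k) int64 arrays in execution order.

    ``k`` is 0 for S2 instances (the stamp convention).
    """
    if n < 2:
        raise EmptyDomainError(f"loop nest is empty for N = {n}")
    ss, ii, jj, kk = [], [], [], []
    for i in range(n - 2, -1, -1):
        m = n - 1 - i  # number of cells in this row
        d_per_cell = np.arange(1, m + 1)
        counts = d_per_cell + 1  # d S1 instances + one S2 per cell
        total = int(counts.sum())
        d_rep = np.repeat(d_per_cell, counts)
        starts = np.repeat(np.cumsum(counts) - counts, counts)
        pos = np.arange(total) - starts  # 0..d-1 are S1 k's, d is S2
        s = (pos == d_rep).astype(np.int64)
        k = np.where(s == 0, pos, 0)
        ss.append(s)
        ii.append(np.full(total, i, dtype=np.int64))
        jj.append(i + d_rep)
        kk.append(k)
    return (
        np.concatenate(ss),
        np.concatenate(ii),
        np.concatenate(jj),
        np.concatenate(kk),
    )


# -- index arithmetic -------------------------------------------------------
# Positions in execution order admit a closed form: row i holds
# m(m+3)/2 instances with m = N-1-i; within a row, the cell (i, j) with
# d = j-i starts at offset (d-1)(d+2)/2 and holds its d S1 instances
# followed by the S2 instance.


def _row_bases(n: int) -> np.ndarray:
    i_vals = np.arange(n - 1)
    m = n - 1 - i_vals
    cnt = m * (m + 3) // 2
    suffix = np.concatenate([np.cumsum(cnt[::-1])[::-1], [0]])
    return suffix[1:]  # base[i] = instances in rows executed before row i


def _cell_offset(d):
    return (d - 1) * (d + 2) // 2


def instance_indices(s, i, j, k, n: int):
    """Execution-order index of instances given as (s, i, j, k) arrays."""
    base = _row_bases(n)
    d = np.asarray(j) - np.asarray(i)
    return base[np.asarray(i)] + _cell_offset(d) + np.where(
        np.asarray(s) == 0, np.asarray(k), d
    )


# -- memory accesses and dependences ----------------------------------------


def accesses_of(inst: StatementInstance):
    """(write cell, tuple of read cells) of one statement instance."""
    i, j = inst.i, inst.j
    if inst.stmt == Stmt.S1:
        k = inst.k
        return (i, j), ((i, j), (i, i + k), (i + k + 1, j))
    return (i, j), ((i, j), (i + 1, j - 1))


@dataclass(frozen=True)
class Dependence:
    """An ordered pair of instances touching the same cell, >= 1 write."""

    src: StatementInstance
    dst: StatementInstance
    category: str  # "flow" | "anti" | "output"
    cell: tuple


def _check_cap(n: int, cap: int) -> None:
    if n < 2:
        raise EmptyDomainError(f"loop nest is empty for N = {n}")
    if n > cap:
        raise DomainCapError(
            f"N = {n} exceeds the brute-force dependence cap ({cap}); "
            f"pass a larger cap explicitly if you accept the cost"
        )


def _cell_parties(r: int, c: int, n: int):
    """Writers and (pure) readers of cell (r, c), in execution order.

    Writers -- S1(r,c,k) for k = 0..d-1 then S2(r,c) -- all execute before
    every pure reader of the cell, and each writer also reads the cell.
    Pure readers are: S1(r, j', d) for j' > c (reading via S[i, i+k]),
    S1(i', c, r-1-i') for i' < r (via S[i+k+1, j]), and S2(r-1, c+1)
    (via S[i+1, j-1]).  Readers never write (r, c), so every dependence on
    the cell is writer->writer (flow+anti+output) or writer->reader (flow).
    """
    d = c - r
    writers = [S1(r, c, k) for k in range(d)] + [S2(r, c)]
    readers = [S1(r, jp, d) for jp in range(c + 1, n)]
    readers += [S1(ip, c, r - 1 - ip) for ip in range(r)]
    if r >= 1 and c + 1 <= n - 1:
        readers.append(S2(r - 1, c + 1))
    return writers, readers


def extract_deps(n: int, cap: int = DEFAULT_CAP) -> list:
    """All dependences of the nest, categorized, in deterministic order.

    Cells are scanned in (row, column) order; within a cell, writer-writer
    pairs come first (flow, anti, output for each ordered pair -- every
    writer also reads the cell), then writer-reader flow pairs.
    """
    _check_cap(n, cap)
    deps = []
    for r in range(n - 1):
        for c in range(r + 1, n):
            writers, readers = _cell_parties(r, c, n)
            cell = (r, c)
            for a in range(len(writers)):
                for b in range(a + 1, len(writers)):
                    deps.append(Dependence(writers[a], writers[b], "flow", cell))
                    deps.append(Dependence(writers[a], writers[b], "anti", cell))
                    deps.append(Dependence(writers[a], writers[b], "output", cell))
                for rd in readers:
                    deps.append(Dependence(writers[a], rd, "flow", cell))
    return deps


def dependence_pairs(n: int, cap: int = DEFAULT_CAP):
    """All distinct (src, dst) dependence pairs as execution-order indices.

    Categories are dropped (an ordering constraint is identical for flow,
    anti and output); the result is two int64 arrays aligned with
    :func:`domain_arrays` / :func:`enumerate_domain`.
    """
    _check_cap(n, cap)
    base = _row_bases(n)
    srcs, dsts = [], []
    for r in range(n - 1):
        for c in range(r + 1, n):
            d = c - r
            writers = base[r] + _cell_offset(d) + np.arange(d + 1)
            readers = []
            if c + 1 <= n - 1:
                dd = np.arange(d + 1, n - r)  # S1(r, r+dd, d)
                readers.append(base[r] + _cell_offset(dd) + d)
            if r >= 1:
                ip = np.arange(r)  # S1(ip, c, r-1-ip)
                dp = c - ip
                readers.append(base[ip] + _cell_offset(dp) + (r - 1 - ip))
                if c + 1 <= n - 1:  # S2(r-1, c+1)
                    dq = d + 2
                    readers.append(
                        np.array([base[r - 1] + _cell_offset(dq) + dq])
                    )
            a, b = np.triu_indices(d + 1, 1)
            srcs.append(writers[a])
            dsts.append(writers[b])
            if readers:
                rd = np.concatenate(readers)
                srcs.append(np.repeat(writers, rd.size))
                dsts.append(np.tile(rd, d + 1))
    return np.concatenate(srcs), np.concatenate(dsts)


def in_dependence_relation(
    src: StatementInstance, dst: StatementInstance, n: int
) -> bool:
    """Membership in the closed-form affine dependence relation.

    The relation is a union of seven clauses over instance pairs; it is
    cross-checked against the brute-force extractor in the test suite.
    """
    if src.stmt == Stmt.S1 and dst.stmt == Stmt.S2:
        i, j, k = src.i, src.j, src.k
        ip, jp = dst.i, dst.j
        # S1(i,j,k) -> S2(i', i+j-i')
        return (
            jp == i + j - ip
            and 0 <= k < j - i
            and ip >= i - 1
            and ip >= 0
            and i + j - n < ip <= i
        )
    if src.stmt == Stmt.S1 and dst.stmt == Stmt.S1:
        i, j, k = src.i, src.j, src.k
        ip, jp, kp = dst.i, dst.j, dst.k
        # S1(i,j,k) -> S1(i,j,k')
        if ip == i and jp == j and i >= 0 and j < n and 0 <= k < kp < j - i:
            return True
        # S1(i,j,k) -> S1(i,j',j-i)
        if ip == i and kp == j - i and i >= 0 and 0 <= k < j - i and j < jp < n:
            return True
        # S1(i,j,k) -> S1(i',j,i-i'-1)
        if jp == j and kp == i - ip - 1 and j < n and 0 <= k < j - i and 0 <= ip < i:
            return True
        return False
    if src.stmt == Stmt.S2 and dst.stmt == Stmt.S1:
        i, j = src.i, src.j
        ip, jp, kp = dst.i, dst.j, dst.k
        # S2(i,j) -> S1(i,j',j-i)
        if ip == i and kp == j - i and i >= 0 and j > i and j < jp < n:
            return True
        # S2(i,j) -> S1(i',j,i-i'-1)
        if jp == j and kp == i - ip - 1 and i < j < n and 0 <= ip < i:
            return True
        return False
    # S2(i,j) -> S2(i-1,j+1)
    i, j = src.i, src.j
    return dst.i == i - 1 and dst.j == j + 1 and i > 0 and i < j <= n - 2


def distance_vectors(n: int, cap: int = DEFAULT_CAP) -> set:
    """Distance vectors stamp(dst) - stamp(src) over all dependences."""
    si, di = dependence_pairs(n, cap)
    s, i, j, k = domain_arrays(n)
    vecs = np.stack(
        [i[di] - i[si], j[di] - j[si], s[di] - s[si], k[di] - k[si]], axis=1
    )
    return {tuple(int(x) for x in row) for row in np.unique(vecs, axis=0)}


def deps_to_tsv(deps: Iterable[Dependence]) -> str:
    """Dependence dump, one row per (src, dst, category, cell)."""

    def fmt(inst: StatementInstance) -> str:
        if inst.stmt == Stmt.S1:
            return f"S1({inst.i},{inst.j},{inst.k})"
        return f"S2({inst.i},{inst.j})"

    lines = ["src\tdst\tcategory\tcell"]
    for dep in deps:
        lines.append(
            f"{fmt(dep.src)}\t{fmt(dep.dst)}\t{dep.category}\t"
            f"({dep.cell[0]},{dep.cell[1]})"
        )
    return "\n".join(lines) + "\n"
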