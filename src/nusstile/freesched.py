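"""Free (earliest-start) schedules over a box with constant distance vectors.

A small laboratory for the time-partitioning idea used inside space-time
tiles: given a rectangular iteration box ``[0, n_1) x ... x [0, n_d)`` and
a set of constant dependence distance vectors, the *free schedule* assigns
every point ``p`` the length of the longest dependence chain reaching it:

    t(p) = 0                       if no predecessor p - dv lies in the box
    t(p) = 1 + max over in-box predecessors t(p - dv)   otherwise.

Points with equal ``t`` form a *time partition* -- they are mutually
independent and can run in parallel -- and ``W`` consecutive partitions
form a *time slice*.  Enumerating slices in order is legal because every
dependence advances ``t`` by at least one, so all data a slice needs was
produced in earlier slices.

The canonical demo (also exposed on the command line) is the 3x3x3 box
with distance vectors ``(0,0,1), (0,1,0), (1,0,-1)`` -- the intra-tile
dependence pattern of the folding nest -- which yields nine partitions
``t0 .. t8`` and, with ``W = 3``, three slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator, Sequence

__all__ = [
    "DepBox",
    "TimePartitioning",
    "CyclicDependenceError",
    "free_schedule",
    "time_slices",
    "check_slice_legality",
]


class CyclicDependenceError(RuntimeError):
    """The distance vectors induce a dependence cycle on the box."""


@dataclass(frozen=True)
class DepBox:
    """A d-dimensional box ``[0, dims[0]) x ... x [0, dims[d-1])`` with a
    list of integer distance vectors.

    Vectors are expected to be lexicographically positive under the box's
    iteration order (source before destination); this is not enforced
    here -- :func:`free_schedule` detects any resulting cycle at run time.
    """

    dims: tuple
    dvs: tuple

    def __post_init__(self) -> None:
        if not self.dims or any(d < 1 for d in self.dims):
            raise ValueError("box extents must be positive")
        for dv in self.dvs:
            if len(dv) != len(self.dims):
                raise ValueError(f"distance vector {dv} has wrong dimension")
            if not any(dv):
                raise ValueError("zero distance vector")

    def points(self) -> Iterator[tuple]:
        """All points in lexicographic order."""
        return product(*(range(d) for d in self.dims))

    def __contains__(self, p) -> bool:
        return all(0 <= x < d for x, d in zip(p, self.dims))

    def __len__(self) -> int:
        out = 1
        for d in self.dims:
            out *= d
        return out

    @property
    def is_lex_positive(self) -> bool:
        return all(next(x for x in dv if x) > 0 for dv in self.dvs)


@dataclass
class TimePartitioning:
    """An earliest-start time assignment over a box."""

    box: DepBox
    times: dict

    @property
    def max_time(self) -> int:
        return max(self.times.values())

    def partitions(self) -> list:
        """Partition sets indexed 0 .. max_time (some may be empty only if
        the schedule were not earliest-start; here every index is hit)."""
        parts = [set() for _ in range(self.max_time + 1)]
        for p, t in self.times.items():
            parts[t].add(p)
        return parts

    def partition(self, t: int) -> set:
        return {p for p, tv in self.times.items() if tv == t}


def free_schedule(box: DepBox) -> TimePartitioning:
    """Earliest-start schedule, computed by relaxation to a fixpoint.

    Points are swept in lexicographic order; with lexicographically
    positive distance vectors one sweep suffices, but sweeps repeat until
    nothing changes so arbitrary (acyclic) vector sets are handled.  A
    cycle is detected when values keep growing past the longest possible
    chain, and reported with an offending point.
    """
    points = list(box.points())
    t = {p: 0 for p in points}
    last_changed = None
    for _ in range(len(points) + 1):
        changed = False
        for p in points:
            best = 0
            for dv in box.dvs:
                q = tuple(x - d for x, d in zip(p, dv))
                if q in box:
                    cand = t[q] + 1
                    if cand > best:
                        best = cand
            if best != t[p]:
                t[p] = best
                changed = True
                last_changed = p
        if not changed:
            return TimePartitioning(box, t)
    raise CyclicDependenceError(
        f"dependence cycle through point {last_changed} (schedule does not converge)"
    )


def time_slices(tp: TimePartitioning, width: int) -> list:
    """Group partitions into slices of ``width`` consecutive partitions."""
    if width < 1:
        raise ValueError("slice width must be >= 1")
    parts = tp.partitions()
    slices = []
    for start in range(0, len(parts), width):
        merged: set = set()
        for part in parts[start : start + width]:
            merged |= part
        slices.append(merged)
    return slices


def check_slice_legality(box: DepBox, slices: Sequence[Iterable]) -> bool:
    """True iff no dependence runs from a later slice into an earlier one.

    ``slices`` must cover the box (every point assigned a slice index);
    points in several slices take the earliest.
    """
    index: dict = {}
    for s_idx, sl in enumerate(slices):
        for p in sl:
            index.setdefault(tuple(p), s_idx)
    missing = [p for p in box.points() if p not in index]
    if missing:
        raise ValueError(f"slices do not cover the box (e.g. point {missing[0]})")
    for p in box.points():
        for dv in box.dvs:
            q = tuple(x - d for x, d in zip(p, dv))
            if q in box and index[q] > index[p]:
                return False
    return True
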