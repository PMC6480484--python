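"""Space-time tiling of the folding loop nest.

The folding nest has non-uniform dependences (its distance vectors grow
with the iteration point), which defeats standard rectangular tiling of
all three loops.  The construction implemented here tiles all three:

1. **Space bands.**  The iteration space is cut into bands of width ``Ws``
   along two directions at once: *i-bands* indexed by ``ii`` and anchored
   at the top (band ``ii = 0`` covers ``i in [N-Ws, N-1]``, because the
   outer loop decrements ``i``), and *anti-diagonal bands* indexed by
   ``jj`` over the anti-diagonal value ``i0 = j - i`` (band ``jj`` covers
   ``Ws*jj < i0 <= Ws*jj + Ws``).  Every dependence moves forward (or not
   at all) in both ``ii`` and ``jj``, so band pairs can be enumerated
   lexicographically.

2. **Time slices.**  Intersecting the two bands bounds a tile along ``i``
   and ``j`` but not along the split index ``k``.  A two-dimensional
   schedule ``S1(i,j,k) -> (j-i, k)``, ``S2(i,j) -> (j-i, j)`` assigns each
   instance a time partition; ``Wt`` consecutive partitions form a time
   slice indexed by ``tt`` (``tt = k // Wt`` for S1, ``j // Wt`` for S2).

3. **Tiles.**  A tile is the intersection of an i-band, a j-band at a
   fixed anti-diagonal ``i0``, and a time slice; it is identified by
   ``(ii, jj, i0, tt)`` and holds at most ``Ws * Wt`` S1 instances --
   bounded in all three loop dimensions, with a cardinality that stops
   depending on ``N`` once ``N`` is a few bands wide ("non-parametric"
   tile size).

4. **Wavefront schedule.**  Skewing by ``w = ii + jj`` yields the total
   order ``(w, jj, i0, tt, i, j, s, k)`` (``s`` is the statement ordinal:
   S1 before S2 at an equal prefix).  ``w`` is enumerated serially; within
   a wavefront, tiles with different ``jj`` carry no dependences between
   them and may run in any order or concurrently, while tiles sharing
   ``jj`` form a serial chain ordered by ``(i0, tt)``.

:func:`validate_schedule` proves legality exhaustively for a given ``N``:
every brute-force dependence (flow, anti *and* output -- a safe
over-approximation of the value-based set) must be ordered by the
schedule, and no dependence may link two tiles with equal ``w`` but
different ``jj``.  :func:`execute_tiled` runs the folding kernel in this
tiled order and is elementwise equivalent to the reference engine.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .fold import PAIR_SCORE, RnaSequence
from .iterspace import (
    DEFAULT_CAP,
    S1,
    S2,
    StatementInstance,
    Stmt,
    dependence_pairs,
    domain_arrays,
    domain_size,
    in_domain,
)

__all__ = [
    "TilingParams",
    "SpaceTimeTile",
    "ScheduleReport",
    "PartitionReport",
    "TileStats",
    "tile_of_instance",
    "enumerate_tiles",
    "schedule_tuple",
    "schedule_matrix",
    "lexicographic_ranks",
    "validate_schedule",
    "execute_tiled",
    "partition_report",
    "tile_stats",
]


@dataclass(frozen=True)
class TilingParams:
    """Tiling widths for a strand of length ``n``.

    ``ws`` is the space-band width (both i-bands and anti-diagonal bands),
    ``wt`` the time-slice width (number of time partitions per slice).
    The defaults of 16 give 16x16x16 tiles; any positive widths are valid.
    """

    n: int
    ws: int = 16
    wt: int = 16

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.ws < 1 or self.wt < 1:
            raise ValueError("tile widths must be >= 1")


@dataclass(frozen=True)
class SpaceTimeTile:
    """One tile: identity (ii, jj, i0, tt) plus its instances in order."""

    ii: int
    jj: int
    i0: int
    tt: int
    instances: tuple

    @property
    def wavefront(self) -> int:
        return self.ii + self.jj


def tile_of_instance(inst: StatementInstance, p: TilingParams) -> tuple:
    """The (ii, jj, i0, tt) of the tile containing ``inst``."""
    if not in_domain(inst, p.n):
        raise ValueError(f"{inst} outside the iteration domain for N = {p.n}")
    ii = (p.n - 1 - inst.i) // p.ws
    i0 = inst.j - inst.i
    jj = (i0 - 1) // p.ws
    tt = inst.k // p.wt if inst.stmt == Stmt.S1 else inst.j // p.wt
    return (ii, jj, i0, tt)


def schedule_tuple(inst: StatementInstance, p: TilingParams) -> tuple:
    """The 8-tuple (w, jj, i0, tt, i, j, s, k), compared lexicographically."""
    ii, jj, i0, tt = tile_of_instance(inst, p)
    k = inst.k if inst.k is not None else 0
    return (ii + jj, jj, i0, tt, inst.i, inst.j, int(inst.stmt), k)


# -- tile generation --------------------------------------------------------


@lru_cache(maxsize=32)
def _tile_bounds(p: TilingParams) -> np.ndarray:
    """Nonempty tiles as an int64 array, rows (ii, jj, i0, tt, i_lo, i_hi,
    k_lo, k_hi), sorted by (w, jj, i0, tt).

    Per tile: S1 instances are all (i, i0+i, k) with i in [i_lo, i_hi] and
    k in [k_lo, k_hi] (empty if k_lo > k_hi); the S2 instance of cell
    (i, i0+i) belongs to the tile iff (i0+i) // wt == tt.
    """
    n, ws, wt = p.n, p.ws, p.wt
    rows = []
    for i0 in range(1, n):
        jj = (i0 - 1) // ws
        for ii in range(i0 // ws, (n - 1) // ws + 1):
            i_lo = max(0, n - ws * (ii + 1))
            i_hi = min(n - 1 - i0, n - ws * ii - 1)
            if i_lo > i_hi:
                continue
            s1_tt_max = (i0 - 1) // wt
            s2_lo = (i0 + i_lo) // wt
            s2_hi = (i0 + i_hi) // wt
            tts = set(range(s1_tt_max + 1)) | set(range(s2_lo, s2_hi + 1))
            for tt in sorted(tts):
                k_lo = wt * tt
                k_hi = min(wt * tt + wt - 1, i0 - 1)
                rows.append((ii, jj, i0, tt, i_lo, i_hi, k_lo, k_hi))
    if not rows:
        return np.empty((0, 8), dtype=np.int64)
    arr = np.array(rows, dtype=np.int64)
    order = np.lexsort((arr[:, 3], arr[:, 2], arr[:, 1], arr[:, 0] + arr[:, 1]))
    return arr[order]


def _tile_instances(row, wt: int) -> list:
    ii, jj, i0, tt, i_lo, i_hi, k_lo, k_hi = (int(x) for x in row)
    out = []
    for i in range(i_lo, i_hi + 1):
        j = i0 + i
        for k in range(k_lo, k_hi + 1):
            out.append(S1(i, j, k))
        if j // wt == tt:
            out.append(S2(i, j))
    return out


def enumerate_tiles(p: TilingParams) -> list:
    """All nonempty tiles in execution order (w, jj, i0, tt).

    The union of the instance sets is the whole iteration domain and tiles
    are pairwise disjoint (a partition); instances within a tile are in
    intra-tile execution order (i, j, s, k).
    """
    if p.n < 2:
        raise ValueError("enumerate_tiles requires N >= 2")
    tiles = []
    for row in _tile_bounds(p):
        tiles.append(
            SpaceTimeTile(
                int(row[0]),
                int(row[1]),
                int(row[2]),
                int(row[3]),
                tuple(_tile_instances(row, p.wt)),
            )
        )
    return tiles


# -- schedule validation ----------------------------------------------------


def schedule_matrix(p: TilingParams):
    """Schedule tuples of every instance, as an (M, 8) int64 array in
    original execution order (aligned with ``domain_arrays``)."""
    s, i, j, k = domain_arrays(p.n)
    i0 = j - i
    ii = (p.n - 1 - i) // p.ws
    jj = (i0 - 1) // p.ws
    tt = np.where(s == 0, k // p.wt, j // p.wt)
    return np.stack([ii + jj, jj, i0, tt, i, j, s, k], axis=1)


def lexicographic_ranks(tuples: np.ndarray) -> np.ndarray:
    """Rank of each row under ascending lexicographic comparison."""
    order = np.lexsort(tuple(tuples[:, c] for c in range(tuples.shape[1] - 1, -1, -1)))
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(len(order))
    return ranks


def _instance_from_arrays(s, i, j, k, idx: int) -> StatementInstance:
    if s[idx] == 0:
        return S1(int(i[idx]), int(j[idx]), int(k[idx]))
    return S2(int(i[idx]), int(j[idx]))


@dataclass
class ScheduleReport:
    """Outcome of exhaustive schedule validation for one (N, Ws, Wt)."""

    params: TilingParams
    n_instances: int
    n_dependences: int
    order_violations: list = field(default_factory=list)
    wavefront_violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.order_violations and not self.wavefront_violations

    def to_dict(self) -> dict:
        return {
            "n": self.params.n,
            "ws": self.params.ws,
            "wt": self.params.wt,
            "instances": self.n_instances,
            "dependences": self.n_dependences,
            "order_violations": len(self.order_violations),
            "wavefront_violations": len(self.wavefront_violations),
            "valid": self.ok,
        }


def validate_schedule(
    p: TilingParams,
    pairs=None,
    cap: int = DEFAULT_CAP,
    max_report: int = 20,
) -> ScheduleReport:
    """Exhaustively check the space-time schedule against all dependences.

    For every brute-force dependence (src, dst) the schedule tuple of
    ``src`` must precede that of ``dst``; additionally no dependence may
    connect two tiles with equal wavefront ``ii + jj`` and different
    ``jj`` (otherwise same-wavefront tiles could not run concurrently).
    ``pairs`` may carry precomputed ``dependence_pairs(n)`` output.
    Violations are reported as instance pairs (up to ``max_report`` each).
    """
    n = p.n
    if pairs is None:
        pairs = dependence_pairs(n, cap)
    si, di = pairs
    tuples = schedule_matrix(p)
    ranks = lexicographic_ranks(tuples)
    s, i, j, k = domain_arrays(n)
    report = ScheduleReport(p, n_instances=len(ranks), n_dependences=len(si))

    bad_order = np.nonzero(ranks[di] <= ranks[si])[0]
    for idx in bad_order[:max_report]:
        report.order_violations.append(
            (
                _instance_from_arrays(s, i, j, k, si[idx]),
                _instance_from_arrays(s, i, j, k, di[idx]),
            )
        )
    if bad_order.size > max_report:
        report.order_violations.append(("...", f"{bad_order.size} total"))

    w = tuples[:, 0]
    jj = tuples[:, 1]
    bad_wave = np.nonzero((w[si] == w[di]) & (jj[si] != jj[di]))[0]
    for idx in bad_wave[:max_report]:
        report.wavefront_violations.append(
            (
                _instance_from_arrays(s, i, j, k, si[idx]),
                _instance_from_arrays(s, i, j, k, di[idx]),
            )
        )
    if bad_wave.size > max_report:
        report.wavefront_violations.append(("...", f"{bad_wave.size} total"))
    return report


# -- tiled execution --------------------------------------------------------


def _run_tiles_py(s, codes, pair, bounds, wt):  # pragma: no cover - numba source
    for t in range(bounds.shape[0]):
        i0 = bounds[t, 2]
        tt = bounds[t, 3]
        i_lo = bounds[t, 4]
        i_hi = bounds[t, 5]
        k_lo = bounds[t, 6]
        k_hi = bounds[t, 7]
        for i in range(i_lo, i_hi + 1):
            j = i0 + i
            best = s[i, j]
            for k in range(k_lo, k_hi + 1):
                v = s[i, i + k] + s[i + k + 1, j]
                if v > best:
                    best = v
            if j // wt == tt:
                left = s[i + 1, j - 1] if j - 1 > i else 0
                v = left + pair[codes[i], codes[j]]
                if v > best:
                    best = v
            s[i, j] = best


try:
    from numba import njit

    _run_tiles = njit(nogil=True, cache=False)(_run_tiles_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _run_tiles = _run_tiles_py


def _chain_slices(bounds: np.ndarray) -> list:
    """Contiguous runs of equal (w, jj): the serial chains of each wavefront.

    Returns a list of wavefronts; each wavefront is a list of (start, stop)
    row ranges, one per chain.  Chains of one wavefront are mutually
    independent.
    """
    if len(bounds) == 0:
        return []
    w = bounds[:, 0] + bounds[:, 1]
    jj = bounds[:, 1]
    chain_break = np.nonzero((np.diff(w) != 0) | (np.diff(jj) != 0))[0] + 1
    starts = np.concatenate([[0], chain_break])
    stops = np.concatenate([chain_break, [len(bounds)]])
    fronts: list = []
    last_w = None
    for a, b in zip(starts, stops):
        if last_w != w[a]:
            fronts.append([])
            last_w = w[a]
        fronts[-1].append((int(a), int(b)))
    return fronts


def _interleaved_order(bounds: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random legal execution order: wavefronts stay serial and in order;
    within a wavefront the chains are randomly interleaved, each chain's
    internal (i0, tt) order preserved."""
    order = []
    for front in _chain_slices(bounds):
        cursors = [a for a, _ in front]
        stops = [b for _, b in front]
        live = list(range(len(front)))
        while live:
            pick = live[int(rng.integers(len(live)))]
            order.append(cursors[pick])
            cursors[pick] += 1
            if cursors[pick] == stops[pick]:
                live.remove(pick)
    return np.array(order, dtype=np.int64)


def execute_tiled(
    seq: RnaSequence,
    p: Optional[TilingParams] = None,
    threads: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Fold ``seq`` by executing the nest tile by tile in wavefront order.

    Elementwise equal to :func:`nusstile.fold.fold_reference`.  With
    ``threads > 1`` the independent chains of each wavefront run
    concurrently in a thread pool (the kernel releases the GIL).  ``rng``
    randomly interleaves same-wavefront chains instead -- used to
    demonstrate order-independence; it implies single-threaded execution.
    """
    n = len(seq)
    if p is None:
        p = TilingParams(n)
    if p.n != n:
        raise ValueError(f"params built for N = {p.n}, sequence has length {n}")
    if threads < 1:
        raise ValueError("threads must be >= 1")
    s = np.zeros((n, n), dtype=np.int32)
    if n < 2:
        return s
    codes = seq.codes
    bounds = _tile_bounds(p)
    wt = np.int64(p.wt)
    if rng is not None:
        perm = _interleaved_order(bounds, rng)
        _run_tiles(s, codes, PAIR_SCORE, np.ascontiguousarray(bounds[perm]), wt)
    elif threads == 1:
        _run_tiles(s, codes, PAIR_SCORE, bounds, wt)
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            for front in _chain_slices(bounds):
                futures = [
                    pool.submit(_run_tiles, s, codes, PAIR_SCORE, bounds[a:b], wt)
                    for a, b in front
                ]
                for fut in futures:
                    fut.result()
    return s


# -- partition and size reports ---------------------------------------------


@dataclass
class PartitionReport:
    """Multiset comparison of the tiled cover against the iteration domain."""

    params: TilingParams
    n_domain: int
    n_tiled: int
    is_partition: bool

    @property
    def ok(self) -> bool:
        return self.is_partition

    def to_dict(self) -> dict:
        return {
            "n": self.params.n,
            "ws": self.params.ws,
            "wt": self.params.wt,
            "domain_instances": self.n_domain,
            "tiled_instances": self.n_tiled,
            "partition": self.is_partition,
        }


def _tiles_as_arrays(p: TilingParams):
    """(s, i, j, k) arrays of every instance generated tile by tile."""
    wt = p.wt
    ss, ii, jj, kk = [], [], [], []
    for row in _tile_bounds(p):
        i0, tt, i_lo, i_hi, k_lo, k_hi = (int(x) for x in row[2:8])
        for i in range(i_lo, i_hi + 1):
            j = i0 + i
            for k in range(k_lo, k_hi + 1):
                ss.append(0)
                ii.append(i)
                jj.append(j)
                kk.append(k)
            if j // wt == tt:
                ss.append(1)
                ii.append(i)
                jj.append(j)
                kk.append(0)
    return (
        np.array(ss, dtype=np.int64),
        np.array(ii, dtype=np.int64),
        np.array(jj, dtype=np.int64),
        np.array(kk, dtype=np.int64),
    )


def partition_report(p: TilingParams) -> PartitionReport:
    """Check that tiles cover the domain exactly once.

    The tile-generated instance multiset (built from per-tile bounds) is
    compared, after lexicographic sorting, with the directly enumerated
    iteration domain; equality implies full cover with no duplicates.
    """
    dom = np.stack(domain_arrays(p.n), axis=1)
    til = np.stack(_tiles_as_arrays(p), axis=1)
    same = len(dom) == len(til)
    if same:
        dom_sorted = dom[np.lexsort(tuple(dom[:, c] for c in range(3, -1, -1)))]
        til_sorted = til[np.lexsort(tuple(til[:, c] for c in range(3, -1, -1)))]
        same = bool(np.array_equal(dom_sorted, til_sorted))
    return PartitionReport(p, n_domain=len(dom), n_tiled=len(til), is_partition=same)


@dataclass
class TileStats:
    """Tile-size summary for one (N, Ws, Wt)."""

    params: TilingParams
    n_tiles: int
    n_wavefronts: int
    max_instances: int
    max_s1_instances: int
    total_instances: int

    def to_dict(self) -> dict:
        return {
            "n": self.params.n,
            "ws": self.params.ws,
            "wt": self.params.wt,
            "tiles": self.n_tiles,
            "wavefronts": self.n_wavefronts,
            "max_instances_per_tile": self.max_instances,
            "max_s1_instances_per_tile": self.max_s1_instances,
            "total_instances": self.total_instances,
        }


def tile_stats(p: TilingParams) -> TileStats:
    """Closed-form per-tile instance counts (no instance enumeration).

    The S1 count of a tile is (#i values) x (#k values); the S2 count is
    the overlap of the tile's i-interval with the i-values whose cell
    column lands in the tile's time slice.  For fixed widths the maximum
    count saturates as N grows (tile size does not depend on N).
    """
    if p.n < 2:
        raise ValueError("tile_stats requires N >= 2")
    b = _tile_bounds(p)
    n_i = b[:, 5] - b[:, 4] + 1
    n_k = np.maximum(0, b[:, 7] - b[:, 6] + 1)
    s1 = n_i * n_k
    # S2(i, i0+i) is in the tile iff (i0+i)//wt == tt, i.e. i in
    # [wt*tt - i0, wt*tt + wt - 1 - i0] intersected with [i_lo, i_hi].
    lo = np.maximum(b[:, 4], p.wt * b[:, 3] - b[:, 2])
    hi = np.minimum(b[:, 5], p.wt * b[:, 3] + p.wt - 1 - b[:, 2])
    s2 = np.maximum(0, hi - lo + 1)
    counts = s1 + s2
    w = b[:, 0] + b[:, 1]
    return TileStats(
        p,
        n_tiles=len(b),
        n_wavefronts=len(np.unique(w)),
        max_instances=int(counts.max()),
        max_s1_instances=int(s1.max()),
        total_instances=int(counts.sum()),
    )
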