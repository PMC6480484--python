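"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the matching oracle
enumerates every non-crossing matching recursively (no memoization), and
the dependence oracle scans all ordered instance pairs literally.
"""

from itertools import combinations

from nusstile.fold import sigma
from nusstile.iterspace import accesses_of, enumerate_domain


def max_noncrossing_matching(residues: str) -> int:
    """Maximum number of non-crossing complementary pairs, by exhaustive
    recursion over all matchings of the interval [i, j]."""

    def best(i: int, j: int) -> int:
        if i >= j:
            return 0
        # base i unpaired
        out = best(i + 1, j)
        # base i paired with any compatible l in (i, j]
        for l in range(i + 1, j + 1):
            if sigma(residues[i], residues[l]):
                cand = 1 + best(i + 1, l - 1) + best(l + 1, j)
                if cand > out:
                    out = cand
        return out

    return best(0, len(residues) - 1)


def brute_force_dependences(n: int):
    """All (src, dst, category, cell) tuples by scanning every ordered
    instance pair for a shared cell with at least one write."""
    insts = enumerate_domain(n)
    deps = set()
    for a, b in combinations(range(len(insts)), 2):
        src, dst = insts[a], insts[b]
        w_src, r_src = accesses_of(src)
        w_dst, r_dst = accesses_of(dst)
        for cell in {w_src} & set(r_dst):
            deps.add((src, dst, "flow", cell))
        for cell in set(r_src) & {w_dst}:
            deps.add((src, dst, "anti", cell))
        if w_src == w_dst:
            deps.add((src, dst, "output", w_src))
    return deps
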