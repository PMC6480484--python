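# Methods

## The folding model

The package folds a single RNA strand `X = x_0 … x_{N-1}` over
`{A, U, G, C}` by maximizing the number of non-crossing base pairs, a
pair being admissible iff it is AU, GC or the GU wobble.  The integer
recurrence (see `nusstile.fold`) is the textbook maximum-matching DP; it
makes no thermodynamic claims — no stacking energies, no loop penalties,
no partition function — and, deliberately, imposes **no minimum
hairpin-loop length**: the printed recurrence allows `σ(x_i, x_{i+1})`
pairs and the implementation follows it.  Users comparing output with
energy-based folders should expect different (and often sharper-turned)
structures.  Input is FASTA (case-insensitive, `T` read as `U`);
non-AUGC IUPAC ambiguity codes are rejected at parse time rather than
silently scored zero, on the view that a strand containing `N`s should
fail loudly instead of folding to an arbitrary structure.

Traceback is deterministic: at each cell the pairing case is preferred
whenever it attains the cell value (adding a pair only when `σ = 1`),
otherwise the smallest attaining split index is taken.  Any optimal
structure would do; determinism makes outputs reproducible and testable.

## The loop nest and its dependences

The nest executes, for `i = N-2 … 0` (descending), `j = i+1 … N-1`,
first all split updates `S1(i,j,k)` for `k = 0 … j-i-1`, then the pairing
update `S2(i,j)`.  `nusstile.iterspace` models this exactly: every
statement instance, its position in original execution order (the
*global stamp* `(i, j, s, k)`, compared with `i` descending — the one
place the decremented-loop sign convention lives), and its memory
accesses.

Dependences are extracted by brute force, cell by cell: the accessors of
a matrix cell `(r, c)` admit a closed enumeration (its `c-r+1` writers —
which all also read it — followed, in execution order, by its pure
readers), so the extractor lists exactly the pairs an all-pairs scan
would find while staying linear in the number of dependences.  The test
suite verifies this equivalence against a literal all-pairs scan at
small `N`.  Flow, anti and output dependences are all kept: a schedule
validated against this superset is safe regardless of whether a
value-based (last-writer) analysis would have pruned some pairs.  A
closed-form affine description of the dependence relation (seven
clauses) is provided and cross-checked both ways in the tests: every
clause member is a genuine dependence, and every value-carrying flow is
admitted directly or through a composition of admitted pairs.  Exact set
equality between the closed form and any particular dataflow convention
is deliberately not asserted.

Extraction cost is quadratic-ish in instance count, so it is capped
(default `N ≤ 80`) with an explicit error and an override.

## The space-time tiling

Every dependence of the nest moves forward (or stays) both in the
decremented row index `i` and in the anti-diagonal `d = j - i`.  Tiles
exploit this:

* **i-bands** `ii = ⌊(N-1-i)/Ws⌋`, anchored at the *top* (band 0 covers
  `i ∈ [N-Ws, N-1]`) because the outer loop decrements;
* **anti-diagonal bands** `jj = ⌊(d-1)/Ws⌋` over `d = j-i` — bands in the
  diagonal direction, not axis-parallel `j`-bands, because the band
  constraint is `Ws·jj < d ≤ Ws·jj + Ws`;
* **time slices** `tt = ⌊k/Wt⌋` for `S1` and `⌊j/Wt⌋` for `S2`, which
  bound a tile along the otherwise unbounded split dimension.

A tile is identified by `(ii, jj, i0, tt)` with `i0 = d` fixed per tile
(this mirrors the parameterization of the defining sets; a tile holds at
most `Ws` values of `i` and `Wt` values of `k`, hence at most `Ws·Wt`
`S1` instances).  Boundary tiles are clipped by the domain; there is no
padding.  Band intervals follow the defining sets exactly: the `i`-band
is half-open above, the `d`-band half-open below.

The execution schedule is the 8-tuple `(w, jj, i0, tt, i, j, s, k)` with
the skewed wavefront `w = ii + jj` serial and ascending.  The statement
ordinal `s` (S1 = 0 before S2 = 1 at an equal prefix) resolves the order
between `S1(i,j,·)` and `S2(i,j)` when both land in the same tile —
necessary because `S2(i,j)` reads the cell every `S1(i,j,k)` writes —
and the exhaustive validator then proves the completed order safe.

**Validation** (`validate_schedule`) is exhaustive, not symbolic: for a
given `N` it ranks all instances by the schedule and checks (a) every
brute-force dependence is ordered source-before-destination, and
(b) no dependence links two tiles with equal `w` and different `jj`.
Property (b) is what makes the wavefront parallel: same-`w` tiles in
different diagonal bands carry no constraints between each other, while
same-`(w, jj)` tiles form a serial chain ordered by `(i0, tt)`.

**Execution** (`execute_tiled`) walks wavefronts serially and runs each
wavefront's chains either in order, in a thread pool (the per-tile
kernel is numba-compiled and releases the GIL, so threads genuinely
overlap), or — for testing — in a randomly interleaved order driven by a
supplied generator.  Correctness is defined as "any interleaving of
same-wavefront chains yields the identical matrix" and is tested by
shuffling rather than by trusting a particular runtime.  All arithmetic
is integer max/plus, so equality between engines is exact (bit-identical
matrices), never approximate.

The partition property (each instance in exactly one tile) is checked by
generating the instance multiset tile-by-tile from band bounds and
comparing it, sorted, against the directly enumerated domain — two
independent routes to the same set.

## Free-schedule laboratory

`nusstile.freesched` computes earliest-start schedules over a
rectangular box with constant distance vectors: `t(p) = 0` for points
with no in-box predecessor, else one plus the maximum over predecessors,
relaxed to a fixpoint.  Points are swept in lexicographic order; with
lexicographically positive vectors a single sweep converges, but the
sweep repeats until stable so arbitrary acyclic vector sets work, and a
cycle is detected (values growing past the longest possible chain) and
reported with an offending point.  Lexicographic positivity of the
vectors is documented but not enforced at construction, precisely so the
cycle path is reachable.  On the canonical 3×3×3 demo box the
earliest-start times coincide with the affine form `2i + j + k`; the
tests confirm this pointwise rather than assuming it.

## Synthetic data

Benchmark and test strands are uniform i.i.d. over the four bases,
seeded per `(seed, length)`.  Folding *cost* depends only on length, so
uniform strands are adequate for performance work; they do **not**
emulate biological base composition, repeats or covariation, so passing
tests say nothing about the biological plausibility of predicted
structures — only about the optimality and the execution-schedule
correctness of the matrix computation, which hold for any input by the
same argument.

## Problem sizes and defaults

* Tile widths default to `Ws = Wt = 16` (16×16×16 tiles), a shape that
  balances cache footprint against scheduling overhead on current
  x86 cores; any positive widths are accepted.
* Exhaustive schedule validation in the test suite covers every
  `N ∈ [3, 60]` against four tile shapes including degenerate `(1, 1)`;
  engine-equivalence tests use 30 random strands per length in
  {17, 64, 150, 301} and three tile shapes; partition checks go up to
  `N = 200`.  These sizes give full coverage of all clipping cases
  (bands narrower, equal to and much wider than the strand) while
  keeping the default suite quick.
* Optimality is tested against an exhaustive non-crossing-matching
  enumerator for strands up to length 12, where exhaustive enumeration
  is tractable and already exercises every recurrence case.
* The benchmark harness verifies engines against the reference up to a
  configurable cap (default `N = 1000`) and reports timings without
  asserting them: wall-clock numbers are hardware-bound by design.

## Known limitations

* Single strands only; no pseudoknots, no suboptimal structures, no
  energy model.
* The dependence extractor and validator are exhaustive by design and
  therefore capped in `N`; they certify the schedule for the sizes they
  run at, and the band-monotonicity argument (dependences never move
  backwards in `ii` or `jj`) is what extends confidence beyond the cap.
* `threads > 1` helps only the tiled engine, and only once tiles are
  large enough that kernel time dominates scheduling overhead.
* The traceback returns one optimal structure; co-optimal structures are
  not enumerated.
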