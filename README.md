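# nusstile

Maximum base-pair RNA folding with a space-time tiled, wavefront-parallel
execution schedule — and the dependence-analysis machinery that proves the
schedule correct.

## Who this is for

RNA secondary-structure prediction by dynamic programming is a classic
*nonserial polyadic* DP: the cost of cell `(i, j)` depends on a whole row
and a whole column of earlier cells, so the dependences are non-uniform
and ordinary rectangular loop tiling of all three loops is illegal.  This
package is for people studying how to make such kernels cache-efficient
and parallel: it implements the folding DP itself, an exact enumerable
model of its loop nest, and a tiling of **all three** loops whose legality
is not assumed but *checked exhaustively* against every data dependence.

## The model

For a strand `X = x_0 … x_{N-1}` over `{A, U, G, C}`, the score matrix
`S` maximizes the number of non-crossing complementary pairs (AU, GC, GU):

    S[i,j] = max( S[i+1,j-1] + σ(x_i, x_j),
                  max_{0 ≤ k < j-i} ( S[i,i+k] + S[i+k+1,j] ) )

with `S[i,j] = 0` for `j ≤ i`; `σ` is 1 for an admissible pair and 0
otherwise.  `S[0,N-1]` is the optimal pair count; a deterministic
traceback recovers one optimal structure in dot-bracket notation.  **No
minimum hairpin-loop length is imposed** — adjacent bases may pair, so
scores can exceed those of loop-constrained folders.

Three engines fill the matrix and agree elementwise:

* `reference` — the plain triangular loop nest (row index descending);
* `transpose` — mirrors each value into the lower triangle so the inner
  maximisation reads two row-contiguous slices (cache-friendly);
* `tiled` — the space-time schedule: the iteration space is cut into
  bands of width `Ws` along `i` and along the anti-diagonal `j-i`, each
  band intersection is further cut into time slices of `Wt` partitions
  along the split index `k`, and the resulting `(ii, jj, i0, tt)` tiles
  execute along wavefronts `w = ii + jj`; same-wavefront tiles in
  different diagonal bands are independent and can run concurrently
  (`--threads`).

`validate` proves the schedule for a given `N` by brute force: every
flow/anti/output dependence of the nest must be ordered by the schedule,
and no dependence may connect two equal-wavefront tiles of different
diagonal bands.

## Worked example

```sh
$ printf '>tRNA_frag\nGCGGAUUUAGCUCAGUUGGG\n' > demo.fa
$ nusstile fold demo.fa --engine tiled --ws 4 --wt 4
>tRNA_frag
GCGGAUUUAGCUCAGUUGGG
.(((()))(())((()))).
```

The structure has 9 base pairs (count the `(`), the maximum number of
non-crossing AU/GC/GU pairings for this fragment — here including the
sharp turns a loop-length constraint would forbid.

```sh
$ nusstile validate --n 20 --ws 4 --wt 4
N=20 ws=4 wt=4: 22687 dependences over 1520 instances; schedule VALID
```

All 22 687 dependences among the 1 520 statement instances of the N=20
nest are ordered by the tiled schedule — the tiling is legal at this size.

The wavefront idea in miniature (the per-tile dependence pattern, a 3×3×3
box with distance vectors `(0,0,1)`, `(0,1,0)`, `(1,0,-1)`):

```sh
$ nusstile demo
box (3, 3, 3), distance vectors [(0, 0, 1), (0, 1, 0), (1, 0, -1)]
t0: [(0, 0, 0)]
t1: [(0, 0, 1), (0, 1, 0)]
t2: [(0, 0, 2), (0, 1, 1), (0, 2, 0), (1, 0, 0)]
...
t8: [(2, 2, 2)]
TIME3: [(1, 2, 2), (2, 0, 2), (2, 1, 1), (2, 1, 2), (2, 2, 0), (2, 2, 1), (2, 2, 2)]
slices legal under lexicographic order: True
```

Each partition `t0 … t8` holds mutually independent points (the earliest-
start time of each point is the length of the longest dependence chain
reaching it); three consecutive partitions merge into one time slice.

Benchmarking (timings are hardware-dependent; the harness verifies every
engine's matrix against the reference before reporting):

```sh
nusstile bench --lengths 500,1000,2500 --widths 16x16 --threads 1,4 --out bench.tsv
```

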