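"""Maximum base-pair RNA folding.

Given a strand ``X = x_0 ... x_{N-1}`` over the alphabet ``{A, U, G, C}``,
the folding problem solved here is: find a maximum-cardinality set of
non-crossing base pairs, where a pair is admissible iff it is AU, GC or the
GU wobble.  The integer score matrix ``S`` satisfies, for
``0 <= i < j <= N-1``,

    S[i, j] = max( S[i+1, j-1] + sigma(x_i, x_j),
                   max_{0 <= k < j-i} ( S[i, i+k] + S[i+k+1, j] ) )

with ``S[i, j] = 0`` whenever ``j <= i``.  ``S[0, N-1]`` is the maximum
number of non-crossing matchings for the whole strand.

.. note::
   **No minimum hairpin-loop length is imposed**: adjacent bases may pair,
   exactly as the recurrence above allows.  Many folding tools forbid such
   sharp turns, so scores reported here can exceed those of
   loop-constrained folders.

Two engines fill the matrix:

* :func:`fold_reference` -- the plain triangular loop nest, row index ``i``
  descending, split maximisation (statement S1, for every split ``k``)
  followed by the pairing update (statement S2) for each cell.
* :func:`fold_transpose` -- stores each computed value at both ``S[i, j]``
  and ``S[j, i]``, so the split maximisation reads two row-contiguous
  slices instead of a row and a column; better cache behaviour on long
  strands.  Its upper triangle is identical to the reference engine's.

:func:`traceback` recovers one optimal structure from a completed matrix
and renders it in dot-bracket notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "PAIR_SCORE",
    "RnaValidationError",
    "FastaError",
    "TracebackError",
    "RnaSequence",
    "SecondaryStructure",
    "FoldResult",
    "sigma",
    "fold_reference",
    "fold_transpose",
    "traceback",
    "parse_fasta",
    "write_results",
    "summary_tsv",
    "validate_score_matrix",
]

ALPHABET = "AUGC"
_CODES = {base: code for code, base in enumerate(ALPHABET)}

#: ``PAIR_SCORE[code_a, code_b] == 1`` iff {a, b} is AU, GC or GU (unordered).
PAIR_SCORE = np.zeros((4, 4), dtype=np.int32)
for _a, _b in (("A", "U"), ("G", "C"), ("G", "U")):
    PAIR_SCORE[_CODES[_a], _CODES[_b]] = 1
    PAIR_SCORE[_CODES[_b], _CODES[_a]] = 1
del _a, _b


class RnaValidationError(ValueError):
    """A residue outside {A, U, G, C} (after normalization) was seen."""


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class TracebackError(RuntimeError):
    """The score matrix is inconsistent with the recurrence."""


def _normalize(raw: str) -> str:
    return raw.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA strand.

    ``residues`` must already be normalized (uppercase, U not T); use
    :meth:`from_string` to build one from arbitrary user input.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise RnaValidationError("empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise RnaValidationError(
                f"invalid residue(s) {sorted(bad)!r} in sequence {self.name!r}; "
                f"only A, U, G, C are accepted (IUPAC ambiguity codes are rejected)"
            )

    @classmethod
    def from_string(cls, raw: str, name: str = "") -> "RnaSequence":
        """Normalize (lowercase -> upper, T -> U) and validate."""
        return cls(_normalize(raw), name)

    @property
    def codes(self) -> np.ndarray:
        """Residues encoded as uint8 in A=0, U=1, G=2, C=3."""
        return np.frombuffer(
            bytes(_CODES[b] for b in self.residues), dtype=np.uint8
        ).copy()

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def sigma(a: str, b: str) -> int:
    """Pairing indicator: 1 for AU, GC, GU (unordered), else 0."""
    a = _normalize(a)
    b = _normalize(b)
    if a not in _CODES or b not in _CODES:
        raise RnaValidationError(f"invalid nucleotide pair ({a!r}, {b!r})")
    return int(PAIR_SCORE[_CODES[a], _CODES[b]])


def fold_reference(seq: RnaSequence) -> np.ndarray:
    """Fill the score matrix in the original loop order.

    Rows are visited with ``i`` descending, columns with ``j`` ascending;
    for each cell all splits (S1) are applied before the pairing update
    (S2).  Returns an ``N x N`` int32 matrix whose lower triangle is zero.
    """
    codes = seq.codes
    n = len(seq)
    s = np.zeros((n, n), dtype=np.int32)
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            # S1, k = 0 .. j-i-1: S[i,j] = max(S[i,j], S[i,i+k] + S[i+k+1,j])
            best = int((s[i, i:j] + s[i + 1 : j + 1, j]).max())
            # S2: S[i,j] = max(S[i,j], S[i+1,j-1] + sigma(x_i, x_j))
            stack = (int(s[i + 1, j - 1]) if j > i + 1 else 0) + int(
                PAIR_SCORE[codes[i], codes[j]]
            )
            if stack > best:
                best = stack
            s[i, j] = best
    return s


def fold_transpose(seq: RnaSequence) -> np.ndarray:
    """Cache-friendly engine mirroring values into the lower triangle.

    As each cell value is produced it is stored at both ``S[i, j]`` and
    ``S[j, i]``; the split maximisation then reads ``S[i, i+k]`` and
    ``S[j, i+k+1]`` -- two row-contiguous slices.  The upper triangle is
    elementwise equal to :func:`fold_reference`; the lower triangle holds
    the transpose rather than zeros.
    """
    codes = seq.codes
    n = len(seq)
    s = np.zeros((n, n), dtype=np.int32)
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            best = int((s[i, i:j] + s[j, i + 1 : j + 1]).max())
            stack = (int(s[i + 1, j - 1]) if j > i + 1 else 0) + int(
                PAIR_SCORE[codes[i], codes[j]]
            )
            if stack > best:
                best = stack
            s[i, j] = best
            s[j, i] = best
    return s


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing pairing of a strand of given length."""

    length: int
    pairs: frozenset

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair {(i, j)} out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"index reused by pair {(i, j)}")
            seen.add(i)
            seen.add(j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                ip, jp = ordered[b]
                if i < ip < j < jp:
                    raise ValueError(f"crossing pairs {(i, j)} and {(ip, jp)}")

    @classmethod
    def from_pairs(cls, length: int, pairs: Iterable) -> "SecondaryStructure":
        return cls(length, frozenset((int(i), int(j)) for i, j in pairs))

    @property
    def dotbracket(self) -> str:
        out = ["."] * self.length
        for i, j in self.pairs:
            out[i] = "("
            out[j] = ")"
        return "".join(out)

    def __len__(self) -> int:
        return self.length


def _cell(s: np.ndarray, a: int, b: int) -> int:
    # Treat diagonal and sub-diagonal entries as zero so that matrices with
    # a mirrored lower triangle trace back identically to reference ones.
    return int(s[a, b]) if b > a else 0


def traceback(seq: RnaSequence, s: np.ndarray) -> SecondaryStructure:
    """Recover one optimal structure from a completed score matrix.

    Deterministic rule at each cell: prefer the pairing case
    ``S[i+1, j-1] + sigma`` whenever it attains the cell value (adding the
    pair only when sigma is 1), otherwise take the smallest split ``k``
    attaining it.  The result has exactly ``S[0, N-1]`` pairs.
    """
    codes = seq.codes
    n = len(seq)
    pairs: list = []
    stack = [(0, n - 1)] if n > 1 else []
    while stack:
        i, j = stack.pop()
        if j <= i:
            continue
        target = _cell(s, i, j)
        if target == 0:
            continue
        sig = int(PAIR_SCORE[codes[i], codes[j]])
        if _cell(s, i + 1, j - 1) + sig == target:
            if sig:
                pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(j - i):
            if _cell(s, i, i + k) + _cell(s, i + k + 1, j) == target:
                stack.append((i, i + k))
                stack.append((i + k + 1, j))
                break
        else:
            raise TracebackError(
                f"no recurrence case attains S[{i},{j}] = {target}"
            )
    return SecondaryStructure.from_pairs(n, pairs)


def validate_score_matrix(s: np.ndarray, *, mirrored: bool = False) -> None:
    """Raise ``ValueError`` if ``s`` violates the score-matrix contract.

    Checks: zero (or mirrored) lower triangle, the pairing upper bound
    ``S[i,j] <= floor((j-i+1)/2)``, and monotonicity in both directions.
    """
    n = s.shape[0]
    if s.shape != (n, n):
        raise ValueError("score matrix must be square")
    lower = np.tril(s)
    if mirrored:
        if not np.array_equal(np.tril(s, -1), np.triu(s, 1).T):
            raise ValueError("lower triangle is not the transpose of the upper")
        if np.diagonal(s).any():
            raise ValueError("nonzero diagonal")
    elif lower.any():
        raise ValueError("nonzero entry on or below the diagonal")
    ii, jj = np.triu_indices(n, 1)
    vals = s[ii, jj]
    if (vals < 0).any() or (vals > (jj - ii + 1) // 2).any():
        raise ValueError("entry outside [0, floor((j-i+1)/2)]")
    up = np.triu(s, 1)
    if n >= 2:
        if (up[:-1, 1:] < np.triu(s[1:, 1:], 1))[np.triu_indices(n - 1)].any():
            raise ValueError("monotonicity S[i,j] >= S[i+1,j] violated")
        if (up[:-1, 1:] < np.triu(s[:-1, :-1], 1))[np.triu_indices(n - 1)].any():
            raise ValueError("monotonicity S[i,j] >= S[i,j-1] violated")


# ---------------------------------------------------------------------------
# FASTA in / results out


def parse_fasta(path) -> list:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Records are normalized (case, T -> U) and validated; an empty file or
    an illegal character raises :class:`FastaError` naming the file and
    record.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise FastaError(f"{path}: {exc}") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        try:
            out.append(RnaSequence.from_string(str(rec.seq), name=rec.id))
        except RnaValidationError as exc:
            raise FastaError(f"{path}, record {rec.id!r}: {exc}") from exc
    return out


@dataclass(frozen=True)
class FoldResult:
    """One folded record: sequence, optimal score and one optimal structure."""

    seq: RnaSequence
    score: int
    structure: SecondaryStructure


def write_results(results: Sequence[FoldResult]) -> str:
    """Render results in Vienna layout: name, sequence line, structure line."""
    blocks = []
    for r in results:
        blocks.append(f">{r.seq.name}\n{r.seq.residues}\n{r.structure.dotbracket}\n")
    return "".join(blocks)


def summary_tsv(results: Sequence[FoldResult]) -> str:
    """Per-record TSV summary: name, length, maximum pair count."""
    lines = ["name\tlength\tscore"]
    for r in results:
        lines.append(f"{r.seq.name}\t{len(r.seq)}\t{r.score}")
    return "\n".join(lines) + "\n"
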