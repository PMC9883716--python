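"""Maximum-score (Viterbi) alignment by dynamic programming.

Two classic local-alignment variants are implemented exactly as stated in
their recurrence form:

* Algorithm I tracks the optimal score of prefixes ending with a match
  (``X``), a deletion (``Y``) or an insertion (``Z``); it considers
  insertions after deletions but not deletions after insertions (the two
  orders always score the same, so one suffices).
* Algorithm II folds the cell maximum into ``W = max(X, Y, Z, 0)`` and gives
  identical scores whenever a_D <= b_D and a_I <= b_I.

Gap scores use the a + b*(k-1) convention for a length-k gap.  A global
affine aligner and the score transformations that leave optima invariant
(positive scaling; per-sequence shifts for global alignment) round out the
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import Alphabet, AlnprobError, ScoreScheme

__all__ = [
    "Sequence",
    "LocalAlignment",
    "DpTables",
    "align_local_algI",
    "align_local_algII",
    "traceback",
    "align_global",
    "transform_scheme",
    "score_columns",
]

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")

# alignment column operations: ("M", x, y), ("D", x), ("I", y)
Column = tuple


@dataclass
class Sequence:
    """A named sequence over the scheme's alphabet (case-folded to upper)."""

    id: str
    letters: str

    def __post_init__(self) -> None:
        self.letters = self.letters.upper()

    def __len__(self) -> int:
        return len(self.letters)

    def encode(self, alphabet: Alphabet) -> np.ndarray:
        for pos, c in enumerate(self.letters):
            if c not in alphabet.letters:
                raise AlnprobError(
                    f"sequence {self.id!r}: letter {c!r} at position {pos} "
                    f"is not in alphabet {''.join(alphabet.letters)}"
                )
        return alphabet.encode(self.letters)


@dataclass
class LocalAlignment:
    """An alignment of R[r_start:r_end] to Q[q_start:q_end].

    Coordinates are 0-based half-open.  ``columns`` lists the operations
    ("M", x, y) / ("D", x) / ("I", y); the empty alignment has score 0.
    """

    r_start: int
    r_end: int
    q_start: int
    q_end: int
    columns: list[Column]
    score: float

    def __post_init__(self) -> None:
        nm = sum(1 for c in self.columns if c[0] == "M")
        nd = sum(1 for c in self.columns if c[0] == "D")
        ni = sum(1 for c in self.columns if c[0] == "I")
        if self.r_end - self.r_start != nm + nd:
            raise AlnprobError("reference span does not match columns")
        if self.q_end - self.q_start != nm + ni:
            raise AlnprobError("query span does not match columns")

    @property
    def cigar(self) -> str:
        """Compact run-length string, e.g. '5M1D3M'."""
        out: list[str] = []
        run, n = None, 0
        for c in self.columns:
            if c[0] == run:
                n += 1
            else:
                if run is not None:
                    out.append(f"{n}{run}")
                run, n = c[0], 1
        if run is not None:
            out.append(f"{n}{run}")
        return "".join(out) or "*"


def score_columns(columns: list[Column], scheme: ScoreScheme) -> float:
    """Recompute an alignment's score: S_xy per match column plus
    a + b*(k-1) per maximal gap run."""
    ab = scheme.alphabet
    total = 0.0
    prev = None
    for col in columns:
        op = col[0]
        if op == "M":
            total += scheme.S[ab.index(col[1]), ab.index(col[2])]
        elif op == "D":
            total += scheme.b_D if prev == "D" else scheme.a_D
        elif op == "I":
            total += scheme.b_I if prev == "I" else scheme.a_I
        else:
            raise AlnprobError(f"unknown column op {op!r}")
        prev = op
    return total


@dataclass
class DpTables:
    """Filled DP matrices plus everything traceback needs."""

    kind: Literal["I", "II"]
    X: np.ndarray  # X for Algorithm I, W for Algorithm II
    Y: np.ndarray
    Z: np.ndarray
    best_score: float
    best_cells: list[tuple[int, int]]
    R: Sequence = field(repr=False)
    Q: Sequence = field(repr=False)


def _prep(R: Sequence, Q: Sequence, scheme: ScoreScheme):
    if not scheme.gapped:
        raise AlnprobError("local alignment requires gap scores")
    r = R.encode(scheme.alphabet)
    q = Q.encode(scheme.alphabet)
    if scheme.a_D > scheme.b_D or scheme.a_I > scheme.b_I:
        logger.warning(
            "a > b on some gap side: Algorithms I and II may disagree "
            "(II can split a long gap into several first-gap openings)"
        )
    return r, q


def align_local_algI(
    R: Sequence, Q: Sequence, scheme: ScoreScheme
) -> tuple[float, DpTables]:
    """Local alignment, variant tracking match/deletion/insertion endings."""
    r, q = _prep(R, Q, scheme)
    m, n = len(r), len(q)
    aD, bD, aI, bI = scheme.a_D, scheme.b_D, scheme.a_I, scheme.b_I
    X = np.zeros((m + 1, n + 1))
    Y = np.full((m + 1, n + 1), NEG_INF)
    Z = np.full((m + 1, n + 1), NEG_INF)
    S = scheme.S
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            X[i, j] = (
                max(X[i - 1, j - 1], Y[i - 1, j - 1], Z[i - 1, j - 1], 0.0)
                + S[r[i - 1], q[j - 1]]
            )
            Y[i, j] = max(X[i - 1, j] + aD, Y[i - 1, j] + bD)
            Z[i, j] = max(X[i, j - 1] + aI, Y[i, j - 1] + aI, Z[i, j - 1] + bI)
    best = float(X.max()) if X.size else 0.0
    best = max(best, 0.0)
    cells = (
        [(int(i), int(j)) for i, j in np.argwhere(X == best)]
        if best > 0
        else []
    )
    return best, DpTables("I", X, Y, Z, best, sorted(cells), R, Q)


def align_local_algII(
    R: Sequence, Q: Sequence, scheme: ScoreScheme
) -> tuple[float, DpTables]:
    """Local alignment, variant with the folded cell maximum W."""
    r, q = _prep(R, Q, scheme)
    m, n = len(r), len(q)
    aD, bD, aI, bI = scheme.a_D, scheme.b_D, scheme.a_I, scheme.b_I
    W = np.zeros((m + 1, n + 1))
    Y = np.full((m + 1, n + 1), NEG_INF)
    Z = np.full((m + 1, n + 1), NEG_INF)
    S = scheme.S
    for i in range(1, m + 1):
        for j in range(0, n + 1):
            Y[i, j] = max(W[i - 1, j] + aD, Y[i - 1, j] + bD)
            if j > 0:
                Z[i, j] = max(W[i, j - 1] + aI, Z[i, j - 1] + bI)
                W[i, j] = max(
                    W[i - 1, j - 1] + S[r[i - 1], q[j - 1]],
                    Y[i, j],
                    Z[i, j],
                    0.0,
                )
    for j in range(1, n + 1):  # i = 0 row of Z per the stated ranges
        Z[0, j] = max(W[0, j - 1] + aI, Z[0, j - 1] + bI)
    best = float(W.max())
    cells = (
        [(int(i), int(j)) for i, j in np.argwhere(W == best)]
        if best > 0
        else []
    )
    return best, DpTables("II", W, Y, Z, best, sorted(cells), R, Q)


def traceback(tables: DpTables, scheme: ScoreScheme) -> LocalAlignment:
    """Recover one optimal local alignment from filled tables.

    Deterministic tie-break: prefer a match step over a deletion over an
    insertion over a local restart; among equal-scoring endpoints the
    smallest (i, j) is chosen.  The recomputed column score equals
    ``best_score`` exactly.
    """
    if not tables.best_cells:
        return LocalAlignment(0, 0, 0, 0, [], 0.0)
    i, j = tables.best_cells[0]
    r, q = tables.R.letters, tables.Q.letters
    S = scheme.S
    ab = scheme.alphabet
    aD, bD, aI, bI = scheme.a_D, scheme.b_D, scheme.a_I, scheme.b_I
    sc = lambda i, j: S[ab.index(r[i - 1]), ab.index(q[j - 1])]  # noqa: E731
    cols: list[Column] = []
    r_end, q_end = i, j
    X, Y, Z = tables.X, tables.Y, tables.Z

    if tables.kind == "II":
        state = "W"
        while True:
            if state == "W":
                v = X[i, j]
                if v == 0.0 and (i == 0 or j == 0):
                    break
                if i > 0 and j > 0 and v == X[i - 1, j - 1] + sc(i, j):
                    cols.append(("M", r[i - 1], q[j - 1]))
                    i, j = i - 1, j - 1
                elif v == Y[i, j]:
                    state = "Y"
                elif v == Z[i, j]:
                    state = "Z"
                else:  # local restart
                    break
            elif state == "Y":
                v = Y[i, j]
                cols.append(("D", r[i - 1]))
                if v == X[i - 1, j] + aD:
                    i, state = i - 1, "W"
                else:
                    i = i - 1
            else:  # Z
                v = Z[i, j]
                cols.append(("I", q[j - 1]))
                if v == X[i, j - 1] + aI:
                    j, state = j - 1, "W"
                else:
                    j = j - 1
    else:
        state = "X"
        while True:
            if state == "X":
                # X cell: a match column was consumed entering here; compare
                # candidates in the exact form the recursion computed them
                v = X[i, j]
                s = sc(i, j)
                cols.append(("M", r[i - 1], q[j - 1]))
                i, j = i - 1, j - 1
                if i > 0 and j > 0 and v == X[i, j] + s:
                    state = "X"
                elif v == Y[i, j] + s:
                    state = "Y"
                elif v == Z[i, j] + s:
                    state = "Z"
                else:
                    break
            elif state == "Y":
                v = Y[i, j]
                cols.append(("D", r[i - 1]))
                if v == X[i - 1, j] + aD:
                    i = i - 1
                    if i == 0:  # border X is the local restart
                        break
                    state = "X"
                else:
                    i = i - 1
            else:
                v = Z[i, j]
                cols.append(("I", q[j - 1]))
                if v == X[i, j - 1] + aI:
                    j = j - 1
                    if j == 0:
                        break
                    state = "X"
                elif v == Y[i, j - 1] + aI:
                    j, state = j - 1, "Y"
                else:
                    j = j - 1
    cols.reverse()
    aln = LocalAlignment(i, r_end, j, q_end, cols, tables.best_score)
    recomputed = score_columns(cols, scheme)
    if abs(recomputed - tables.best_score) > 1e-9 * max(
        1.0, abs(tables.best_score)
    ):
        raise AssertionError(
            f"traceback score {recomputed} != best {tables.best_score}"
        )
    return aln


def align_global(
    R: Sequence, Q: Sequence, scheme: ScoreScheme
) -> tuple[float, LocalAlignment]:
    """End-to-end optimal affine-gap alignment (same a + b*(k-1) convention)."""
    if not scheme.gapped:
        raise AlnprobError("global alignment requires gap scores")
    r = R.encode(scheme.alphabet)
    q = Q.encode(scheme.alphabet)
    m, n = len(r), len(q)
    aD, bD, aI, bI = scheme.a_D, scheme.b_D, scheme.a_I, scheme.b_I
    S = scheme.S
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    Z = np.full((m + 1, n + 1), NEG_INF)
    X[0, 0] = 0.0
    for i in range(1, m + 1):
        Y[i, 0] = aD + bD * (i - 1)
    for j in range(1, n + 1):
        Z[0, j] = aI + bI * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            X[i, j] = (
                max(X[i - 1, j - 1], Y[i - 1, j - 1], Z[i - 1, j - 1])
                + S[r[i - 1], q[j - 1]]
            )
            Y[i, j] = max(
                X[i - 1, j] + aD, Y[i - 1, j] + bD, Z[i - 1, j] + aD
            )
            Z[i, j] = max(
                X[i, j - 1] + aI, Y[i, j - 1] + aI, Z[i, j - 1] + bI
            )
    score = float(max(X[m, n], Y[m, n], Z[m, n]))
    # traceback
    cols: list[Column] = []
    i, j = m, n
    state = (
        "X"
        if score == X[m, n]
        else ("Y" if score == Y[m, n] else "Z")
    )
    rl, ql = R.letters, Q.letters
    while i > 0 or j > 0:
        if state == "X":
            v = X[i, j]
            s = S[r[i - 1], q[j - 1]]
            cols.append(("M", rl[i - 1], ql[j - 1]))
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            # compare candidates in the exact form the recursion computed
            if v == X[i, j] + s:
                state = "X"
            elif v == Y[i, j] + s:
                state = "Y"
            else:
                state = "Z"
        elif state == "Y":
            v = Y[i, j]
            cols.append(("D", rl[i - 1]))
            if i == 1 and j == 0:
                i = 0
                break
            if v == X[i - 1, j] + aD:
                state = "X"
            elif v == Z[i - 1, j] + aD:
                state = "Z"
            i -= 1
        else:
            v = Z[i, j]
            cols.append(("I", ql[j - 1]))
            if j == 1 and i == 0:
                j = 0
                break
            if v == X[i, j - 1] + aI:
                state = "X"
            elif v == Y[i, j - 1] + aI:
                state = "Y"
            j -= 1
    cols.reverse()
    return score, LocalAlignment(0, m, 0, n, cols, score)


def transform_scheme(
    scheme: ScoreScheme,
    mode: Literal["scale", "shift_ref", "shift_query"],
    value: float,
) -> ScoreScheme:
    """Score transformations with one degree of freedom each.

    ``scale`` multiplies every score and t by k > 0 (local and global optima
    unchanged); ``shift_ref`` adds h to a_D, b_D and every S_xy, which adds
    exactly h*m to every global score; ``shift_query`` is symmetric in the
    insertions, adding h*n.
    """
    if mode == "scale":
        if not value > 0:
            raise AlnprobError("scale factor must be positive")
        g = lambda x: None if x is None else x * value  # noqa: E731
        return ScoreScheme(
            scheme.alphabet, scheme.S * value, t=scheme.t * value,
            a_D=g(scheme.a_D), b_D=g(scheme.b_D),
            a_I=g(scheme.a_I), b_I=g(scheme.b_I),
        )
    if mode == "shift_ref":
        return ScoreScheme(
            scheme.alphabet, scheme.S + value, t=scheme.t,
            a_D=scheme.a_D + value, b_D=scheme.b_D + value,
            a_I=scheme.a_I, b_I=scheme.b_I,
        )
    if mode == "shift_query":
        return ScoreScheme(
            scheme.alphabet, scheme.S + value, t=scheme.t,
            a_D=scheme.a_D, b_D=scheme.b_D,
            a_I=scheme.a_I + value, b_I=scheme.b_I + value,
        )
    raise AlnprobError(f"unknown transform mode {mode!r}")
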