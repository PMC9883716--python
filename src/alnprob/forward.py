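"""Sum-over-alignments probability calculations.

The Forward algorithm sums, over every path of the PHMM, the probability
ratio of that path to the null alignment (zero aligned letters).  Only the
primed invariants S', a', b' enter the recurrences, so the result is shared
by every PHMM realization of one scoring scheme — the free choice of
omega_D, omega_I changes the null probability mu_G but not the ratio.

Model A (the symmetric affine topology) uses the sum-product counterpart of
the W-folded Viterbi recursion, with a "+1" per cell that counts the
distinguishable ways of splitting unaligned flanks around an empty core.
Model B restricts paths to cores that begin and end with an aligned pair and
never delete immediately after inserting; its Forward is the sum-product
counterpart of the X/Y/Z recursion.  The two totals genuinely differ: the
path set is part of the model.

A brute-force path enumerator over the same path semantics serves as the
independent oracle for both, and a forward-backward combination yields the
posterior probability that any R_i is aligned to any Q_j (column
reliability).  Tables are kept in scaled arithmetic (per-row scaling
exponents) so that primed factors like e^{91/30} do not overflow on long
sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import logsumexp, softmax

from .core import AlnprobError, LetterProbs, PhmmParams, PrimedParams
from .dp import LocalAlignment, Sequence

__all__ = [
    "ForwardResult",
    "PosteriorTable",
    "NullProb",
    "forward_modelA",
    "forward_modelB",
    "enumerate_paths",
    "null_probability",
    "posterior_match_probs",
    "column_reliability",
    "mapping_probability",
    "hybrid_score",
    "background_cprime",
]

logger = logging.getLogger(__name__)

#: rows are rescaled once any scaled table entry exceeds this
_SCALE_LIMIT = 2.0**512


@dataclass
class ForwardResult:
    """Total path-probability ratio and the scaled per-cell tables.

    ``Wp[i, j] * exp(row_log[i])`` is the true W' value (for model B the
    table holds X').  ``total_ratio`` is sum(paths) prob(path,R,Q)/mu_G and
    is always >= 1 because the null paths alone contribute >= 1.
    """

    topology: Literal["A", "B"]
    m: int
    n: int
    log_total: float
    Wp: np.ndarray = field(repr=False)
    Xp: np.ndarray = field(repr=False)
    row_log: np.ndarray = field(repr=False)

    @property
    def total_ratio(self) -> float:
        try:
            return math.exp(self.log_total)
        except OverflowError:
            return math.inf


@dataclass
class PosteriorTable:
    """P[i, j] = posterior probability that R_i is aligned to Q_j."""

    P: np.ndarray


@dataclass
class NullProb:
    """Probability mu (or mu_G) of the null alignment; also kept in log."""

    mu: float
    log_mu: float


def _encode_pair(R: Sequence, Q: Sequence, primed: PrimedParams):
    return R.encode(primed.alphabet), Q.encode(primed.alphabet)


def _check_convergence(primed: PrimedParams) -> None:
    if primed.b_D_pr >= 1.0 or primed.b_I_pr >= 1.0:
        logger.warning(
            "gap extension b' >= 1: gap probabilities do not converge as a "
            "geometric series (results are still finite for finite sequences)"
        )


def forward_modelA(
    R: Sequence, Q: Sequence, primed: PrimedParams
) -> ForwardResult:
    """Forward algorithm for the symmetric affine topology (model A).

    Recurrences (true values; the implementation scales rows):
        W'_ij = X'_ij + Y'_ij + Z'_ij + 1
        X'_ij = W'_{i-1,j-1} * S'_{R_i Q_j}
        Y'_ij = W'_{i-1,j} * a'_D + Y'_{i-1,j} * b'_D
        Z'_ij = W'_{i,j-1} * a'_I + Z'_{i,j-1} * b'_I
    with X', Z' zero on the i=0 / j=0 borders as appropriate, and
    total = sum_ij W'_ij.
    """
    _check_convergence(primed)
    r, q = _encode_pair(R, Q, primed)
    m, n = len(r), len(q)
    Sp = primed.Sprime
    aD, bD = primed.a_D_pr, primed.b_D_pr
    aI, bI = primed.a_I_pr, primed.b_I_pr
    Xp = np.zeros((m + 1, n + 1))
    Yp = np.zeros((m + 1, n + 1))
    Zp = np.zeros((m + 1, n + 1))
    Wp = np.zeros((m + 1, n + 1))
    row_log = np.zeros(m + 1)
    # row 0: X' = Y' = 0; Z' accumulates insertions along j
    Wp[0, 0] = 1.0
    for j in range(1, n + 1):
        Zp[0, j] = Wp[0, j - 1] * aI + Zp[0, j - 1] * bI
        Wp[0, j] = Zp[0, j] + 1.0
    L = 0.0
    for i in range(1, m + 1):
        unit = math.exp(-L) if L < 700.0 else 0.0
        Xp[i, 1:] = Wp[i - 1, :-1] * Sp[r[i - 1], q]
        Yp[i, :] = Wp[i - 1, :] * aD + Yp[i - 1, :] * bD
        Wp[i, 0] = Yp[i, 0] + unit
        Xi, Yi, Zi, Wi = Xp[i], Yp[i], Zp[i], Wp[i]
        for j in range(1, n + 1):
            z = Wi[j - 1] * aI + Zi[j - 1] * bI
            Zi[j] = z
            Wi[j] = Xi[j] + Yi[j] + z + unit
        mx = Wi.max()
        if not np.isfinite(mx):
            raise AlnprobError(
                "numeric overflow in Forward despite row scaling"
            )
        if mx > _SCALE_LIMIT:
            for T in (Xi, Yi, Zi, Wi):
                T /= mx
            L += math.log(mx)
        row_log[i] = L
    core = Xp + Yp + Zp
    row_sums = core.sum(axis=1)
    terms = [math.log((m + 1) * (n + 1))]
    for i in range(m + 1):
        if row_sums[i] > 0:
            terms.append(math.log(row_sums[i]) + row_log[i])
    log_total = float(logsumexp(terms))
    return ForwardResult("A", m, n, log_total, Wp, Xp, row_log)


def forward_modelB(
    R: Sequence, Q: Sequence, primed: PrimedParams
) -> ForwardResult:
    """Forward algorithm for the stricter topology (model B).

    Sum-product counterpart of the X/Y/Z Viterbi recursion: alignment cores
    start and end with an aligned pair, a gap of length k is a single gap
    (no splitting), and deletions never immediately follow insertions:
        X'_ij = (X' + Y' + Z' + 1)_{i-1,j-1} * S'_{R_i Q_j}
        Y'_ij = X'_{i-1,j} * a'_D + Y'_{i-1,j} * b'_D
        Z'_ij = (X'_{i,j-1} + Y'_{i,j-1}) * a'_I + Z'_{i,j-1} * b'_I
    and total = 1 + sum_ij X'_ij.  This total is strictly smaller than model
    A's whenever any gap factor is positive: model B's path set is smaller.
    """
    _check_convergence(primed)
    r, q = _encode_pair(R, Q, primed)
    m, n = len(r), len(q)
    Sp = primed.Sprime
    aD, bD = primed.a_D_pr, primed.b_D_pr
    aI, bI = primed.a_I_pr, primed.b_I_pr
    Xp = np.zeros((m + 1, n + 1))
    Yp = np.zeros((m + 1, n + 1))
    Zp = np.zeros((m + 1, n + 1))
    row_log = np.zeros(m + 1)
    L = 0.0
    for i in range(1, m + 1):
        unit = math.exp(-L) if L < 700.0 else 0.0
        Yp[i, :] = Xp[i - 1, :] * aD + Yp[i - 1, :] * bD
        prev = Xp[i - 1] + Yp[i - 1] + Zp[i - 1]
        Xp[i, 1:] = (prev[:-1] + unit) * Sp[r[i - 1], q]
        Xi, Yi, Zi = Xp[i], Yp[i], Zp[i]
        for j in range(1, n + 1):
            Zi[j] = (Xi[j - 1] + Yi[j - 1]) * aI + Zi[j - 1] * bI
        mx = max(Xi.max(), Yi.max(), Zi.max())
        if not np.isfinite(mx):
            raise AlnprobError(
                "numeric overflow in Forward despite row scaling"
            )
        if mx > _SCALE_LIMIT:
            for T in (Xi, Yi, Zi):
                T /= mx
            L += math.log(mx)
        row_log[i] = L
    row_sums = Xp.sum(axis=1)
    terms = [0.0]  # the single null contribution
    for i in range(m + 1):
        if row_sums[i] > 0:
            terms.append(math.log(row_sums[i]) + row_log[i])
    log_total = float(logsumexp(terms))
    return ForwardResult("B", m, n, log_total, Xp, Xp, row_log)


def enumerate_paths(
    R: Sequence,
    Q: Sequence,
    primed: PrimedParams,
    topology: Literal["A", "B"] = "A",
) -> float:
    """Exhaustive sum of path-probability ratios (the oracle).

    Explicitly enumerates every distinguishable state path, including the
    flank-split variants of identical alignments for model A (an empty core
    can split the unaligned letters (m+1)(n+1) ways; a run of k deletions can
    be any mix of new-gap and extension steps).  Exponential: m + n <= 12.
    """
    m, n = len(R), len(Q)
    if m + n > 12:
        raise AlnprobError("enumerate_paths is exponential; need m + n <= 12")
    r, q = _encode_pair(R, Q, primed)
    Sp = primed.Sprime
    aD, bD = primed.a_D_pr, primed.b_D_pr
    aI, bI = primed.a_I_pr, primed.b_I_pr
    total = 0.0

    if topology == "A":
        total += (m + 1) * (n + 1)  # null paths: every flank split

        def dfs(i: int, j: int, last: str, w: float) -> float:
            acc = 0.0
            if i < m and j < n:
                w2 = w * Sp[r[i], q[j]]
                acc += w2 + dfs(i + 1, j + 1, "M", w2)
            if i < m:
                for f in (aD, bD) if last == "D" else (aD,):
                    w2 = w * f
                    acc += w2 + dfs(i + 1, j, "D", w2)
            if j < n:
                for f in (aI, bI) if last == "I" else (aI,):
                    w2 = w * f
                    acc += w2 + dfs(i, j + 1, "I", w2)
            return acc

        for i0 in range(m + 1):
            for j0 in range(n + 1):
                total += dfs(i0, j0, "", 1.0)
        return total

    # model B: cores start and end with M; one path per gap run; no D after I
    total += 1.0

    def dfsB(i: int, j: int, last: str, w: float) -> float:
        acc = 0.0
        if i < m and j < n:
            w2 = w * Sp[r[i], q[j]]
            acc += w2 + dfsB(i + 1, j + 1, "M", w2)
        if i < m and last in ("M", "D"):
            w2 = w * (bD if last == "D" else aD)
            acc += dfsB(i + 1, j, "D", w2)
        if j < n:
            w2 = w * (bI if last == "I" else aI)
            acc += dfsB(i, j + 1, "I", w2)
        return acc

    for i0 in range(m):
        for j0 in range(n):
            w0 = Sp[r[i0], q[j0]]
            total += w0 + dfsB(i0 + 1, j0 + 1, "M", w0)
    return total


def null_probability(params: PhmmParams, R: Sequence, Q: Sequence) -> NullProb:
    """Probability of the null alignment: all letters in unaligned flanks.

    mu = prod_k omega_D phi_{R_k} * prod_k omega_I psi_{Q_k}
         * (1-omega_D)^2 (1-omega_I)^2 * (1 - gamma [- alpha_D - alpha_I]).
    """
    ab = params.pi.alphabet
    r = R.encode(ab)
    q = Q.encode(ab)
    lp = 0.0
    for idx in r:
        lp += math.log(params.omega_D * params.phi.p[idx])
    for idx in q:
        lp += math.log(params.omega_I * params.psi.p[idx])
    lp += 2.0 * math.log1p(-params.omega_D)
    lp += 2.0 * math.log1p(-params.omega_I)
    if params.topology == "gapless":
        lp += math.log1p(-params.gamma)
    else:
        lp += math.log1p(-(params.gamma + params.alpha_D + params.alpha_I))
    return NullProb(math.exp(lp), lp)


def posterior_match_probs(
    R: Sequence, Q: Sequence, primed: PrimedParams
) -> PosteriorTable:
    """Posterior probability, under model A, that R_i is aligned to Q_j.

    Forward-backward: model A path weights are invariant under jointly
    reversing both sequences, so the backward table is the forward X' table
    of the reversed problem.  A path whose core aligns R_i:Q_j splits
    uniquely into a prefix ending with that match and a suffix starting with
    it, each carrying one S' factor:
        P[i-1, j-1] = X'_ij * X''_{m-i+1, n-j+1} / (S'_{R_i Q_j} * total).
    """
    m, n = len(R), len(Q)
    fwd = forward_modelA(R, Q, primed)
    Rrev = Sequence(R.id, R.letters[::-1])
    Qrev = Sequence(Q.id, Q.letters[::-1])
    bwd = forward_modelA(Rrev, Qrev, primed)
    r, q = _encode_pair(R, Q, primed)
    P = np.zeros((m, n))
    with np.errstate(divide="ignore"):
        lXf = np.log(fwd.Xp)
        lXb = np.log(bwd.Xp)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sp = primed.Sprime[r[i - 1], q[j - 1]]
            if sp == 0.0:
                continue
            lx = lXf[i, j] + fwd.row_log[i]
            lb = lXb[m - i + 1, n - j + 1] + bwd.row_log[m - i + 1]
            if not (np.isfinite(lx) and np.isfinite(lb)):
                continue
            P[i - 1, j - 1] = math.exp(
                lx + lb - math.log(sp) - fwd.log_total
            )
    return PosteriorTable(np.clip(P, 0.0, 1.0))


def column_reliability(
    aln: LocalAlignment, post: PosteriorTable
) -> list[float]:
    """Per-column reliability of an alignment given a posterior table.

    Match columns get P[i, j]; a deletion column gets the posterior
    probability that its reference letter is not aligned to any query letter
    (1 - row sum), and symmetrically for insertions.
    """
    P = post.P
    m, n = P.shape
    if aln.r_end > m or aln.q_end > n:
        raise AlnprobError("alignment coordinates exceed the posterior table")
    out: list[float] = []
    i, j = aln.r_start, aln.q_start
    for col in aln.columns:
        if col[0] == "M":
            out.append(float(P[i, j]))
            i += 1
            j += 1
        elif col[0] == "D":
            out.append(float(max(0.0, 1.0 - P[i, :].sum())))
            i += 1
        else:
            out.append(float(max(0.0, 1.0 - P[:, j].sum())))
            j += 1
    return out


def mapping_probability(scores: list[float], t: float) -> list[float]:
    """Probability that each candidate locus is the correct one.

    p_k = exp(s_k/t) / sum_j exp(s_j/t), assuming exactly one locus is
    correct; computed with max-subtraction for stability.
    """
    if len(scores) == 0:
        raise AlnprobError("mapping_probability needs at least one score")
    if not t > 0:
        raise AlnprobError("temperature t must be positive")
    return list(softmax(np.asarray(scores, dtype=float) / t))


def hybrid_score(
    R: Sequence, Q: Sequence, primed: PrimedParams, t: float
) -> float:
    """Semi-probabilistic local score: max_ij t ln W'_ij.

    The Forward summation over end cells is replaced by maximization, so the
    score integrates over alternative alignments sharing the best end cell
    but still localizes.  Under balanced parameters these scores follow a
    Gumbel distribution with scale lambda = 1/t for random sequences.
    """
    fres = forward_modelA(R, Q, primed)
    with np.errstate(divide="ignore"):
        lw = np.log(fres.Wp) + fres.row_log[:, None]
    return float(t * lw.max())


def background_cprime(
    Sprime: np.ndarray, Phi: LetterProbs, Psi: LetterProbs
) -> float:
    """c' against arbitrary background letter probabilities:
    c' = sum_xy Phi_x Psi_y S'_xy (equals the model c' when Phi=phi, Psi=psi).
    """
    Sprime = np.asarray(Sprime, dtype=float)
    if Sprime.shape != (len(Phi.p), len(Psi.p)):
        raise AlnprobError("S' dimensions do not match the distributions")
    return float(Phi.p @ Sprime @ Psi.p)
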