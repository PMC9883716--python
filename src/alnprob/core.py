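"""Score/probability correspondence for pairwise alignment.

A scoring scheme (substitution matrix ``S``, affine gap scores, temperature
``t``) corresponds to a whole family of pair hidden Markov models (PHMMs):
exponentiating the scores at temperature ``t`` yields "primed" invariants

    S'_xy = exp(S_xy / t)        a' = exp(a / t)        b' = exp(b / t)

that every PHMM in the family shares, while the flank-emission probabilities
``omega_D, omega_I`` remain free.  This module houses that correspondence:

* converting scores to aligned-pair probabilities and back,
* solving for homogeneous letter probabilities (same letter distribution in
  aligned and unaligned regions) at a given temperature,
* finding the special temperature with uniform length probability (c = 1),
* the balanced-length-probability condition C' = 1 for gapped models and the
  temperatures at which it holds,
* feasibility limits on omega (and thus gamma, alpha, beta) from the cubic
  boundary of gamma + alpha_D + alpha_I = 1.

Probabilities are dimensionless; scores and ``t`` share arbitrary "score
units" (only ratios score/t matter).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence as _Seq

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "Alphabet",
    "DNA",
    "ScoreScheme",
    "LetterProbs",
    "PairProbs",
    "PhmmParams",
    "PrimedParams",
    "BalanceReport",
    "AlnprobError",
    "SingularMatrixError",
    "HomogeneityError",
    "InfeasibleError",
    "primed_params",
    "pair_probs_from_scores",
    "scores_from_pair_probs",
    "solve_homogeneous",
    "find_uniform_length_temperature",
    "realize_phmm",
    "classify_balance",
    "find_balanced_temperatures",
    "max_omega_symmetric",
    "limit_params_at_omega",
    "sweep_max_omega",
    "balance_shift",
]

logger = logging.getLogger(__name__)

Topology = Literal["gapless", "linear", "A", "B"]

#: tolerance below which slightly negative probabilities are treated as
#: float noise and clamped to zero
_NEG_TOL = 1e-12

#: |C' - 1| within this band counts as balanced
BALANCE_TOL = 1e-9


class AlnprobError(ValueError):
    """Base class for domain errors raised by this package."""


class SingularMatrixError(AlnprobError):
    """exp(S/t) is singular; the homogeneous linear system has no solution."""


class HomogeneityError(AlnprobError):
    """These values of S and t are not consistent with homogeneous letter
    probabilities (a solved phi or psi component is negative)."""


class InfeasibleError(AlnprobError):
    """A requested PHMM realization violates a probability constraint."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Alphabet:
    """Ordered alphabet; the order fixes matrix row/column indexing."""

    letters: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.letters:
            raise AlnprobError("alphabet must be non-empty")
        if len(set(self.letters)) != len(self.letters):
            raise AlnprobError("alphabet letters must be distinct")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.letters)}
        )

    def __len__(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        try:
            return self._index[letter]  # type: ignore[attr-defined]
        except KeyError:
            raise AlnprobError(
                f"letter {letter!r} is not in alphabet {''.join(self.letters)}"
            ) from None

    def encode(self, letters: _Seq[str]) -> np.ndarray:
        return np.array([self.index(c) for c in letters], dtype=np.intp)


DNA = Alphabet(("A", "C", "G", "T"))


@dataclass
class ScoreScheme:
    """A score-side description: substitution matrix, affine gaps, temperature.

    Gap scores use the convention that a length-k deletion scores
    ``a_D + b_D * (k - 1)`` (first gap score ``a``, extension ``b``); gap
    fields are ``None`` for gapless schemes.
    """

    alphabet: Alphabet
    S: np.ndarray
    t: float = 1.0
    a_D: float | None = None
    b_D: float | None = None
    a_I: float | None = None
    b_I: float | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.alphabet)
        if self.S.shape != (k, k):
            raise AlnprobError(
                f"matrix shape {self.S.shape} does not match alphabet size {k}"
            )
        if not self.t > 0:
            raise AlnprobError("temperature t must be positive")
        gaps = (self.a_D, self.b_D, self.a_I, self.b_I)
        if any(g is None for g in gaps) and any(g is not None for g in gaps):
            raise AlnprobError("specify all four gap scores or none")

    @property
    def gapped(self) -> bool:
        return self.a_D is not None

    @classmethod
    def symmetric(
        cls,
        alphabet: Alphabet,
        S: np.ndarray,
        a: float,
        b: float,
        t: float = 1.0,
    ) -> "ScoreScheme":
        """Scheme with identical deletion and insertion scores."""
        return cls(alphabet, S, t=t, a_D=a, b_D=b, a_I=a, b_I=b)


@dataclass
class LetterProbs:
    """A probability distribution over the alphabet."""

    alphabet: Alphabet
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.alphabet),):
            raise AlnprobError("letter probability vector has wrong length")
        if (self.p < 0).any():
            raise AlnprobError("letter probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise AlnprobError("letter probabilities must sum to 1")

    @classmethod
    def uniform(cls, alphabet: Alphabet) -> "LetterProbs":
        k = len(alphabet)
        return cls(alphabet, np.full(k, 1.0 / k))


@dataclass
class PairProbs:
    """Joint emission probabilities pi[x][y] of the aligned-pair state."""

    alphabet: Alphabet
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        k = len(self.alphabet)
        if self.pi.shape != (k, k):
            raise AlnprobError("pair probability matrix has wrong shape")
        if (self.pi < 0).any():
            raise AlnprobError("pair probabilities must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise AlnprobError("pair probabilities must sum to 1")


@dataclass
class PhmmParams:
    """One concrete PHMM: emission distributions plus transition probabilities.

    ``omega_D, omega_I`` govern unaligned flank letters, ``gamma`` enters (or
    continues) the aligned core, ``alpha``/``beta`` open/extend gaps.  Which
    transition fields exist depends on the topology: gapless has no alpha or
    beta, the linear-gap model has no beta.
    """

    topology: Topology
    phi: LetterProbs
    psi: LetterProbs
    pi: PairProbs
    omega_D: float
    omega_I: float
    gamma: float
    alpha_D: float | None = None
    beta_D: float | None = None
    alpha_I: float | None = None
    beta_I: float | None = None

    def __post_init__(self) -> None:
        for name in ("omega_D", "omega_I", "gamma"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise AlnprobError(f"{name}={v} must lie in [0, 1)")
        if self.topology == "gapless":
            if self.alpha_D is not None or self.beta_D is not None:
                raise AlnprobError("gapless topology has no alpha/beta")
            if not self.gamma < 1:
                raise AlnprobError("gamma must be < 1")
        else:
            if self.alpha_D is None or self.alpha_I is None:
                raise AlnprobError("gapped topology requires alpha_D, alpha_I")
            if self.topology == "linear":
                if self.beta_D is not None or self.beta_I is not None:
                    raise AlnprobError("linear topology has no beta")
            elif self.beta_D is None or self.beta_I is None:
                raise AlnprobError("affine topology requires beta_D, beta_I")
            if not self.gamma + self.alpha_D + self.alpha_I < 1:
                raise InfeasibleError(
                    "gamma + alpha_D + alpha_I = "
                    f"{self.gamma + self.alpha_D + self.alpha_I} must be < 1"
                )


@dataclass
class PrimedParams:
    """Temperature-exponentiated invariants shared by all PHMMs that map to
    one scoring scheme: S' = exp(S/t), a' = exp(a/t), b' = exp(b/t), and
    c' = sum_xy phi_x psi_y S'_xy.  Gapless schemes have a' = b' = 0.
    """

    alphabet: Alphabet
    Sprime: np.ndarray
    c_pr: float
    a_D_pr: float = 0.0
    b_D_pr: float = 0.0
    a_I_pr: float = 0.0
    b_I_pr: float = 0.0

    @property
    def C_pr(self) -> float | None:
        """C' = c' + a'_D/(1-b'_D) + a'_I/(1-b'_I); None when some b' >= 1
        (the gap-extension geometric series diverges)."""
        if self.b_D_pr >= 1.0 or self.b_I_pr >= 1.0:
            return None
        return (
            self.c_pr
            + self.a_D_pr / (1.0 - self.b_D_pr)
            + self.a_I_pr / (1.0 - self.b_I_pr)
        )

    @property
    def symmetric(self) -> bool:
        return (
            self.a_D_pr == self.a_I_pr and self.b_D_pr == self.b_I_pr
        )


@dataclass
class BalanceReport:
    """Classification of a model family's length-probability bias."""

    C_pr: float
    classification: Literal["balanced", "shorter_bias", "longer_bias"]
    tolerance: float = BALANCE_TOL


# ---------------------------------------------------------------------------
# score -> probability conversions


def primed_params(
    scheme: ScoreScheme, phi: LetterProbs, psi: LetterProbs
) -> PrimedParams:
    """Exponentiate a scoring scheme at its temperature.

    c' = sum_xy phi_x psi_y exp(S_xy/t); for gapped schemes also
    a' = exp(a/t), b' = exp(b/t) per gap side.
    """
    _check_dists(scheme, phi, psi)
    Sp = np.exp(scheme.S / scheme.t)
    c_pr = float(phi.p @ Sp @ psi.p)
    if scheme.gapped:
        e = lambda s: math.exp(s / scheme.t)  # noqa: E731
        return PrimedParams(
            scheme.alphabet, Sp, c_pr,
            a_D_pr=e(scheme.a_D), b_D_pr=e(scheme.b_D),
            a_I_pr=e(scheme.a_I), b_I_pr=e(scheme.b_I),
        )
    return PrimedParams(scheme.alphabet, Sp, c_pr)


def pair_probs_from_scores(
    scheme: ScoreScheme, phi: LetterProbs, psi: LetterProbs
) -> tuple[PairProbs, float]:
    """Aligned-pair probabilities implied by a scheme at temperature t.

    pi_xy = phi_x psi_y exp(S_xy/t) / c with c = sum phi psi exp(S/t);
    c is the invariant gamma/(omega_D omega_I) (written c' for gapped
    models), shared by every PHMM realization of the scheme.
    """
    _check_dists(scheme, phi, psi)
    Sp = np.exp(scheme.S / scheme.t)
    w = phi.p[:, None] * psi.p[None, :] * Sp
    c = float(w.sum())
    pi = w / c
    return PairProbs(scheme.alphabet, pi), c


def scores_from_pair_probs(params: PhmmParams, t: float) -> ScoreScheme:
    """Recover the scoring scheme a PHMM corresponds to, at temperature t.

    S_xy = t ln(pi_xy/(phi_x psi_y) * gamma/(omega_D omega_I)): each aligned
    pair replaces one reference-flank and one query-flank emission.
    Affine (model A/B) gap scores: a_D = t ln(alpha_D (1-beta_D) / omega_D),
    b_D = t ln(beta_D / omega_D); linear gaps: a = b = t ln(alpha/omega).
    """
    if not t > 0:
        raise AlnprobError("temperature t must be positive")
    ab = params.pi.alphabet
    _require_positive("pi", params.pi.pi)
    _require_positive("phi", params.phi.p)
    _require_positive("psi", params.psi.p)
    _require_positive("omega_D", params.omega_D)
    _require_positive("omega_I", params.omega_I)
    _require_positive("gamma", params.gamma)
    f = params.gamma / (params.omega_D * params.omega_I)
    S = t * np.log(
        params.pi.pi / (params.phi.p[:, None] * params.psi.p[None, :]) * f
    )
    if params.topology == "gapless":
        return ScoreScheme(ab, S, t=t)
    _require_positive("alpha_D", params.alpha_D)
    _require_positive("alpha_I", params.alpha_I)
    if params.topology == "linear":
        aD = t * math.log(params.alpha_D / params.omega_D)
        aI = t * math.log(params.alpha_I / params.omega_I)
        return ScoreScheme(ab, S, t=t, a_D=aD, b_D=aD, a_I=aI, b_I=aI)
    _require_positive("beta_D", params.beta_D)
    _require_positive("beta_I", params.beta_I)
    aD = t * math.log(params.alpha_D * (1.0 - params.beta_D) / params.omega_D)
    bD = t * math.log(params.beta_D / params.omega_D)
    aI = t * math.log(params.alpha_I * (1.0 - params.beta_I) / params.omega_I)
    bI = t * math.log(params.beta_I / params.omega_I)
    return ScoreScheme(ab, S, t=t, a_D=aD, b_D=bD, a_I=aI, b_I=bI)


# ---------------------------------------------------------------------------
# homogeneous letter probabilities and special temperatures


def solve_homogeneous(
    S: np.ndarray, t: float, alphabet: Alphabet | None = None
) -> tuple[LetterProbs, LetterProbs, float]:
    """Letter probabilities that are identical inside and outside alignments.

    Solves the linear system sum_y exp(S_xy/t) psi'_y = 1 (and its transpose
    for phi), then c = 1/sum(psi') and psi = psi' * c.  The returned
    distributions satisfy phi_x = sum_y pi_xy and psi_y = sum_x pi_xy for the
    pair probabilities implied by (S, t).

    Raises :class:`SingularMatrixError` if exp(S/t) is singular and
    :class:`HomogeneityError` if any solved component is negative beyond
    float noise (noise within 1e-12 is clamped to zero).
    """
    S = np.asarray(S, dtype=float)
    if alphabet is None:
        alphabet = _default_alphabet(S.shape[0])
    with np.errstate(over="ignore", under="ignore"):
        Sp = np.exp(S / t)
    ones = np.ones(S.shape[0])
    try:
        psi_p = np.linalg.solve(Sp, ones)
        phi_p = np.linalg.solve(Sp.T, ones)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(f"exp(S/t) is singular at t={t}") from exc
    if (
        not np.isfinite(psi_p).all()
        or not np.isfinite(phi_p).all()
        or psi_p.sum() == 0.0
        or phi_p.sum() == 0.0
    ):
        raise SingularMatrixError(
            f"exp(S/t) is numerically degenerate at t={t}"
        )
    c = 1.0 / float(psi_p.sum())
    psi = _clamp_probs(psi_p * c, "psi", t)
    phi = _clamp_probs(phi_p / phi_p.sum(), "phi", t)
    return LetterProbs(alphabet, phi), LetterProbs(alphabet, psi), c


def _homog_c(S: np.ndarray, t: float) -> float:
    with np.errstate(over="ignore", under="ignore"):
        Sp = np.exp(S / t)
    psi_p = np.linalg.solve(Sp, np.ones(S.shape[0]))
    total = float(psi_p.sum())
    if not np.isfinite(total) or total == 0.0:
        raise SingularMatrixError(
            f"exp(S/t) is numerically degenerate at t={t}"
        )
    return 1.0 / total


def find_uniform_length_temperature(
    S: np.ndarray,
    n_scan: int = 512,
    rtol: float = 1e-12,
) -> float:
    """The finite temperature at which c(t) = 1 with valid letter probabilities.

    At this t the gapless model has uniform length probability (no prior bias
    over alignment lengths: gamma*omega_D*omega_I = 1).  c(t) - 1 is bracketed
    on a log-spaced scan of t in [1e-3, 1e6] * max|S| and refined by bisection
    (brentq) to relative tolerance ``rtol``.  There is at most one such finite
    t; S must have at least one positive entry, otherwise c(t) < 1 throughout.
    """
    S = np.asarray(S, dtype=float)
    if not (S > 0).any():
        raise AlnprobError(
            "no uniform-length temperature: S has no positive entry, "
            "so c(t) < 1 for every t"
        )
    smax = float(np.abs(S).max())
    grid = np.geomspace(1e-3 * smax, 1e6 * smax, n_scan)
    vals = np.full(n_scan, np.nan)
    for i, t in enumerate(grid):
        try:
            vals[i] = _homog_c(S, t) - 1.0
        except (SingularMatrixError, FloatingPointError, np.linalg.LinAlgError):
            continue
    for i in range(n_scan - 1):
        lo, hi = vals[i], vals[i + 1]
        if np.isnan(lo) or np.isnan(hi) or np.sign(lo) == np.sign(hi):
            continue
        root = brentq(
            lambda t: _homog_c(S, t) - 1.0,
            grid[i], grid[i + 1], xtol=1e-300, rtol=max(rtol, 1e-15),
        )
        try:
            solve_homogeneous(S, root)
        except HomogeneityError:
            continue
        return float(root)
    raise AlnprobError(
        "no uniform-length temperature: c(t) = 1 has no root with "
        "non-negative letter probabilities in the scan range"
    )


# ---------------------------------------------------------------------------
# realizations and their limits


def realize_phmm(
    primed: PrimedParams,
    phi: LetterProbs,
    psi: LetterProbs,
    omega_D: float,
    omega_I: float,
    topology: Topology = "A",
) -> PhmmParams:
    """Pick one concrete PHMM out of the family sharing ``primed``.

    For the affine topologies: beta = b' omega, alpha = a' omega/(1 - b' omega),
    gamma = c' omega_D omega_I.  Raises :class:`InfeasibleError` when the
    chosen omegas violate gamma + alpha_D + alpha_I < 1 (or b' omega >= 1).
    """
    for name, w in (("omega_D", omega_D), ("omega_I", omega_I)):
        if not 0 < w < 1:
            raise AlnprobError(f"{name}={w} must lie in (0, 1)")
    pi = PairProbs(primed.alphabet, _pi_from_primed(primed, phi, psi))
    gamma = primed.c_pr * omega_D * omega_I
    if topology == "gapless":
        if gamma >= 1:
            raise InfeasibleError(
                f"gamma = c' * omega_D * omega_I = {gamma} >= 1; "
                "decrease the omegas"
            )
        return PhmmParams("gapless", phi, psi, pi, omega_D, omega_I, gamma)
    if topology == "linear":
        alpha_D = primed.a_D_pr * omega_D
        alpha_I = primed.a_I_pr * omega_I
        total = gamma + alpha_D + alpha_I
        if total >= 1:
            raise InfeasibleError(
                f"gamma + alpha_D + alpha_I = {total} >= 1 at "
                f"omega_D={omega_D}, omega_I={omega_I}"
            )
        return PhmmParams(
            "linear", phi, psi, pi, omega_D, omega_I, gamma,
            alpha_D=alpha_D, alpha_I=alpha_I,
        )
    bD = primed.b_D_pr * omega_D
    bI = primed.b_I_pr * omega_I
    if bD >= 1 or bI >= 1:
        raise InfeasibleError(
            f"b' * omega >= 1 (beta_D={bD}, beta_I={bI}): gap extensions "
            "cannot form a probability"
        )
    alpha_D = primed.a_D_pr * omega_D / (1.0 - bD)
    alpha_I = primed.a_I_pr * omega_I / (1.0 - bI)
    total = gamma + alpha_D + alpha_I
    if total >= 1:
        raise InfeasibleError(
            f"gamma + alpha_D + alpha_I = {total} >= 1 at "
            f"omega_D={omega_D}, omega_I={omega_I}"
        )
    return PhmmParams(
        topology, phi, psi, pi, omega_D, omega_I, gamma,
        alpha_D=alpha_D, beta_D=bD, alpha_I=alpha_I, beta_I=bI,
    )


def classify_balance(
    primed: PrimedParams,
    topology: Topology = "A",
    tolerance: float = BALANCE_TOL,
) -> BalanceReport:
    """Is the model family biased toward longer or shorter alignments?

    The criterion value is C' = c' + a'_D/(1-b'_D) + a'_I/(1-b'_I) for affine
    topologies, c' + a'_D + a'_I for linear gaps, and plain c' for gapless
    models.  Balanced means the value equals 1 (no length bias); below 1 the
    family is biased toward shorter alignments, above 1 toward longer ones.
    """
    if topology == "gapless":
        crit = primed.c_pr
    elif topology == "linear":
        crit = primed.c_pr + primed.a_D_pr + primed.a_I_pr
    else:
        C = primed.C_pr
        if C is None:
            raise AlnprobError(
                "C' is undefined: a gap-extension b' >= 1 (b >= 0)"
            )
        crit = C
    if abs(crit - 1.0) <= tolerance:
        cls = "balanced"
    elif crit < 1.0:
        cls = "shorter_bias"
    else:
        cls = "longer_bias"
    return BalanceReport(float(crit), cls, tolerance)


def find_balanced_temperatures(
    S: np.ndarray,
    a: float,
    b: float,
    t_lo: float | None = None,
    t_hi: float | None = None,
    n_scan: int = 1024,
) -> list[float]:
    """All temperatures at which C'(t) = 1 for a symmetric-gap affine scheme.

    Letter probabilities are the homogeneous solution at each t.  Roots of
    C'(t) - 1 are bracketed on a log-spaced scan and refined by bisection;
    a scheme has 0, 1 (tangency) or 2 balanced temperatures.  Grid points
    where the homogeneous solve fails are skipped with a logged warning.
    """
    S = np.asarray(S, dtype=float)
    if b >= 0:
        raise AlnprobError("gap extension score b must be negative (b' < 1)")
    smax = float(np.abs(S).max())
    lo = 1e-3 * smax if t_lo is None else t_lo
    hi = 1e5 * smax if t_hi is None else t_hi
    grid = np.geomspace(lo, hi, n_scan)

    def crit(t: float) -> float:
        cp = _homog_c(S, t)
        ap, bp = math.exp(a / t), math.exp(b / t)
        return cp + 2.0 * ap / (1.0 - bp) - 1.0

    vals = np.full(n_scan, np.nan)
    n_failed = 0
    for i, t in enumerate(grid):
        try:
            vals[i] = crit(t)
        except (SingularMatrixError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.debug("homogeneous solve failed at t=%g: %s", t, exc)
    if n_failed:
        logger.warning(
            "homogeneous solve failed at %d of %d scan temperatures "
            "(points skipped)", n_failed, n_scan,
        )
    roots: list[float] = []
    for i in range(n_scan - 1):
        vlo, vhi = vals[i], vals[i + 1]
        if np.isnan(vlo) or np.isnan(vhi) or np.sign(vlo) == np.sign(vhi):
            continue
        r = float(brentq(crit, grid[i], grid[i + 1], rtol=1e-15))
        try:
            solve_homogeneous(S, r)
        except HomogeneityError:
            continue
        if not roots or abs(r - roots[-1]) > 1e-9 * max(1.0, abs(r)):
            roots.append(r)
    return roots


def max_omega_symmetric(primed: PrimedParams) -> float:
    """Upper feasibility limit on omega for symmetric gaps.

    Smallest root in (0, 1) of the cubic b'c' w^3 - c' w^2 - (2a'+b') w + 1 = 0
    (the boundary where gamma + alpha_D + alpha_I reaches 1), or 1.0 when no
    root lies in (0, 1), i.e. omega is unconstrained below 1.
    """
    if not primed.symmetric:
        raise AlnprobError("max_omega_symmetric requires symmetric gap scores")
    ap, bp, cp = primed.a_D_pr, primed.b_D_pr, primed.c_pr
    if bp > 1:
        raise AlnprobError("requires b' <= 1 (non-positive gap extension)")
    # substitute w = v/s with s = max(1, sqrt(c')) so that the smallest root
    # (~1/sqrt(c') when c' is huge) stays representable in the companion
    # eigenproblem
    s = max(1.0, math.sqrt(cp))
    coeffs = np.array(
        [bp * (cp / s) / s / s, -(cp / s) / s, -(2.0 * ap + bp) / s, 1.0]
    )
    # degenerate leading terms (e.g. b' underflowed to ~0) only carry the
    # irrelevant huge root; drop them so the companion matrix stays finite
    scale = np.abs(coeffs).max()
    lead = 0
    while lead < 3 and abs(coeffs[lead]) < 1e-14 * scale:
        lead += 1
    if lead == 3:
        return 1.0
    roots = np.roots(coeffs[lead:]) / s
    real = sorted(
        r.real
        for r in roots
        if abs(r.imag) <= 1e-10 * max(1.0, abs(r.real)) and 0 < r.real < 1
    )
    return float(real[0]) if real else 1.0


def limit_params_at_omega(
    primed: PrimedParams, omega: float
) -> tuple[float, float, float]:
    """(gamma, alpha, beta) of the symmetric realization at a given omega:
    beta = b' w, alpha = a' w / (1 - b' w), gamma = c' w^2."""
    if not primed.symmetric:
        raise AlnprobError("limit_params_at_omega requires symmetric gaps")
    if not 0 <= omega <= 1:
        raise AlnprobError("omega must lie in [0, 1]")
    ap, bp, cp = primed.a_D_pr, primed.b_D_pr, primed.c_pr
    bw = bp * omega
    if bw >= 1:
        raise AlnprobError(f"b' * omega = {bw} >= 1: beta is not a probability")
    beta = bw
    alpha = ap * omega / (1.0 - bw)
    gamma = cp * omega * omega
    return gamma, alpha, beta


def sweep_max_omega(
    S: np.ndarray,
    a: float,
    b: float,
    t_grid: _Seq[float] | None = None,
) -> tuple[float, float, float]:
    """Maximize the omega feasibility limit over temperature.

    For each t on the grid: homogeneous c'(t), a' = exp(a/t), b' = exp(b/t),
    and the cubic root omega_max(t); the best grid point is refined by
    bounded golden-section search (tolerance 1e-6 in t driving omega).
    Returns (t_star, omega_star, c_pr_star).
    """
    S = np.asarray(S, dtype=float)
    if t_grid is None:
        smax = float(np.abs(S).max())
        t_grid = np.geomspace(1e-3 * smax, 1e4 * smax, 600)
    t_grid = np.asarray(t_grid, dtype=float)

    def omega_at(t: float) -> float:
        try:
            phi, psi, cp = solve_homogeneous(S, t)
        except AlnprobError:
            return np.nan
        ap, bp = math.exp(a / t), math.exp(b / t)
        if bp >= 1:
            return np.nan
        with np.errstate(over="ignore"):
            Sp = np.exp(S / t)
        pr = PrimedParams(
            _default_alphabet(S.shape[0]), Sp, cp,
            a_D_pr=ap, b_D_pr=bp, a_I_pr=ap, b_I_pr=bp,
        )
        return max_omega_symmetric(pr)

    ws = np.array([omega_at(t) for t in t_grid])
    if np.isnan(ws).all():
        raise AlnprobError("entire temperature grid is infeasible")
    if len(t_grid) == 1:
        t_star = float(t_grid[0])
        return t_star, float(ws[0]), _homog_c(S, t_star)
    i = int(np.nanargmax(ws))
    lo = t_grid[max(0, i - 1)]
    hi = t_grid[min(len(t_grid) - 1, i + 1)]
    res = minimize_scalar(
        lambda t: -np.nan_to_num(omega_at(t), nan=-1.0),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-6},
    )
    t_star = float(res.x)
    w_star = omega_at(t_star)
    if np.isnan(w_star) or w_star < ws[i]:
        t_star, w_star = float(t_grid[i]), float(ws[i])
    return t_star, float(w_star), float(_homog_c(S, t_star))


def balance_shift(
    scheme: ScoreScheme, phi: LetterProbs, psi: LetterProbs
) -> float:
    """Constant to subtract from every S_xy so that C' becomes exactly 1.

    h = t ln( c' / (1 - a'_D/(1-b'_D) - a'_I/(1-b'_I)) ).  Subtracting h from
    the matrix rescales c' to 1 minus the gap terms, fixing the length bias of
    schemes built from gapless-balanced matrices plus ad hoc gap costs.
    Raises when the gap terms alone reach 1 (no matrix shift can balance).
    """
    primed = primed_params(scheme, phi, psi)
    if primed.b_D_pr >= 1 or primed.b_I_pr >= 1:
        raise AlnprobError("cannot balance by matrix shift: some b' >= 1")
    gap_terms = primed.a_D_pr / (1.0 - primed.b_D_pr) + primed.a_I_pr / (
        1.0 - primed.b_I_pr
    )
    if gap_terms >= 1.0:
        raise AlnprobError(
            "cannot balance by matrix shift: gap terms alone reach "
            f"{gap_terms} >= 1"
        )
    h = scheme.t * math.log(primed.c_pr / (1.0 - gap_terms))
    shifted = ScoreScheme(
        scheme.alphabet, scheme.S - h, t=scheme.t,
        a_D=scheme.a_D, b_D=scheme.b_D, a_I=scheme.a_I, b_I=scheme.b_I,
    )
    check = primed_params(shifted, phi, psi).C_pr
    assert check is not None and abs(check - 1.0) < 1e-9
    return h


# ---------------------------------------------------------------------------
# helpers


def _default_alphabet(k: int) -> Alphabet:
    if k == 4:
        return DNA
    return Alphabet(tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:k]))


def _check_dists(
    scheme: ScoreScheme, phi: LetterProbs, psi: LetterProbs
) -> None:
    if phi.alphabet != scheme.alphabet or psi.alphabet != scheme.alphabet:
        raise AlnprobError("phi/psi alphabet does not match the scheme")


def _pi_from_primed(
    primed: PrimedParams, phi: LetterProbs, psi: LetterProbs
) -> np.ndarray:
    w = phi.p[:, None] * psi.p[None, :] * primed.Sprime
    return w / w.sum()


def _require_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if (arr <= 0).any():
        raise AlnprobError(
            f"parameter {name} contains a zero or negative entry where a "
            "logarithm is required"
        )


def _clamp_probs(p: np.ndarray, name: str, t: float) -> np.ndarray:
    if (p < -_NEG_TOL).any():
        raise HomogeneityError(
            f"S and t={t} are not consistent with homogeneous letter "
            f"probabilities ({name} has negative components)"
        )
    return np.clip(p, 0.0, None)
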