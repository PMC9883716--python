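"""Gumbel calibration of hybrid alignment scores.

Under balanced length probability, hybrid scores (max_ij t ln W'_ij) of
random independent-monomer sequences are expected to follow a Gumbel
distribution with scale parameter lambda = 1/t.  This module simulates
random sequence pairs, fits a Gumbel by maximum likelihood and reports the
product lambda_hat * t, which should sit near 1 at each balanced
temperature.

Simulation defaults (m = n = 100, 1000 replicates) are desk-scale: large
enough for a usable fit standard error, small enough to run in seconds to
minutes.  Sequence lengths are finite, so edge effects are not corrected
for; the check is of the qualitative scale claim, not a theorem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AlnprobError,
    LetterProbs,
    ScoreScheme,
    find_balanced_temperatures,
    primed_params,
    solve_homogeneous,
)
from .dp import Sequence
from .forward import hybrid_score

__all__ = [
    "GumbelFit",
    "SimConfig",
    "CalibrationResult",
    "simulate_pair",
    "fit_gumbel",
    "fit_gumbel_moments",
    "check_lambda",
]


@dataclass
class GumbelFit:
    """Maximum-likelihood Gumbel (location mu, scale 1/lambda) fit."""

    lambda_hat: float
    mu_hat: float
    se_lambda: float
    n: int

    def __post_init__(self) -> None:
        if not self.lambda_hat > 0:
            raise AlnprobError("lambda_hat must be positive")
        if self.n < 2:
            raise AlnprobError("need at least two samples")


@dataclass
class SimConfig:
    """Random-pair simulation settings: independent monomers from Phi/Psi."""

    m: int
    n: int
    Phi: LetterProbs
    Psi: LetterProbs
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise AlnprobError("sequence lengths must be >= 1")
        if self.replicates < 1:
            raise AlnprobError("replicates must be >= 1")


@dataclass
class CalibrationResult:
    """lambda_hat * t should be ~1 at a balanced temperature."""

    t_balanced: float
    fit: GumbelFit
    ratio: float  # lambda_hat * t


def simulate_pair(config: SimConfig, index: int) -> tuple[Sequence, Sequence]:
    """Draw one random pair; deterministic given (config.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    ab = config.Phi.alphabet
    letters = np.array(list(ab.letters))
    r = "".join(rng.choice(letters, size=config.m, p=config.Phi.p))
    q = "".join(rng.choice(letters, size=config.n, p=config.Psi.p))
    return Sequence(f"R{index}", r), Sequence(f"Q{index}", q)


def _gumbel_loglik(x: np.ndarray, mu: float, beta: float) -> float:
    z = (x - mu) / beta
    return float(-len(x) * math.log(beta) - z.sum() - np.exp(-z).sum())


def fit_gumbel(samples, tol: float = 1e-10, max_iter: int = 200) -> GumbelFit:
    """ML fit of a Gumbel (maximum) distribution.

    Newton iteration on the profile likelihood equation for the scale beta,
        g(beta) = beta - mean(x) + sum(x e^{-x/beta}) / sum(e^{-x/beta}) = 0,
    then mu = -beta ln(mean(e^{-x/beta})).  lambda_hat = 1/beta; its standard
    error comes from the observed information matrix at the optimum.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise AlnprobError("fit_gumbel needs at least 10 samples")
    if np.ptp(x) == 0.0:
        raise AlnprobError("degenerate (constant) sample")
    xbar = float(x.mean())
    shift = float(x.max())  # subtract before exponentiating
    beta = float(x.std(ddof=1)) * math.sqrt(6.0) / math.pi  # moments start
    lo, hi = 1e-12 * (shift - x.min() + 1.0), 100.0 * beta

    def g_and_slope(b: float) -> tuple[float, float]:
        e = np.exp(-(x - shift) / b)
        s0 = e.sum()
        s1 = float((x * e).sum())
        s2 = float((x * x * e).sum())
        g = b - xbar + s1 / s0
        slope = 1.0 + (s2 * s0 - s1 * s1) / (s0 * s0 * b * b)
        return g, slope

    for _ in range(max_iter):
        g, slope = g_and_slope(beta)
        step = g / slope
        new = beta - step
        if not lo < new < hi:  # Newton left the bracket: bisect instead
            glo, _ = g_and_slope(lo)
            new = 0.5 * (lo + hi) if glo * g < 0 else 0.5 * (beta + hi)
        if abs(new - beta) <= tol * beta:
            beta = new
            break
        beta = new
    mu = shift - beta * math.log(float(np.exp(-(x - shift) / beta).mean()))
    # observed information by central differences of the log-likelihood
    h_m = 1e-5 * max(1.0, abs(mu))
    h_b = 1e-5 * beta
    f = _gumbel_loglik
    d2m = (f(x, mu + h_m, beta) - 2 * f(x, mu, beta) + f(x, mu - h_m, beta)) / h_m**2
    d2b = (f(x, mu, beta + h_b) - 2 * f(x, mu, beta) + f(x, mu, beta - h_b)) / h_b**2
    dmb = (
        f(x, mu + h_m, beta + h_b)
        - f(x, mu + h_m, beta - h_b)
        - f(x, mu - h_m, beta + h_b)
        + f(x, mu - h_m, beta - h_b)
    ) / (4 * h_m * h_b)
    info = -np.array([[d2m, dmb], [dmb, d2b]])
    var_beta = float(np.linalg.inv(info)[1, 1])
    se_beta = math.sqrt(max(var_beta, 0.0))
    lam = 1.0 / beta
    return GumbelFit(lam, mu, se_beta / beta**2, n)


def fit_gumbel_moments(samples) -> GumbelFit:
    """Method-of-moments cross-check: beta = s sqrt(6)/pi, mu = xbar - g*beta."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0.0:
        raise AlnprobError("degenerate sample")
    beta = float(x.std(ddof=1)) * math.sqrt(6.0) / math.pi
    mu = float(x.mean()) - np.euler_gamma * beta
    se = beta / math.sqrt(len(x))  # rough
    return GumbelFit(1.0 / beta, mu, se / beta**2, len(x))


def check_lambda(
    S: np.ndarray,
    a: float,
    b: float,
    config: SimConfig,
) -> list[CalibrationResult]:
    """Check lambda = 1/t at every balanced temperature of (S, a, b).

    For each balanced t: homogeneous letter probabilities, primed parameters,
    hybrid scores over ``config.replicates`` simulated pairs, ML Gumbel fit.
    Raises if the scheme has no balanced temperature (consider balance_shift).
    """
    ts = find_balanced_temperatures(S, a, b)
    if not ts:
        raise AlnprobError(
            "no balanced temperature for this scheme; "
            "consider balance_shift to fix the matrix first"
        )
    out = []
    for t in ts:
        phi, psi, _ = solve_homogeneous(S, t)
        scheme = ScoreScheme.symmetric(phi.alphabet, S, a, b, t=t)
        primed = primed_params(scheme, phi, psi)
        scores = np.empty(config.replicates)
        for k in range(config.replicates):
            R, Q = simulate_pair(config, k)
            scores[k] = hybrid_score(R, Q, primed, t)
        fit = fit_gumbel(scores)
        out.append(CalibrationResult(t, fit, fit.lambda_hat * t))
    return out
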