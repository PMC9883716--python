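import numpy as np
import pytest

import alnprob as ap


@pytest.fixture
def uniform():
    return ap.LetterProbs.uniform(ap.DNA)


@pytest.fixture
def skewed():
    return ap.LetterProbs(ap.DNA, [0.3, 0.2, 0.2, 0.3])


def random_sequences(rng, m, n, alphabet=ap.DNA):
    letters = list(alphabet.letters)
    R = ap.Sequence("r", "".join(rng.choice(letters, size=m)))
    Q = ap.Sequence("q", "".join(rng.choice(letters, size=n)))
    return R, Q


def random_primed(rng, smin=0.1, smax=3.0, gmax=0.9):
    """A random primed parameter set with positive factors."""
    Sp = rng.uniform(smin, smax, (4, 4))
    aD, bD, aI, bI = rng.uniform(0.05, gmax, 4)
    return ap.PrimedParams(
        ap.DNA, Sp, float(Sp.mean()),
        a_D_pr=aD, b_D_pr=bD, a_I_pr=aI, b_I_pr=bI,
    )


def random_phmm(rng, topology="A"):
    """A random valid PHMM with all entries strictly inside (0, 1)."""
    phi = ap.LetterProbs(ap.DNA, _dirichlet(rng))
    psi = ap.LetterProbs(ap.DNA, _dirichlet(rng))
    w = rng.dirichlet(np.ones(16)) * 0.98 + 0.02 / 16
    pi = ap.PairProbs(ap.DNA, (w / w.sum()).reshape(4, 4))
    omega_D, omega_I = rng.uniform(0.1, 0.9, 2)
    tr = rng.dirichlet(np.ones(4)) * 0.9 + 0.01
    gamma, alpha_D, alpha_I = tr[0], tr[1], tr[2]
    if topology == "gapless":
        return ap.PhmmParams(
            "gapless", phi, psi, pi, omega_D, omega_I, gamma
        )
    if topology == "linear":
        return ap.PhmmParams(
            "linear", phi, psi, pi, omega_D, omega_I, gamma,
            alpha_D=alpha_D, alpha_I=alpha_I,
        )
    beta_D, beta_I = rng.uniform(0.05, 0.9, 2)
    return ap.PhmmParams(
        topology, phi, psi, pi, omega_D, omega_I, gamma,
        alpha_D=alpha_D, beta_D=beta_D, alpha_I=alpha_I, beta_I=beta_I,
    )


def _dirichlet(rng):
    p = rng.dirichlet(np.ones(4)) * 0.9 + 0.025
    return p / p.sum()
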