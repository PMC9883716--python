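"""Score <-> probability conversions, special temperatures, limits."""

import math

import numpy as np
import pytest

import alnprob as ap
from alnprob.core import _homog_c

from conftest import random_phmm

SIMPLE_T_STAR = 1.0 / math.log(3.0)  # closed form for +1/-1, uniform letters


# ---------------------------------------------------------------------------
# primed parameters and pair probabilities


def test_primed_c_is_one_for_zero_scores(uniform):
    scheme = ap.ScoreScheme(ap.DNA, np.zeros((4, 4)), t=2.3)
    assert ap.primed_params(scheme, uniform, uniform).c_pr == pytest.approx(
        1.0, abs=1e-15
    )


@pytest.mark.parametrize(
    "S, phi_p, t, expected",
    [
        (ap.SIMPLE, (0.25, 0.25, 0.25, 0.25), SIMPLE_T_STAR, 1.0),
        (ap.HOXD70, (0.288, 0.212, 0.212, 0.288), 30.0, 6.06),
    ],
)
def test_primed_c_table_values(S, phi_p, t, expected):
    phi = ap.LetterProbs(ap.DNA, np.array(phi_p) / sum(phi_p))
    scheme = ap.ScoreScheme(ap.DNA, S, t=t)
    c = ap.primed_params(scheme, phi, phi).c_pr
    assert c == pytest.approx(expected, rel=5e-3)


def test_pair_probs_simple_at_special_temperature(uniform):
    scheme = ap.ScoreScheme(ap.DNA, ap.SIMPLE, t=SIMPLE_T_STAR)
    pi, c = ap.pair_probs_from_scores(scheme, uniform, uniform)
    assert c == pytest.approx(1.0, abs=1e-12)
    assert pi.pi[0, 0] == pytest.approx(0.1875, abs=5e-4)  # printed 0.188
    assert pi.pi[0, 1] == pytest.approx(0.0208, abs=5e-5)


def test_pair_probs_zero_scores_gives_independence(uniform, skewed):
    scheme = ap.ScoreScheme(ap.DNA, np.zeros((4, 4)))
    pi, c = ap.pair_probs_from_scores(scheme, uniform, skewed)
    assert c == pytest.approx(1.0, abs=1e-15)
    np.testing.assert_allclose(
        pi.pi, uniform.p[:, None] * skewed.p[None, :], rtol=1e-12
    )


def test_pair_probs_hoxd70_special_temperature():
    phi = ap.LetterProbs(ap.DNA, [0.266, 0.234, 0.234, 0.266])
    scheme = ap.ScoreScheme(ap.DNA, ap.HOXD70, t=96.1735)
    pi, _ = ap.pair_probs_from_scores(scheme, phi, phi)
    assert pi.pi[0, 0] == pytest.approx(0.182, abs=5e-4)


# ---------------------------------------------------------------------------
# scores from PHMM parameters


def test_scores_zero_when_pi_factorizes(uniform, skewed):
    pi = ap.PairProbs(ap.DNA, uniform.p[:, None] * skewed.p[None, :])
    params = ap.PhmmParams(
        "gapless", uniform, skewed, pi,
        omega_D=0.6, omega_I=0.5, gamma=0.3,
    )
    scheme = ap.scores_from_pair_probs(params, t=1.0)
    np.testing.assert_allclose(scheme.S, 0.0, atol=1e-12)


def test_scores_recover_simple_matrix_from_table_row(uniform):
    pi_vals = np.where(np.eye(4, dtype=bool), 0.1875, 1.0 / 48.0)
    params = ap.PhmmParams(
        "gapless", uniform, uniform, ap.PairProbs(ap.DNA, pi_vals),
        omega_D=0.5, omega_I=0.5, gamma=0.25,  # gamma/(wD wI) = 1
    )
    scheme = ap.scores_from_pair_probs(params, t=SIMPLE_T_STAR)
    np.testing.assert_allclose(scheme.S, ap.SIMPLE, atol=1e-9)


@pytest.mark.parametrize("topology", ["gapless", "linear", "A"])
def test_round_trip_random_phmm(topology):
    """scores -> pair probabilities reproduces pi for random models."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        params = random_phmm(rng, topology)
        t = float(rng.uniform(0.2, 5.0))
        scheme = ap.scores_from_pair_probs(params, t)
        pi, c = ap.pair_probs_from_scores(scheme, params.phi, params.psi)
        np.testing.assert_allclose(pi.pi, params.pi.pi, rtol=1e-9)
        assert c == pytest.approx(
            params.gamma / (params.omega_D * params.omega_I), rel=1e-9
        )


def test_scores_error_on_zero_probability(uniform):
    pi_vals = uniform.p[:, None] * uniform.p[None, :]
    pi_vals = pi_vals.copy()
    pi_vals[0, 0] = 0.0
    pi_vals /= pi_vals.sum()
    params = ap.PhmmParams(
        "gapless", uniform, uniform, ap.PairProbs(ap.DNA, pi_vals),
        omega_D=0.5, omega_I=0.5, gamma=0.2,
    )
    with pytest.raises(ap.AlnprobError, match="pi"):
        ap.scores_from_pair_probs(params, 1.0)


# ---------------------------------------------------------------------------
# homogeneous letter probabilities


@pytest.mark.parametrize(
    "S, t, c_expected, tol",
    [
        (ap.SIMPLE, 10.0, 0.955, 5e-4),
        (ap.SIMPLE, 0.3, 7.03, 5e-3),
        (ap.HOXD70, 96.1735, 1.0, 1e-4),
    ],
)
def test_solve_homogeneous_table_values(S, t, c_expected, tol):
    phi, psi, c = ap.solve_homogeneous(S, t)
    assert c == pytest.approx(c_expected, abs=tol)
    if S is ap.SIMPLE:
        np.testing.assert_allclose(phi.p, 0.25, atol=1e-12)
        np.testing.assert_allclose(psi.p, 0.25, atol=1e-12)
    else:
        assert phi.p[0] == pytest.approx(0.266, abs=5e-4)


def test_homogeneous_marginals_match_pair_probs():
    """phi_x = sum_y pi_xy and psi_y = sum_x pi_xy for the implied pi."""
    for S, t in [(ap.HOXD70, 30.0), (ap.HOXD70, 96.1735), (ap.SIMPLE, 0.7)]:
        phi, psi, c = ap.solve_homogeneous(S, t)
        pi, _ = ap.pair_probs_from_scores(
            ap.ScoreScheme(ap.DNA, S, t=t), phi, psi
        )
        np.testing.assert_allclose(pi.pi.sum(axis=1), phi.p, atol=1e-9)
        np.testing.assert_allclose(pi.pi.sum(axis=0), psi.p, atol=1e-9)


def test_homogeneous_negative_components_rejected():
    """A matrix whose implied letter probabilities go negative errors out."""
    ab = ap.Alphabet(("A", "B"))
    S = np.array([[2.0, 1.0], [1.0, -3.0]])
    with pytest.raises(
        ap.HomogeneityError, match="not consistent with homogeneous"
    ):
        ap.solve_homogeneous(S, 1.0, ab)


def test_homogeneous_singular_matrix_rejected():
    with pytest.raises(ap.SingularMatrixError):
        ap.solve_homogeneous(np.zeros((4, 4)), 1.0)


# ---------------------------------------------------------------------------
# uniform-length temperature


def test_uniform_length_temperature_closed_form():
    t = ap.find_uniform_length_temperature(ap.SIMPLE)
    assert t == pytest.approx(SIMPLE_T_STAR, rel=1e-9)
    assert t == pytest.approx(0.910239, abs=5e-7)


def test_uniform_length_temperature_hoxd70():
    t = ap.find_uniform_length_temperature(ap.HOXD70)
    assert t == pytest.approx(96.1735, abs=5e-5)


def test_uniform_length_temperature_needs_positive_entry():
    with pytest.raises(ap.AlnprobError, match="no positive entry"):
        ap.find_uniform_length_temperature(-np.ones((4, 4)))


def test_c_approaches_one_from_below_at_high_t():
    for S in (ap.SIMPLE, ap.HOXD70):
        c = _homog_c(S, 1e6 * float(np.abs(S).max()))
        assert 1.0 - 1e-3 < c < 1.0


def test_mismatch_score_monotonicity():
    """Stronger mismatch scores lower c(t) at every temperature."""
    mats = [
        np.where(np.eye(4, dtype=bool), 1.0, mm) for mm in (-1.0, -2.0, -3.0)
    ]
    for t in np.geomspace(0.3, 30, 12):
        cs = [_homog_c(S, t) for S in mats]
        assert cs[0] > cs[1] > cs[2]


# ---------------------------------------------------------------------------
# realizations


def test_realize_trivial_gapless_like():
    primed = ap.PrimedParams(ap.DNA, np.ones((4, 4)), 1.0)
    phi = ap.LetterProbs.uniform(ap.DNA)
    params = ap.realize_phmm(primed, phi, phi, 0.5, 0.5, topology="A")
    assert params.gamma == pytest.approx(0.25)
    assert params.alpha_D == 0.0 and params.beta_D == 0.0


def test_realize_round_trips_scheme(uniform):
    t = ap.find_uniform_length_temperature(ap.SIMPLE)
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -3, -1, t=t)
    primed = ap.primed_params(scheme, uniform, uniform)
    params = ap.realize_phmm(primed, uniform, uniform, 0.9, 0.9)
    back = ap.scores_from_pair_probs(params, t)
    np.testing.assert_allclose(back.S, scheme.S, atol=1e-9)
    for g in ("a_D", "b_D", "a_I", "b_I"):
        assert getattr(back, g) == pytest.approx(getattr(scheme, g), abs=1e-9)


def test_realize_infeasible_omega_raises(uniform):
    t = ap.find_uniform_length_temperature(ap.SIMPLE)
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -3, -1, t=t)
    primed = ap.primed_params(scheme, uniform, uniform)
    w_max = ap.max_omega_symmetric(primed)
    assert w_max < 1.0
    with pytest.raises(ap.InfeasibleError, match="gamma \\+ alpha"):
        ap.realize_phmm(
            primed, uniform, uniform, w_max * 1.02, w_max * 1.02
        )


def test_reparameterization_invariance(uniform):
    """Different omega choices give PHMMs mapping to identical scores."""
    rng = np.random.default_rng(7)
    t = 1.3
    scheme = ap.ScoreScheme.symmetric(
        ap.DNA, rng.uniform(-3, 1.5, (4, 4)), -4, -2, t=t
    )
    primed = ap.primed_params(scheme, uniform, uniform)
    w_max = ap.max_omega_symmetric(primed)
    schemes = []
    for wD, wI in [(0.1, 0.2), (0.4, 0.1), (0.8 * w_max, 0.9 * w_max)]:
        params = ap.realize_phmm(primed, uniform, uniform, wD, wI)
        schemes.append(ap.scores_from_pair_probs(params, t))
    for other in schemes[1:]:
        np.testing.assert_allclose(schemes[0].S, other.S, atol=1e-9)
        assert schemes[0].a_D == pytest.approx(other.a_D, abs=1e-9)
        assert schemes[0].b_I == pytest.approx(other.b_I, abs=1e-9)


# ---------------------------------------------------------------------------
# balance


def test_classify_balance_exact_arithmetic():
    primed = ap.PrimedParams(
        ap.DNA, np.ones((4, 4)), 0.5,
        a_D_pr=0.25, b_D_pr=0.0, a_I_pr=0.25, b_I_pr=0.0,
    )
    rep = ap.classify_balance(primed)
    assert rep.C_pr == 1.0
    assert rep.classification == "balanced"


def test_simple_3_1_never_balanced():
    assert ap.find_balanced_temperatures(ap.SIMPLE, -3, -1) == []


def test_simple_6_1_balanced_at_two_temperatures(uniform):
    roots = ap.find_balanced_temperatures(ap.SIMPLE, -6, -1)
    assert len(roots) == 2
    for t in roots:
        scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -6, -1, t=t)
        primed = ap.primed_params(scheme, uniform, uniform)
        assert ap.classify_balance(
            primed, tolerance=1e-8
        ).classification == "balanced"


def test_hoxd70_430_30_never_balanced():
    assert ap.find_balanced_temperatures(ap.HOXD70, -430, -30) == []


def test_balance_classification_signs(uniform):
    # weak gaps at the uniform-length t: C' > 1, longer bias
    t = ap.find_uniform_length_temperature(ap.SIMPLE)
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -3, -1, t=t)
    primed = ap.primed_params(scheme, uniform, uniform)
    assert ap.classify_balance(primed).classification == "longer_bias"
    # between the two Simple:6:1 roots: C' < 1, shorter bias
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -6, -1, t=1.2)
    primed = ap.primed_params(scheme, uniform, uniform)
    assert ap.classify_balance(primed).classification == "shorter_bias"


# ---------------------------------------------------------------------------
# omega limits


def test_cubic_limit_at_unit_primes():
    primed = ap.PrimedParams(
        ap.DNA, np.ones((4, 4)), 1.0,
        a_D_pr=1.0, b_D_pr=1.0, a_I_pr=1.0, b_I_pr=1.0,
    )
    w = ap.max_omega_symmetric(primed)
    assert w == pytest.approx(0.311, abs=5e-4)
    gamma, alpha, beta = ap.limit_params_at_omega(primed, w)
    assert alpha == pytest.approx(0.452, abs=5e-4)
    assert beta == pytest.approx(0.311, abs=5e-4)
    assert alpha == pytest.approx(w / (1 - w), rel=1e-12)


def test_cubic_degenerates_to_gapless():
    primed = ap.PrimedParams(ap.DNA, np.ones((4, 4)), 4.0)
    assert ap.max_omega_symmetric(primed) == pytest.approx(0.5, rel=1e-9)


def test_omega_unconstrained_inside_simple_6_1_balanced_range(uniform):
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -6, -1, t=1.2)
    _, _, c = ap.solve_homogeneous(ap.SIMPLE, 1.2)
    primed = ap.primed_params(scheme, uniform, uniform)
    primed = ap.PrimedParams(
        ap.DNA, primed.Sprime, c,
        a_D_pr=primed.a_D_pr, b_D_pr=primed.b_D_pr,
        a_I_pr=primed.a_I_pr, b_I_pr=primed.b_I_pr,
    )
    assert ap.max_omega_symmetric(primed) == 1.0


def test_limit_params_at_zero_omega():
    rng = np.random.default_rng(3)
    ap_, bp, cp = rng.uniform(0.1, 0.9, 3)
    primed = ap.PrimedParams(
        ap.DNA, np.ones((4, 4)), cp,
        a_D_pr=ap_, b_D_pr=bp, a_I_pr=ap_, b_I_pr=bp,
    )
    assert ap.limit_params_at_omega(primed, 0.0) == (0.0, 0.0, 0.0)


def test_limit_root_saturates_continuation_probability():
    """At the cubic root, gamma + alpha_D + alpha_I = 1 to 1e-9."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        ap_, bp = rng.uniform(0.05, 0.95, 2)
        cp = rng.uniform(0.5, 5.0)
        primed = ap.PrimedParams(
            ap.DNA, np.ones((4, 4)), cp,
            a_D_pr=ap_, b_D_pr=bp, a_I_pr=ap_, b_I_pr=bp,
        )
        w = ap.max_omega_symmetric(primed)
        if w == 1.0:
            continue
        gamma, alpha, _ = ap.limit_params_at_omega(primed, w)
        assert gamma + 2 * alpha == pytest.approx(1.0, abs=1e-9)


def test_sweep_degenerate_gapless_grid():
    t = 2.0
    _, _, c = ap.solve_homogeneous(ap.HOXD70, t)
    t_star, w_star, c_star = ap.sweep_max_omega(
        ap.HOXD70, -1e9, -1e9, t_grid=[t]
    )
    assert w_star == pytest.approx(min(1.0, 1.0 / math.sqrt(c)), rel=1e-6)


def test_sweep_simple_3_1():
    t_star, w_star, c_star = ap.sweep_max_omega(ap.SIMPLE, -3, -1)
    assert w_star == pytest.approx(0.948, abs=5e-4)
    assert c_star == pytest.approx(0.980, abs=2e-3)


# ---------------------------------------------------------------------------
# balance shift


def test_balance_shift_zero_when_already_balanced(uniform):
    ts = ap.find_balanced_temperatures(ap.SIMPLE, -6, -1)
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -6, -1, t=ts[0])
    h = ap.balance_shift(scheme, uniform, uniform)
    assert h == pytest.approx(0.0, abs=1e-9)


def test_balance_shift_direct_substitution(uniform):
    # c' = 2 via S = ln 2 everywhere at t = 1; gap terms ~ 0.5
    S = np.full((4, 4), math.log(2.0))
    scheme = ap.ScoreScheme.symmetric(
        ap.DNA, S, a=math.log(0.25), b=-40.0, t=1.0
    )
    h = ap.balance_shift(scheme, uniform, uniform)
    assert h == pytest.approx(math.log(4.0), abs=1e-9)


def test_balance_shift_fixes_simple_3_1(uniform):
    t = ap.find_uniform_length_temperature(ap.SIMPLE)
    scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -3, -1, t=t)
    h = ap.balance_shift(scheme, uniform, uniform)
    shifted = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE - h, -3, -1, t=t)
    rep = ap.classify_balance(ap.primed_params(shifted, uniform, uniform))
    assert rep.classification == "balanced"


def test_balance_shift_impossible_when_gap_terms_saturate(uniform):
    scheme = ap.ScoreScheme.symmetric(
        ap.DNA, np.zeros((4, 4)), a=-0.01, b=-0.01, t=1.0
    )
    with pytest.raises(ap.AlnprobError, match="cannot balance"):
        ap.balance_shift(scheme, uniform, uniform)
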