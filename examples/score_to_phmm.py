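"""Convert a scoring scheme into probability models, and back.

One scoring scheme corresponds to many PHMMs: the primed invariants
S' = exp(S/t), a' = exp(a/t), b' = exp(b/t) are shared, while the flank
probabilities omega_D, omega_I can be chosen freely (within feasibility).
Every choice maps back to exactly the same scores.
"""

import numpy as np

import alnprob as ap

t = 30.0
scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.HOXD70, a=-430, b=-30, t=t)
phi, psi, c = ap.solve_homogeneous(ap.HOXD70, t)
print(f"homogeneous letter probabilities at t={t}: phi = {phi.p.round(4)}")
print(f"c' = gamma/(omega_D omega_I) = {c:.4g}")

primed = ap.primed_params(scheme, phi, psi)
for omega in (0.1, 0.3):
    params = ap.realize_phmm(primed, phi, psi, omega, omega, topology="A")
    back = ap.scores_from_pair_probs(params, t)
    err = np.abs(back.S - scheme.S).max()
    print(
        f"omega={omega}: gamma={params.gamma:.4g} alpha_D={params.alpha_D:.4g}"
        f" beta_D={params.beta_D:.4g} -> scores recovered to {err:.2e}"
    )

print(
    "\nTwo different-looking PHMMs above map to the identical HoxD70 scheme:"
    "\nthe scores cannot distinguish them, so alignment results are the same."
)
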