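"""Feasibility limits on PHMM parameters for a given scoring scheme.

The freedom to raise omega (the flank-emission probability) ends where
gamma + alpha_D + alpha_I would reach 1; for symmetric gaps that boundary
is the smallest (0,1)-root of the cubic b'c'w^3 - c'w^2 - (2a'+b')w + 1.
"""

import numpy as np

import alnprob as ap

# the universal large-t limit: a' = b' = c' = 1
unit = ap.PrimedParams(
    ap.DNA, np.ones((4, 4)), 1.0,
    a_D_pr=1.0, b_D_pr=1.0, a_I_pr=1.0, b_I_pr=1.0,
)
w = ap.max_omega_symmetric(unit)
gamma, alpha, beta = ap.limit_params_at_omega(unit, w)
print(f"large-t limit: omega_max={w:.3f} alpha={alpha:.3f} beta={beta:.3f}")

for name, S, a, b in [
    ("Simple:3:1", ap.SIMPLE, -3, -1),
    ("HoxD70:430:30", ap.HOXD70, -430, -30),
    ("Simple:6:1", ap.SIMPLE, -6, -1),
]:
    t_star, w_star, c_star = ap.sweep_max_omega(S, a, b)
    print(
        f"{name}: max over t of omega_max = {w_star:.3f} "
        f"(at t={t_star:.4g}, c'={c_star:.4g})"
    )

print(
    "\nomega_max < 1 means the scheme can never be realized with flanks"
    "\nemitting almost surely; Simple:6:1 reaches 1.0 inside its balanced"
    "\ntemperature range, where omega is unconstrained."
)
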