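"""Find the special temperatures of a substitution matrix.

The uniform-length temperature is the unique finite t at which c(t) = 1
under homogeneous letter probabilities: no prior bias over alignment
lengths in the gapless model.  With affine gaps the analogous "balanced"
condition C' = c' + a'_D/(1-b'_D) + a'_I/(1-b'_I) = 1 can hold at zero,
one or two temperatures.
"""

import alnprob as ap

for name, S in [("HoxD70", ap.HOXD70), ("Simple", ap.SIMPLE)]:
    t = ap.find_uniform_length_temperature(S)
    print(f"{name}: uniform-length temperature t* = {t:.6g}")

print()
for name, S, a, b in [
    ("Simple:6:1", ap.SIMPLE, -6, -1),
    ("Simple:3:1", ap.SIMPLE, -3, -1),
    ("HoxD70:430:30", ap.HOXD70, -430, -30),
]:
    roots = ap.find_balanced_temperatures(S, a, b)
    shown = ", ".join(f"{t:.4f}" for t in roots) or "none"
    print(f"{name}: balanced temperatures: {shown}")

print(
    "\nOnly strong gap+mismatch costs (Simple:6:1) admit balance, and then"
    "\nat two temperatures - balance does not pin down t for gapped schemes."
    "\nAn unbalanced scheme can be fixed by subtracting a constant:"
)
phi = ap.LetterProbs.uniform(ap.DNA)
t = ap.find_uniform_length_temperature(ap.SIMPLE)
scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.SIMPLE, -3, -1, t=t)
h = ap.balance_shift(scheme, phi, phi)
print(f"Simple:3:1 at t*={t:.4f}: subtract h = {h:.6f} from every S_xy")
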