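# alnprob

**alnprob** implements the many-to-one correspondence between pairwise
alignment scoring schemes and pair hidden Markov models (PHMMs), for
sequence analysts who want probability semantics — alignment reliability,
partition functions, significance — out of ordinary score matrices and
affine gap costs.

## The correspondence

A scoring scheme assigns `S_xy` to aligning letters `x:y` and `a + b(k-1)`
to a length-`k` gap. Exponentiating at a temperature `t`,

```
S'_xy = exp(S_xy / t)     a' = exp(a / t)     b' = exp(b / t)
```

defines invariants shared by an entire family of PHMMs: writing `φ, ψ` for
the letter distributions, `π` for the aligned-pair distribution, `ω_D, ω_I`
for the flank-emission probabilities and `γ, α, β` for the core transition
probabilities,

```
S_xy = t ln( π_xy / (φ_x ψ_y) · γ/(ω_D ω_I) )
a_D  = t ln( α_D (1 − β_D) / ω_D )        b_D = t ln( β_D / ω_D )
```

so `c' = γ/(ω_D ω_I) = Σ_xy φ_x ψ_y S'_xy`, and `ω_D, ω_I` may be varied
freely (within feasibility) with no effect on the scores. Special model
classes fall out of this algebra:

* **uniform length probability** — the unique finite `t` with `c(t) = 1`
  under homogeneous letter probabilities (`φ_x = Σ_y π_xy`);
* **balanced length probability** — the gapped analogue
  `C' = c' + a'_D/(1−b'_D) + a'_I/(1−b'_I) = 1`, which holds at zero, one
  or two temperatures;
* **feasibility limits** — the largest admissible `ω` solves the cubic
  `b'c'ω³ − c'ω² − (2a'+b')ω + 1 = 0` (the boundary `γ + α_D + α_I = 1`).

On top of the conversions the package provides maximum-score (Viterbi)
local and global alignment, the Forward sum over all paths for two affine
topologies, forward–backward posterior column reliabilities, read-mapping
probabilities, hybrid scores (`max_ij t ln W'_ij`), and a Gumbel
calibration of hybrid-score statistics (`λ = 1/t` under balance).

## Worked example

```python
import alnprob as ap

# the special temperature of the HoxD70 genome-alignment matrix
t = ap.find_uniform_length_temperature(ap.HOXD70)
phi, psi, c = ap.solve_homogeneous(ap.HOXD70, t)
print(f"t* = {t:.6g}, c = {c:.4g}, phi_A = {phi.p[0]:.3f}")

# one concrete PHMM realization of HoxD70:430:30 at that temperature
scheme = ap.ScoreScheme.symmetric(ap.DNA, ap.HOXD70, -430, -30, t=t)
primed = ap.primed_params(scheme, phi, psi)
params = ap.realize_phmm(primed, phi, psi, 0.3, 0.3, topology="A")
print(f"gamma = {params.gamma:.4g}, beta_D = {params.beta_D:.4g}")
```

prints

```
t* = 96.1735, c = 1, phi_A = 0.266
gamma = 0.09, beta_D = 0.2196
```

`t* = 96.1735` is the temperature at which HoxD70's implied pair
probabilities have homogeneous letters (A/T at 26.6%) and no length bias;
`gamma` and `beta_D` are one of infinitely many transition-probability
choices that reproduce the scheme exactly (any other feasible `ω` gives
the same scores back). The `examples/` directory has one short script per
capability — conversions, special temperatures, parameter limits,
alignment with posterior reliabilities, Gumbel calibration — each printing
and explaining its numbers.

A thin CLI wraps the library for shell use:

```sh
alnprob temperature --matrix HoxD70
alnprob align pair.fa --matrix HoxD70 --open 430 --extend 30
alnprob posterior pair.fa --matrix HoxD70 --open 430 --extend 30 --t 30 --maf
alnprob calibrate --matrix Simple --open 6 --extend 1 --seed 1
```

Gap costs on the command line are positive open/extend costs; internally a
length-k gap scores `a + b(k−1)` with `a = −open`, `b = −extend`.

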