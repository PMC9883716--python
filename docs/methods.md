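# Methods

## Model

A pair hidden Markov model (PHMM) generates two sequences `R` (length m)
and `Q` (length n): unaligned flank letters are emitted with probabilities
`ω_D φ_x` (reference side) and `ω_I ψ_y` (query side), an aligned core
emits pairs `x:y` with probability `π_xy` under transition probabilities
`γ` (aligned pair), `α` (open gap) and `β` (extend gap). The probability of
any path factorizes against the null path (zero aligned letters, probability
`μ_G`), and the per-column ratios are exactly the exponentiated scores:

```
match x:y        S'_xy = exp(S_xy/t) = π_xy/(φ_x ψ_y) · γ/(ω_D ω_I)
first gap        a'    = exp(a/t)    = α(1−β)/ω
gap extension    b'    = exp(b/t)    = β/ω
```

Gap scores use the `a + b(k−1)` convention for a length-k gap, which makes
these identities exact. The primed quantities are invariant across the
family: `ω_D, ω_I` can be chosen freely and `γ = c'ω_Dω_I`,
`β = b'ω`, `α = a'ω/(1−b'ω)` recover a concrete model, provided
`γ + α_D + α_I < 1`. Maximum-score alignment is Viterbi decoding of any
family member; the Forward sum over all paths is likewise shared by the
family, because only primed quantities enter its recurrences.

One point deserves emphasis because typesetting often obscures it: the
invariant tied to the matrix is `c' = γ/(ω_D ω_I) = Σ_xy φ_x ψ_y S'_xy` —
a ratio, not a product — which is why tabulated values like 6.06 (HoxD70 at
t=30) are legitimate despite every individual parameter being < 1. This
package uses the ratio form uniformly for all topologies.

### Special temperatures

With homogeneous letter probabilities (`φ_x = Σ_y π_xy`, `ψ_y = Σ_x π_xy`),
`ψ'` solves the linear system `Σ_y S'_xy ψ'_y = 1` and `c(t) = 1/Σψ'`.
`c(t)` falls from large values at small t to a minimum below 1 and returns
to 1 from below as t → ∞; the single finite crossing `c(t) = 1` is the
uniform-length temperature (no prior bias over alignment lengths). For
affine gaps the balanced condition is `C' = c' + a'_D/(1−b'_D) +
a'_I/(1−b'_I) = 1`; since the gap terms are positive, balance requires
`c'` slightly below 1, which happens at two temperatures (or none) — it
never pins down t uniquely.

### Feasibility limits

For symmetric gaps, `γ + α_D + α_I = c'ω² + 2a'ω/(1−b'ω)` is increasing in
ω, so the feasible region ends at the smallest (0,1)-root of
`b'c'ω³ − c'ω² − (2a'+b')ω + 1 = 0`; when no root lies in (0,1), ω is
unconstrained below 1 (this happens exactly when `C' ≤ 1`). In the large-t
limit `a', b', c' → 1` and the root tends to 0.311, with
`α = ω/(1−ω) → 0.452`.

The "maximum possible γ" over temperature is deliberately not exposed as a
tested quantity: evaluating `γ = c'ω²` at the cubic root does not
reproduce a single obvious limiting value, and the optimization that would
define a γ-maximum is not determined by the quantities above. Only the ω,
α and β limit curves, which follow directly from the cubic, are computed.

## Algorithms

* **Viterbi local alignment**, two variants: the X/Y/Z form (match,
  deletion, insertion endings; insertions may follow deletions but not the
  reverse) and the W-folded form. They return equal optima whenever
  `a ≤ b` on both gap sides; when `a > b` the W-folded variant may split a
  long gap into several first-gaps, which is a modeling choice, so both
  are computed and a warning is logged rather than an error raised.
  Traceback prefers match over deletion over insertion over restart, and
  the smallest (i, j) among equal-scoring endpoints; predecessor tests
  compare values in exactly the form the recursion computed them, so
  recomputed alignment scores equal the DP optimum bit-for-bit.
* **Forward, model A** (symmetric affine topology): sum-product
  counterpart of the W-folded recursion with a "+1" per cell. The "+1"
  counts null flank-split paths — the model distinguishes which flank
  emits each unaligned letter, so an empty core corresponds to
  (m+1)(n+1) distinct paths, and a run of k deletions to every mix of
  new-gap/extension steps. The exhaustive path enumerator in
  `enumerate_paths` implements precisely this path semantics and is the
  oracle the Forward implementation is tested against (1e-9 relative on
  all m, n ≤ 4).
* **Forward, model B**: the stricter topology — cores begin and end with
  an aligned pair, one path per gap run, no deletion directly after an
  insertion — implemented as the sum-product counterpart of the X/Y/Z
  recursion with starts entering at match cells and total
  `1 + Σ X'`. Its recurrences are validated only against its own
  enumerator; model A's total strictly exceeds model B's whenever any gap
  factor is positive, because A's path set is a superset.
* **Posterior column reliability**: model A's path weights are invariant
  under jointly reversing both sequences, so the backward table is the
  forward X' table of the reversed problem and
  `P[i,j] = X'_f · X'_b / (S'_xy · total)` (one S' factor is shared).
  Deletion/insertion columns report `1 − (row/column sum)` — the posterior
  that the letter is unaligned.
* **Hybrid score**: `max_ij t·ln W'_ij` — the Forward table with the final
  summation replaced by maximization.

### Numerics

Forward tables are scaled per row once any entry exceeds 2^512, with an
accumulated log-scale per row; totals are assembled by log-sum-exp, so
schemes with per-match odds like e^{91/30} run on hundreds of letters
without overflow. Mapping probabilities use max-subtracted softmax.
Temperature searches scan 512 (balance: 1024) log-spaced points over
`[10⁻³, 10⁶]·max|S|` and refine each bracket by bisection to near machine
precision; grid points where the linear solve is singular or numerically
degenerate (exp overflow at tiny t) are skipped, with a summary warning.
Solved letter probabilities in [−10⁻¹², 0] are clamped to zero; anything
more negative raises a "not consistent with homogeneous letter
probabilities" error. The cubic is solved via the companion matrix after
substituting `ω = v/√c'` (so the small root survives when c' is
astronomically large) and dropping leading coefficients below 10⁻¹⁴ of the
largest; |C'−1| ≤ 10⁻⁹ counts as balanced.

## Gumbel calibration

`check_lambda` simulates independent-monomer sequence pairs from Φ, Ψ
(deterministically seeded per replicate), computes hybrid scores, and fits
a Gumbel by maximum likelihood (Newton on the profile equation for the
scale, tolerance 10⁻¹⁰; standard errors from the observed information; a
method-of-moments fit is available as a cross-check). Defaults are
m = n = 100 and 1000 replicates — large enough for a fit SE of a few
percent, small enough to run in seconds to minutes.

What the simulations do and do not show: the generator emulates the null
model of the significance claim (i.i.d. letters), not real genomic
sequence — no repeats, no composition heterogeneity, no indel clustering.
`λ̂·t` should approach 1 under balanced parameters as sequences grow. At
the lower balanced temperature of Simple:6:1 the measured ratio is ≈ 1.05
at length 100 and ≈ 1.01 at length 200; at the higher balanced
temperature, where mismatch probabilities are large, convergence is much
slower (≈ 1.6 at length 100), an edge effect this package does not
correct for. The length trend is what the test suite asserts in addition
to the fixed-length value.

## Design choices

* "Alignment" means "path": the enumerator counts distinguishable state
  paths, including flank splits; this is the convention that makes
  `Σ W'` equal the enumeration exactly.
* The CLI accepts positive open/extend gap costs and converts to
  `a = −open`, `b = −extend`; the library uses signed scores throughout.
* Coordinates are 0-based half-open internally and in TSV output; MAF
  output follows MAF conventions, with a `p` line encoding per-column
  reliability as deciles '0'–'9' and '+' for ≥ 0.95.
* The default alphabet is DNA (ACGT); other alphabets enter via matrix
  files, whose header defines the letters.
* Only the symmetric-gap cubic is implemented as a limit solver; for
  asymmetric gaps, feasibility is checked numerically inside
  `realize_phmm` instead.

## Limitations

* No multi-segment (split) alignment, no E-value machinery, no
  importance-sampling Gumbel estimation, and no summation over
  indistinguishable path classes beyond what the Forward recursion itself
  performs.
* Model B's exact recurrence form is a package convention (documented
  above), isolated behind its topology tag and validated against its own
  enumerator.
* No Baum–Welch estimation: scores are mapped to models, not data to
  models.
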