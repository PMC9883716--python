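"""Check the Gumbel scale of hybrid scores under balanced parameters.

Hybrid scores (Forward summation replaced by a final maximization) of
random independent-monomer sequences are expected to follow a Gumbel
distribution with scale lambda = 1/t when the parameters satisfy the
balanced length condition.  This runs a small simulation at both balanced
temperatures of Simple:6:1 and reports lambda_hat * t.
"""

import alnprob as ap

phi = ap.LetterProbs.uniform(ap.DNA)
config = ap.SimConfig(
    m=100, n=100, Phi=phi, Psi=phi, replicates=200, seed=7
)
for res in ap.check_lambda(ap.SIMPLE, -6, -1, config):
    print(
        f"t = {res.t_balanced:.4f}: lambda_hat = {res.fit.lambda_hat:.3f} "
        f"(SE {res.fit.se_lambda:.3f}), lambda_hat * t = {res.ratio:.3f}"
    )
print(
    "\nlambda_hat * t near 1 supports the lambda = 1/t claim; the deviation"
    "\nis a finite-length effect and shrinks as sequences grow (slowly at"
    "\nthe higher balanced temperature, where mismatches are frequent)."
)
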