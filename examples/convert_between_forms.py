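"""Translate a Gompertz-Laird parameter set into interpretable forms.

The Laird parameters (W_0, L, K) are hard to read directly: L and K
jointly control the asymptote, the inflection time and the growth rate.
Converting to the unified summary exposes A, T_i, k_U and K_U, and the
same curve can then be re-expressed in any other parameterization —
exact algebra, no refitting.
"""

import growthfit as gf

laird = gf.ParamVector("laird", {"W_0": 1.0, "L": 3.45388, "K": 1.5})

s = gf.to_summary(laird)
print("Gompertz-Laird (W_0=1, L=3.45388, K=1.5) describes:")
print(f"  upper asymptote     A   = {s.A:.4f}")
print(f"  inflection time     T_i = {s.T_i:.4f}")
print(f"  max relative rate   k_U = {s.k_U:.4f}  (= k_G/e)")
print(f"  max absolute rate   K_U = {s.K_U:.4f}  (= A·k_U)")
print(f"  initial abs. rate       = {gf.initial_rates(laird)['absolute']:.4f}  (= W_0·L)")

for target in ("gompertz-ti", "u-gompertz-ti", "zwietering"):
    q = gf.from_summary(s, target)
    printable = ", ".join(f"{k}={v:.4f}" for k, v in q.params.items())
    print(f"  as {target:14s} -> {printable}")
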