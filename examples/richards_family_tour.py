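"""The Richards shape parameter d selects the family member.

d=2 is the logistic (inflection at A/2), d=2/3 the von Bertalanffy
(inflection at 8A/27), and d→1 the Gompertz limit (A/e).  The unified
forms share the k_U parameter — the maximum relative growth rate — so it
is comparable across members without conversion equations.
"""

import growthfit as gf

A, k_U, T_i = 10.0, 0.4, 2.0
for d in (2.0, 2 / 3, 1.0, 1.37):
    label = gf.special_case_of(d)
    w_i = gf.richards_inflection_value(A, d)
    p = gf.ParamVector("u-richards-ti", {"A": A, "k_U": k_U, "T_i": T_i, "d": d})
    slope = gf.derivative(p, T_i, 1)
    print(
        f"d={d:5.3f}  {label:16s}  W_i = {w_i:6.3f} ({100 * w_i / A:5.1f}% of A)"
        f"   max slope = {slope:.4f} (= A·k_U for every member)"
    )
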