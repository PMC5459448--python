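"""Evaluate a Gompertz curve and locate its inflection point.

Builds the reference curve (A=10, k_G=1.5, T_i=2) and prints the fixed
geometry of the Gompertz family: the inflection always falls at A/e,
36.8% of the upper asymptote, where the slope is k_G·A/e.
"""

import growthfit as gf

p = gf.ParamVector("gompertz-ti", {"A": 10.0, "k_G": 1.5, "T_i": 2.0})

point = gf.inflection(p)
print(f"W(0)      = {gf.evaluate(p, 0.0):.4g}     (starting value)")
print(f"W(T_i)    = {point.W_i:.4f}     ({100 * point.W_i / 10:.1f}% of A — fixed for any Gompertz)")
print(f"dW/dt|T_i = {gf.derivative(p, point.T_i, 1):.4f}     (max slope, k_G·A/e)")
print(f"d2W/dt2|T_i = {gf.derivative(p, point.T_i, 2):.1e}  (zero at inflection)")

rates = gf.max_rates(p)
print(f"k_U = {rates['k_U']:.4f} per day  (max relative growth rate, k_G/e)")
print(f"K_U = {rates['K_U']:.4f} per day  (max absolute growth rate, A·k_U)")
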