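# growthfit

Sigmoid growth curves of the Gompertz/Richards family for biologists:
evaluate, convert between, fit, and simulate every common parameterization
of the Gompertz growth model, including the *unified* (U-Gompertz,
U-Richards) forms whose growth parameter is directly the maximum relative
or absolute growth rate.

## Who this is for

Anyone fitting S-shaped trajectories — chick and fish body mass, bacterial
counts or optical density, tumour volume, shell length.  The Gompertz model
appears in the literature under more than a dozen algebraically equivalent
parameterizations (Gompertz-Laird in cancer and poultry work, the
Zwietering "modified Gompertz" in food microbiology, the Zweifel-Lasker /
Ricker form in fisheries, …), and their coefficients are routinely
misread — the traditional k_G, for instance, is *not* the maximum relative
growth rate; that is k_G/e.  This package treats all of these as
coordinates on one curve and moves between them exactly.

## The model

Every three-parameter Gompertz form draws

    W(t) = A · exp(−exp(−k_G (t − T_i)))

with upper asymptote A, growth coefficient k_G and inflection time T_i.
The inflection value is locked at W_i = A/e ≈ 36.8% of A; the maximum
relative growth rate is k_U = k_G/e and the maximum absolute growth rate
(the tangent at inflection) is K_U = A·k_U.  The U-Gompertz forms

    W(t) = A · exp(−exp(−e·k_U (t − T_i)))          (Ti-form)
    W(t) = A · (W_0/A)^exp(−e·k_U·t)                (W0-form)

expose k_U (or, in the absolute-rate variants, K_U) as a fitted parameter,
so confidence intervals for the biologically meaningful rate come straight
from the regression.  The enclosing Richards family

    W(t) = A · (1 + (d−1) exp(−k_U d^{d/(d−1)} (t − T_i)))^{1/(1−d)}

adds a shape parameter d moving the inflection: d=2 gives the logistic
(W_i = A/2), d=2/3 the von Bertalanffy (8A/27), and d→1 the Gompertz.
All U-forms share the same k_U, comparable across members without
conversion equations.

Supported forms (by `GrowthForm` name): `gompertz-ti`, `gompertz-b`,
`gompertz-c`, `gompertz-w0`, `four-param-compressed`, `four-param-offset`,
`zwietering`, `zweifel-lasker`, `laird`, `richards`, `u-richards-ti`,
`u-richards-w0`, `u-gompertz-ti`, `u-gompertz-w0`, `u-gompertz-abs-ti`,
`u-gompertz-abs-w0`.

## Worked example

Laird coordinates (common in tumour and poultry growth) are notoriously
hard to interpret; convert them instead of squinting:

```python
import growthfit as gf

laird = gf.ParamVector("laird", {"W_0": 1.0, "L": 3.45388, "K": 1.5})
s = gf.to_summary(laird)
```

`examples/convert_between_forms.py` prints:

```
Gompertz-Laird (W_0=1, L=3.45388, K=1.5) describes:
  upper asymptote     A   = 10.0000
  inflection time     T_i = 0.5560
  max relative rate   k_U = 0.5518  (= k_G/e)
  max absolute rate   K_U = 5.5182  (= A·k_U)
  initial abs. rate       = 3.4539  (= W_0·L)
  as gompertz-ti    -> A=10.0000, k_G=1.5000, T_i=0.5560
  as u-gompertz-ti  -> A=10.0000, k_U=0.5518, T_i=0.5560
  as zwietering     -> A=10.0000, K_Z=5.5182, T_lag=-0.1106
```

So this parameter set describes growth to an asymptote of 10.0 with its
fastest (absolute) growth of 5.52 units per day at t = 0.556; the negative
Zwietering lag time says the inflection tangent crosses zero before the
start of observation.  The other scripts under `examples/` fit noisy data
(`fit_growth_data.py`), tour the Richards members
(`richards_family_tour.py`), locate inflections
(`evaluate_and_inflect.py`) and calibrate confidence intervals by
simulation (`parameter_recovery.py`).

A thin CLI wraps the same functions:

```sh
growthfit simulate --form gompertz-ti --params "A=10,kG=1.5,Ti=2" \
    --n 50 --noise additive:0.2 --seed 42 --out data.csv
growthfit fit data.csv --form u-gompertz-w0 --ci 0.95 --out result.json
growthfit convert --from laird --to u-gompertz-ti --params "W0=1,L=3.4539,K=1.5"
```

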