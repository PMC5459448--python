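# Methods

## The model family and its coordinates

All sixteen supported forms describe a monotonically increasing sigmoid.
The three-parameter Gompertz members reduce to the canonical double
exponential

    W(t) = B + S · exp(−exp(−k_G (t − T_i))),

with lower asymptote B (zero outside the four-parameter forms), span S,
growth coefficient k_G (per unit time) and inflection time T_i.  The
conversion layer works through a single unified summary
(A, W_0, T_i, W_i, k_G, k_U, K_U, d, B) and the identities

    b = ln c = k_G·T_i,           A = W_0·exp(m),       m = L/K,
    k_U = k_G/e,                  K_U = A·k_U,
    W_0 = A·exp(−exp(e·k_U·T_i)), T_i = ln(−ln(W_0/A))/(e·k_U),
    Zwietering: k_U = K_Z/A,      T_i = T_lag + A/(e·K_Z).

Conversions are exact algebra, never refits.  The Zwietering inflection
time is derived by setting the form's inner argument to zero; its
geometric meaning (the inflection tangent crosses W=0 at T_lag) is
asserted in the tests.  Negative inflection times are legal and flagged
(`past_inflection_at_start`): late sampling windows genuinely produce
them.

The Richards members are implemented as

    W(t) = A (1 + (d−1) e^{−r(t−T_i)})^{1/(1−d)},   r = k_U · d^{d/(d−1)},

the convention in which d=2 is the logistic, d=2/3 the von Bertalanffy and
d→1 the Gompertz, and in which k_U is the maximum relative growth rate for
*every* member (the normalization d^{d/(d−1)} → e as d→1 makes the limit
exactly the U-Gompertz).  The inflection value is W_i = A·d^{1/(1−d)},
which correctly gives A/2 at d=2, 8A/27 at d=2/3 and A/e in the limit; a
version of this expression circulates with the factor inverted, which
would place the logistic inflection at 2A, above the asymptote.

For the four-parameter forms the summary defines K_U = (A−B)·k_G/e (the
true maximum slope) and k_U = K_U/A, so K_U = A·k_U holds for every form
and k_U = k_G/e holds exactly whenever B = 0.

## Numerical choices

- Inner exponential arguments are clamped to ±700 before exponentiation;
  extreme times return the asymptotes rather than NaN.
- |d − 1| < 1e−8 dispatches Richards evaluation to the matched Gompertz
  limit, avoiding cancellation in d^{d/(d−1)}; away from the cutoff the
  d-exponents are computed through log1p and are stable to |d−1| ≈ 1e−8.
- W0-form evaluation stays in W_0 coordinates (A·exp(ln(W_0/A)·e^{−k t}))
  rather than converting to T_i, so optimizer iterates with W_0 ≥ A remain
  finite; the ParamVector boundary rejects such decreasing curves for
  users.
- Only increasing curves are modelled; parameter sets with W_0 ≥ A, or
  nonpositive rates, are rejected at construction.
- Time units are caller-defined and never rescaled internally.

## Fitting

Ordinary least squares on the measurement scale (optionally on ln W for
count-like data), minimized by bounded trust-region least squares (scipy
`least_squares`, method `trf`, ftol = xtol = 1e−12).  Strictly positive
parameters are optimized internally on the log scale: the W0-forms place
the starting value many orders of magnitude below the asymptote, and log
coordinates keep that direction well conditioned — with it, all Gompertz
forms reach the same optimum to the reparameterization-invariance
tolerances (RSS within 1e−6 relative, summaries within 1e−4 relative).

Default bounds: A ∈ (0, 10·max W], rate coefficients ∈ (0, 100/t-range],
T_i and T_lag within one data span of the observation window, d ∈
[0.05, 10].  The initial guess sets A₀ = 1.05·max W, W₀₀ to the first
positive observation, T_i₀ to the time of the observation nearest A₀/e,
and k_G₀ from the slope of ln(−ln(W/A₀)) against t over mid-range points
(2–90% of A₀), where the transform is linear with slope −k_G on an exact
Gompertz curve; the guess is then mapped into the target form through the
summary.  Multistart (default 5) perturbs positive parameters by ±30%
lognormal and location parameters additively, from a seeded generator;
equal-RSS ties break deterministically toward the smaller parameter norm.
Non-convergence is reported via `converged=False`, never raised.

Uncertainty is Wald: covariance s²(JᵀJ)⁻¹ with s² = RSS/(n−p), the
Jacobian mapped back to natural coordinates by the chain rule, a
pseudo-inverse plus warning when the (correlation-scaled) Jacobian is rank
deficient, and Student-t intervals on n−p degrees of freedom — the
behaviour of standard NLS software.  No weighting scheme is built in;
heteroscedastic weights are a deliberate extension point.

## The simulator and what passing tests mean

`simulate_series` evaluates a known curve on a design grid (uniform or
log-spaced) and adds either additive Gaussian noise (constant measurement
error) or multiplicative lognormal noise (constant CV, natural for
counts).  Values driven below 1e−9·A are clipped to that floor, with the
count recorded, so log-response fitting stays defined.  Per-replicate
seeds are `seed + replicate_index`, making any single replicate
reproducible in isolation.

The default validation conditions are a 50-point uniform design on
t ∈ [0, 8] around the reference curve (A = 10, K_U = 1.5, T_i = 2 — the
set whose implied starting value rounds to 1.0), with additive noise
sd = 0.2 for coverage experiments (500 replicates) and sd = 0.02·A for the
bias check (200 replicates).  These sizes keep the whole suite near a few
seconds while giving Monte-Carlo standard errors of about 0.01 on a
coverage estimate near 0.95.

The generator emulates independent homoscedastic (or constant-CV) errors
on a single trajectory.  It does not emulate repeated measures on the same
individual, autocorrelated residuals, or design imbalance, so passing
recovery and coverage tests certify the estimator and its intervals under
the assumed error model — not robustness to correlation structure in real
longitudinal data.

## Known limitations and open choices

- The four-parameter forms' B is weakly identified when the data's lower
  plateau is unobserved or at zero; recovery tests therefore use a truth
  with a visible lower asymptote (B = 2).
- Decreasing ("inactivation") Gompertz variants, linearized fitting,
  Bayesian or mixed-effects estimation, and model selection beyond
  RSS/AIC per form are out of scope.
- Uncertainty on converted (non-native) parameters is not propagated
  through conversions; fit the form that exposes the parameter you need —
  that is the point of the unified forms.
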