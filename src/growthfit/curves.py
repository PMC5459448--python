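"""Closed-form evaluation of every model form in the family.

Every form here draws the same S-shaped trajectory in different coordinates.
The three-parameter Gompertz forms all reduce to

    W(t) = B + S * exp(-exp(-k_G * (t - T_i)))

for some lower asymptote ``B`` (zero except in the four-parameter forms),
span ``S`` and growth coefficient ``k_G``; the Richards forms generalize the
double exponential to

    W(t) = A * (1 + (d - 1) * exp(-r * (t - T_i)))**(1 / (1 - d))

whose d→1 limit recovers the Gompertz.  Evaluation, analytic first/second
derivatives and the inflection point are implemented per-form so that the
computation stays in each form's native coordinates (important for fitting,
where intermediate iterates may violate cross-parameter constraints such as
W_0 < A that the canonical coordinates require).

Inner exponential arguments are clamped to ±700 before exponentiation so
extreme times return the asymptotes instead of overflowing to NaN.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .errors import DomainError, UnsupportedFormError
from .forms import (
    PARAM_NAMES,
    RICHARDS_FORMS,
    GrowthForm,
    InflectionPoint,
    ParamVector,
    coerce_form,
)

_E = math.e
_CLAMP = 700.0
#: |d - 1| below this dispatches Richards evaluation to the Gompertz limit,
#: avoiding catastrophic cancellation in the d-dependent exponents.
_D_GOMPERTZ_TOL = 1e-8


def _exp(z: np.ndarray) -> np.ndarray:
    """exp with the argument clamped to the representable range."""
    return np.exp(np.clip(z, -_CLAMP, _CLAMP))


def _richards_rate_factor(d: float) -> float:
    """d**(d/(d-1)), the factor relating k_U to the Richards exponent rate.

    Continuous at d=1 with limit e; computed via log1p for stability near 1.
    """
    if abs(d - 1.0) < _D_GOMPERTZ_TOL:
        return _E
    return math.exp(d * math.log1p(d - 1.0) / (d - 1.0))


def _dpow(d: float) -> float:
    """d**(1/(1-d)), the inflection fraction W_i/A of the Richards family.

    Continuous at d=1 with limit 1/e (the Gompertz 36.8% point).
    """
    if abs(d - 1.0) < _D_GOMPERTZ_TOL:
        return 1.0 / _E
    return math.exp(-math.log1p(d - 1.0) / (d - 1.0))


# ---------------------------------------------------------------------------
# canonical pieces: every Gompertz-type form reduces to (B, span, k_G, T_i);
# every Richards-type form to (A, r, T_i, d) with r the exponent rate.
# ---------------------------------------------------------------------------


def _gompertz_pieces(form: GrowthForm, q: Mapping[str, float]):
    """(B, span, k_G, T_i) of the canonical double-exponential, or None.

    Returns None for forms whose T_i is undefined at the given parameters
    (only possible for out-of-domain iterates during optimization).
    """
    if form is GrowthForm.GOMPERTZ_TI:
        return 0.0, q["A"], q["k_G"], q["T_i"]
    if form is GrowthForm.GOMPERTZ_B:
        return 0.0, q["A"], q["k_G"], q["b"] / q["k_G"]
    if form is GrowthForm.GOMPERTZ_C:
        return 0.0, q["A"], q["k_G"], math.log(q["c"]) / q["k_G"]
    if form is GrowthForm.FOUR_PARAM_COMPRESSED:
        return q["B"], q["A"] - q["B"], q["k_G"], q["T_i"]
    if form is GrowthForm.FOUR_PARAM_OFFSET:
        return q["B"], q["A_scale"], q["k_G"], q["T_i"]
    if form is GrowthForm.ZWIETERING:
        k_G = _E * q["K_Z"] / q["A"]
        return 0.0, q["A"], k_G, q["T_lag"] + q["A"] / (_E * q["K_Z"])
    if form is GrowthForm.ZWEIFEL_LASKER:
        return 0.0, q["W_0"] * math.exp(q["m"]), q["k_G"], math.log(q["m"]) / q["k_G"]
    if form is GrowthForm.LAIRD:
        m = q["L"] / q["K"]
        return 0.0, q["W_0"] * math.exp(m), q["K"], math.log(m) / q["K"]
    if form is GrowthForm.U_GOMPERTZ_TI:
        return 0.0, q["A"], _E * q["k_U"], q["T_i"]
    if form is GrowthForm.U_GOMPERTZ_ABS_TI:
        return 0.0, q["A"], _E * q["K_U"] / q["A"], q["T_i"]
    if form in (GrowthForm.GOMPERTZ_W0, GrowthForm.U_GOMPERTZ_W0, GrowthForm.U_GOMPERTZ_ABS_W0):
        A = q["A"]
        if form is GrowthForm.GOMPERTZ_W0:
            k_G = q["k_G"]
        elif form is GrowthForm.U_GOMPERTZ_W0:
            k_G = _E * q["k_U"]
        else:
            k_G = _E * q["K_U"] / A
        ratio = q["W_0"] / A
        if not 0.0 < ratio < 1.0:
            return None
        return 0.0, A, k_G, math.log(-math.log(ratio)) / k_G
    raise UnsupportedFormError(f"{form.value} is not a Gompertz-type form")


def _richards_pieces(form: GrowthForm, q: Mapping[str, float]):
    """(A, r, T_i, d) of the Richards evaluation, or None when T_i undefined."""
    A, d = q["A"], q["d"]
    if form is GrowthForm.RICHARDS:
        return A, q["k_R"], q["T_i"], d
    r = q["k_U"] * _richards_rate_factor(d)
    if form is GrowthForm.U_RICHARDS_TI:
        return A, r, q["T_i"], d
    # u-richards-w0: solve for the T_i giving W(0) = W_0
    ratio = q["W_0"] / A
    if not 0.0 < ratio < 1.0:
        return None
    arg = (math.pow(ratio, 1.0 - d) - 1.0) / (d - 1.0)
    if arg <= 0.0:
        return None
    return A, r, math.log(arg) / r, d


def _as_gompertz_limit(form: GrowthForm, q: Mapping[str, float]) -> ParamVector:
    """The matched U-Gompertz/Gompertz member for a Richards form with d≈1."""
    if form is GrowthForm.RICHARDS:
        return ParamVector(
            GrowthForm.GOMPERTZ_TI, {"A": q["A"], "k_G": q["k_R"], "T_i": q["T_i"]}
        )
    if form is GrowthForm.U_RICHARDS_TI:
        return ParamVector(
            GrowthForm.U_GOMPERTZ_TI, {"A": q["A"], "k_U": q["k_U"], "T_i": q["T_i"]}
        )
    return ParamVector(
        GrowthForm.U_GOMPERTZ_W0, {"A": q["A"], "k_U": q["k_U"], "W_0": q["W_0"]}
    )


# ---------------------------------------------------------------------------
# raw evaluation on plain parameter mappings (no ParamVector validation):
# shared by the public API and by the fitting iterates.
# ---------------------------------------------------------------------------


def _eval_raw(form: GrowthForm, q: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    if form in RICHARDS_FORMS:
        d = q["d"]
        if abs(d - 1.0) < _D_GOMPERTZ_TOL:
            limit = _as_gompertz_limit(form, q)
            return _eval_raw(limit.form, limit.params, t)
        if form is GrowthForm.U_RICHARDS_W0:
            A, d = q["A"], q["d"]
            r = q["k_U"] * _richards_rate_factor(d)
            h0 = math.pow(max(q["W_0"] / A, 1e-300), 1.0 - d) - 1.0
            g = 1.0 + h0 * _exp(-r * t)
        else:
            pieces = _richards_pieces(form, q)
            A, r, T_i, d = pieces
            g = 1.0 + (d - 1.0) * _exp(-r * (t - T_i))
        g = np.maximum(g, 1e-300)
        return A * np.exp(np.clip(np.log(g) / (1.0 - d), -_CLAMP, _CLAMP))

    # direct W0-coordinate evaluation keeps fitting iterates with W_0 >= A
    # finite (they describe a decreasing curve and are rejected only at the
    # ParamVector boundary, not mid-search).
    if form in (GrowthForm.GOMPERTZ_W0, GrowthForm.U_GOMPERTZ_W0, GrowthForm.U_GOMPERTZ_ABS_W0):
        A = q["A"]
        if form is GrowthForm.GOMPERTZ_W0:
            k = q["k_G"]
        elif form is GrowthForm.U_GOMPERTZ_W0:
            k = _E * q["k_U"]
        else:
            k = _E * q["K_U"] / A
        return A * _exp(math.log(q["W_0"] / A) * _exp(-k * t))
    if form in (GrowthForm.ZWEIFEL_LASKER, GrowthForm.LAIRD):
        if form is GrowthForm.ZWEIFEL_LASKER:
            W0, m, k = q["W_0"], q["m"], q["k_G"]
        else:
            W0, m, k = q["W_0"], q["L"] / q["K"], q["K"]
        return W0 * _exp(m * (1.0 - _exp(-k * t)))

    B, S, k_G, T_i = _gompertz_pieces(form, q)
    return B + S * np.exp(-_exp(-k_G * (np.asarray(t, dtype=float) - T_i)))


def _deriv_raw(
    form: GrowthForm, q: Mapping[str, float], t: np.ndarray, order: int
) -> np.ndarray:
    if form in RICHARDS_FORMS:
        d = q["d"]
        if abs(d - 1.0) < _D_GOMPERTZ_TOL:
            limit = _as_gompertz_limit(form, q)
            return _deriv_raw(limit.form, limit.params, t, order)
        if form is GrowthForm.U_RICHARDS_W0:
            A = q["A"]
            r = q["k_U"] * _richards_rate_factor(d)
            h0 = math.pow(max(q["W_0"] / A, 1e-300), 1.0 - d) - 1.0
            u = (h0 / (d - 1.0)) * _exp(-r * t)
        else:
            A, r, T_i, d = _richards_pieces(form, q)
            u = _exp(-r * (t - T_i))
        g = np.maximum(1.0 + (d - 1.0) * u, 1e-300)
        if order == 1:
            return A * r * u * np.exp(np.clip(d * np.log(g) / (1.0 - d), -_CLAMP, _CLAMP))
        return (
            -A * r * r * u * (1.0 - u)
            * np.exp(np.clip((2.0 * d - 1.0) * np.log(g) / (1.0 - d), -_CLAMP, _CLAMP))
        )

    pieces = _gompertz_pieces(form, q)
    if pieces is None:
        raise DomainError("derivative undefined: W_0 must lie in (0, A)")
    B, S, k, T_i = pieces
    E = _exp(-k * (np.asarray(t, dtype=float) - T_i))
    core = S * np.exp(-E)
    if order == 1:
        return k * E * core
    return k * k * E * (E - 1.0) * core


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def evaluate(p: ParamVector, t) -> np.ndarray | float:
    """Expected measurement W(t) of the curve described by ``p``.

    Vectorized over ``t``; returns a scalar for scalar input.  For finite
    times the result lies strictly between the lower and upper asymptotes.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.isfinite(t_arr).all():
        raise DomainError("t must be finite")
    out = _eval_raw(p.form, p.params, t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def evaluate_log(p: ParamVector, t) -> np.ndarray | float:
    """ln W(t), in the numerically direct log form.

    Supported for the forms whose log transform is classically fitted to
    count data: the Ti-form Gompertz (ln W = ln A - exp(-k_G (t - T_i))),
    the Zweifel-Lasker form (ln W = ln W_0 + m (1 - exp(-k_G t))) and the
    W0-form Gompertz.  Agrees with ln(evaluate(p, t)) to machine precision
    but never underflows to log(0) at early times.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.isfinite(t_arr).all():
        raise DomainError("t must be finite")
    q = p.params
    if p.form is GrowthForm.GOMPERTZ_TI:
        out = math.log(q["A"]) - _exp(-q["k_G"] * (t_arr - q["T_i"]))
    elif p.form is GrowthForm.ZWEIFEL_LASKER:
        out = math.log(q["W_0"]) + q["m"] * (1.0 - _exp(-q["k_G"] * t_arr))
    elif p.form is GrowthForm.GOMPERTZ_W0:
        out = math.log(q["A"]) + math.log(q["W_0"] / q["A"]) * _exp(-q["k_G"] * t_arr)
    else:
        raise UnsupportedFormError(
            f"evaluate_log supports gompertz-ti, zweifel-lasker and gompertz-w0; "
            f"got {p.form.value}"
        )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def derivative(p: ParamVector, t, order: int = 1) -> np.ndarray | float:
    """Analytic dW/dt (order=1) or d²W/dt² (order=2).

    The first derivative is strictly positive at finite times for every
    increasing-form parameter set; the second derivative vanishes at the
    inflection time.
    """
    if order not in (1, 2):
        raise DomainError(f"order must be 1 or 2, got {order}")
    t_arr = np.asarray(t, dtype=float)
    if not np.isfinite(t_arr).all():
        raise DomainError("t must be finite")
    out = _deriv_raw(p.form, p.params, t_arr, order)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def inflection(p: ParamVector) -> InflectionPoint:
    """Inflection time and value.

    For every Gompertz form the inflection value is span/e above the lower
    asymptote (the 36.8% point when the lower asymptote is zero); for the
    Richards forms it is A·d^(1/(1-d)).
    """
    q = p.params
    if p.form in RICHARDS_FORMS:
        d = q["d"]
        if abs(d - 1.0) < _D_GOMPERTZ_TOL:
            limit = _as_gompertz_limit(p.form, q)
            return inflection(limit)
        pieces = _richards_pieces(p.form, q)
        if pieces is None:
            raise DomainError("inflection undefined for these parameters")
        A, _, T_i, d = pieces
        return InflectionPoint(T_i=float(T_i), W_i=float(A * _dpow(d)))
    pieces = _gompertz_pieces(p.form, q)
    if pieces is None:
        raise DomainError("inflection undefined: W_0 must lie in (0, A)")
    B, S, _, T_i = pieces
    return InflectionPoint(T_i=float(T_i), W_i=float(B + S / _E))
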