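"""Exact conversion between parameterizations and derived growth rates.

All forms of the Gompertz model describe the same curve; this module moves
between their coordinates by algebra, never by refitting.  The central
object is :class:`CurveSummary`, the unified description

    A    upper asymptote
    W_0  value at t = 0
    T_i  inflection time
    W_i  inflection value (A/e for Gompertz, A·d^(1/(1-d)) for Richards)
    k_G  traditional growth coefficient (e·k_U)
    k_U  maximum relative growth rate  = max dW/dt / A
    K_U  maximum absolute growth rate  = A·k_U
    d    Richards shape (1 for Gompertz members)
    B    lower asymptote (0 for three-parameter forms; None when unknown)

derivable from any form and mappable back into any form.  The key
identities are b = ln c = k_G·T_i, A = W_0·exp(m), k_U = k_G/e, and the
W_0 ↔ T_i bridge

    W_0 = A·exp(-exp(e·k_U·T_i)),     T_i = ln(-ln(W_0/A)) / (e·k_U).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .curves import _dpow, _richards_rate_factor, evaluate, inflection
from .errors import DomainError, UnsupportedFormError
from .forms import (
    FOUR_PARAM_FORMS,
    RICHARDS_FORMS,
    GrowthForm,
    ParamVector,
    coerce_form,
)

_E = math.e

__all__ = [
    "CurveSummary",
    "to_summary",
    "from_summary",
    "w0_from_ti",
    "ti_from_w0",
    "initial_rates",
    "max_rates",
    "richards_inflection_value",
    "special_case_of",
]


@dataclass(frozen=True)
class CurveSummary:
    """Unified description of one growth curve; see module docstring.

    ``past_inflection_at_start`` flags curves whose inflection time is
    negative (the trajectory is already decelerating at t = 0), which late
    sampling windows legitimately produce, e.g. in Laird fits.
    """

    A: float
    W_0: float
    T_i: float
    W_i: float
    k_G: float
    k_U: float
    K_U: float
    d: float = 1.0
    B: float | None = 0.0

    @property
    def past_inflection_at_start(self) -> bool:
        return self.T_i < 0.0

    def replace(self, **updates) -> "CurveSummary":
        return replace(self, **updates)


def w0_from_ti(A: float, k_U: float, T_i: float) -> float:
    """Starting value implied by the inflection time: A·exp(-exp(e·k_U·T_i)).

    Equals the U-Gompertz Ti-form evaluated at t = 0; lies in (0, A) for any
    finite T_i (below A/e when T_i > 0).
    """
    if A <= 0 or k_U <= 0:
        raise DomainError("A and k_U must be > 0")
    return A * math.exp(-math.exp(min(_E * k_U * T_i, 700.0)))


def ti_from_w0(A: float, k_U: float, W_0: float) -> float:
    """Inflection time implied by the starting value: ln(-ln(W_0/A))/(e·k_U).

    Exact inverse of :func:`w0_from_ti`; requires 0 < W_0 < A.
    """
    if A <= 0 or k_U <= 0:
        raise DomainError("A and k_U must be > 0")
    if not 0.0 < W_0 < A:
        raise DomainError(f"W_0 must lie in (0, A); got W_0={W_0}, A={A}")
    return math.log(-math.log(W_0 / A)) / (_E * k_U)


def richards_inflection_value(A: float, d: float) -> float:
    """Inflection value of the Richards family: W_i = A·d^(1/(1-d)).

    Gives the logistic A/2 at d=2, the von Bertalanffy 8A/27 at d=2/3, and
    is continuous at d=1 with the Gompertz value A/e.  (The multiplicative
    form is used throughout; a division by d^(1/(1-d)) would place the
    logistic inflection at 2A, above the asymptote.)
    """
    if A <= 0 or d <= 0:
        raise DomainError("A and d must be > 0")
    return A * _dpow(d)


def special_case_of(d: float, rel_tol: float = 1e-9) -> str:
    """Family member selected by the Richards shape parameter d."""
    if d <= 0:
        raise DomainError("d must be > 0")
    if math.isclose(d, 2.0, rel_tol=rel_tol):
        return "logistic"
    if math.isclose(d, 2.0 / 3.0, rel_tol=rel_tol):
        return "von Bertalanffy"
    if math.isclose(d, 1.0, rel_tol=rel_tol):
        return "Gompertz (limit)"
    return "Richards"


def to_summary(p: ParamVector) -> CurveSummary:
    """Unified curve description of any parameter set, by exact algebra."""
    q = p.params
    if p.form in RICHARDS_FORMS:
        A, d = q["A"], q["d"]
        if p.form is GrowthForm.RICHARDS:
            k_U = q["k_R"] / _richards_rate_factor(d)
        else:
            k_U = q["k_U"]
        point = inflection(p)
        W_0 = q["W_0"] if "W_0" in q else float(evaluate(p, 0.0))
        return CurveSummary(
            A=A,
            W_0=W_0,
            T_i=point.T_i,
            W_i=point.W_i,
            k_G=_E * k_U,
            k_U=k_U,
            K_U=A * k_U,
            d=d,
            B=0.0,
        )

    from .curves import _gompertz_pieces  # canonical (B, span, k_G, T_i)

    pieces = _gompertz_pieces(p.form, q)
    if pieces is None:
        raise DomainError("W_0 must lie in (0, A)")
    B, span, k_G, T_i = pieces
    A = B + span
    k_U = span * k_G / (_E * A)  # max slope span·k_G/e, relative to A
    return CurveSummary(
        A=A,
        W_0=float(evaluate(p, 0.0)),
        T_i=float(T_i),
        W_i=B + span / _E,
        k_G=float(k_G),
        k_U=float(k_U),
        K_U=A * float(k_U),
        d=1.0,
        B=float(B),
    )


def from_summary(s: CurveSummary, target: GrowthForm | str) -> ParamVector:
    """Native parameters of ``target`` describing the summarized curve.

    Richards targets accept d = 1 (the parameter set then evaluates through
    the Gompertz limit).  Gompertz targets require d = 1; four-parameter
    targets require a known lower asymptote B; three-parameter targets
    require B = 0.
    """
    target = coerce_form(target)
    A, k_G, T_i, d = s.A, s.k_G, s.T_i, s.d
    gompertz_like = target not in RICHARDS_FORMS

    if gompertz_like and abs(d - 1.0) > 1e-9:
        raise UnsupportedFormError(
            f"curve with Richards shape d={d} has no {target.value} representation"
        )
    if target in FOUR_PARAM_FORMS:
        if s.B is None:
            raise UnsupportedFormError(
                f"{target.value} requires a known lower asymptote B"
            )
    elif gompertz_like and s.B not in (None, 0.0):
        raise UnsupportedFormError(
            f"{target.value} cannot represent a nonzero lower asymptote (B={s.B})"
        )

    if target is GrowthForm.GOMPERTZ_TI:
        return ParamVector(target, {"A": A, "k_G": k_G, "T_i": T_i})
    if target is GrowthForm.GOMPERTZ_B:
        return ParamVector(target, {"A": A, "k_G": k_G, "b": k_G * T_i})
    if target is GrowthForm.GOMPERTZ_C:
        return ParamVector(target, {"A": A, "k_G": k_G, "c": math.exp(min(k_G * T_i, 700.0))})
    if target is GrowthForm.GOMPERTZ_W0:
        return ParamVector(target, {"A": A, "k_G": k_G, "W_0": w0_from_ti(A, k_G / _E, T_i)})
    if target is GrowthForm.FOUR_PARAM_COMPRESSED:
        return ParamVector(target, {"B": s.B, "A": A, "k_G": k_G, "T_i": T_i})
    if target is GrowthForm.FOUR_PARAM_OFFSET:
        return ParamVector(
            target, {"B": s.B, "A_scale": A - s.B, "k_G": k_G, "T_i": T_i}
        )
    if target is GrowthForm.ZWIETERING:
        K_Z = A * k_G / _E  # absolute growth rate at inflection
        return ParamVector(target, {"A": A, "K_Z": K_Z, "T_lag": T_i - A / (_E * K_Z)})
    if target is GrowthForm.ZWEIFEL_LASKER:
        W_0 = w0_from_ti(A, k_G / _E, T_i)
        return ParamVector(target, {"W_0": W_0, "m": math.log(A / W_0), "k_G": k_G})
    if target is GrowthForm.LAIRD:
        W_0 = w0_from_ti(A, k_G / _E, T_i)
        return ParamVector(target, {"W_0": W_0, "L": k_G * math.log(A / W_0), "K": k_G})
    if target is GrowthForm.RICHARDS:
        k_R = s.k_U * _richards_rate_factor(d)
        return ParamVector(target, {"A": A, "k_R": k_R, "T_i": T_i, "d": d})
    if target is GrowthForm.U_RICHARDS_TI:
        return ParamVector(target, {"A": A, "k_U": s.k_U, "T_i": T_i, "d": d})
    if target is GrowthForm.U_RICHARDS_W0:
        return ParamVector(
            target, {"A": A, "k_U": s.k_U, "W_0": _richards_w0(A, s.k_U, T_i, d), "d": d}
        )
    if target is GrowthForm.U_GOMPERTZ_TI:
        return ParamVector(target, {"A": A, "k_U": s.k_U, "T_i": T_i})
    if target is GrowthForm.U_GOMPERTZ_W0:
        return ParamVector(target, {"A": A, "k_U": s.k_U, "W_0": w0_from_ti(A, s.k_U, T_i)})
    if target is GrowthForm.U_GOMPERTZ_ABS_TI:
        return ParamVector(target, {"A": A, "K_U": s.K_U, "T_i": T_i})
    if target is GrowthForm.U_GOMPERTZ_ABS_W0:
        return ParamVector(
            target, {"A": A, "K_U": s.K_U, "W_0": w0_from_ti(A, s.k_U, T_i)}
        )
    raise UnsupportedFormError(f"no conversion to {target!r}")  # pragma: no cover


def _richards_w0(A: float, k_U: float, T_i: float, d: float) -> float:
    """W(0) of the U-Richards Ti-form."""
    if abs(d - 1.0) < 1e-8:
        return w0_from_ti(A, k_U, T_i)
    r = k_U * _richards_rate_factor(d)
    g = 1.0 + (d - 1.0) * math.exp(min(r * T_i, 700.0))
    return A * math.exp(math.log(g) / (1.0 - d))


def initial_rates(p: ParamVector) -> dict[str, float]:
    """Absolute and relative growth rates at t = 0.

    The absolute rate is dW/dt at zero (W_0·k_G·m for the Zweifel-Lasker
    form, W_0·L for the Gompertz-Laird); the relative rate divides by the
    upper asymptote.
    """
    from .curves import derivative

    absolute = float(derivative(p, 0.0, 1))
    A = to_summary(p).A
    return {"absolute": absolute, "relative": absolute / A}


def max_rates(p: ParamVector) -> dict[str, float]:
    """Maximum (inflection-point) growth rates: k_U relative, K_U absolute.

    For every Gompertz form k_U = k_G/e and K_U = A·k_U; the Zwietering
    coefficient K_Z is already K_U.
    """
    s = to_summary(p)
    return {"k_U": s.k_U, "K_U": s.K_U}
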