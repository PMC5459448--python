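"""Model-form inventory and parameter containers.

The Gompertz model exists in the literature under many exactly equivalent
parameterizations.  Each member of :class:`GrowthForm` names one of them;
:class:`ParamVector` pairs a form with its native parameter values, after
validating the form's domain constraints (positive asymptote and rates,
starting value below the asymptote, and so on).  The Richards forms carry a
shape exponent ``d`` selecting the family member (d=2 logistic, d=2/3 von
Bertalanffy, d→1 Gompertz).

Only increasing curves are modelled: decreasing ("inactivation-kinetics")
Gompertz variants are out of scope and their parameter sets are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import numpy as np

from .errors import DomainError, NonMonotoneTimeError, UnsupportedFormError


class GrowthForm(str, Enum):
    """Enumeration of the supported growth-model parameterizations."""

    GOMPERTZ_TI = "gompertz-ti"            # A·exp(-exp(-kG(t-Ti)))
    GOMPERTZ_B = "gompertz-b"              # A·exp(-exp(-kG·t + b))
    GOMPERTZ_C = "gompertz-c"              # A·exp(-c·exp(-kG·t))
    GOMPERTZ_W0 = "gompertz-w0"            # A·(W0/A)^exp(-kG·t)
    FOUR_PARAM_COMPRESSED = "four-param-compressed"  # B + (A-B)·exp(-exp(-kG(t-Ti)))
    FOUR_PARAM_OFFSET = "four-param-offset"          # B + A_scale·exp(-exp(-kG(t-Ti)))
    ZWIETERING = "zwietering"              # A·exp(-exp(e·KZ/A·(TLag-t) + 1))
    ZWEIFEL_LASKER = "zweifel-lasker"      # W0·exp(m(1-exp(-kG·t)))
    LAIRD = "laird"                        # W0·exp((L/K)(1-exp(-K·t)))
    RICHARDS = "richards"                  # A·(1+(d-1)exp(-kR(t-Ti)))^(1/(1-d))
    U_RICHARDS_TI = "u-richards-ti"
    U_RICHARDS_W0 = "u-richards-w0"
    U_GOMPERTZ_TI = "u-gompertz-ti"        # A·exp(-exp(-e·kU(t-Ti)))
    U_GOMPERTZ_W0 = "u-gompertz-w0"        # A·(W0/A)^exp(-e·kU·t)
    U_GOMPERTZ_ABS_TI = "u-gompertz-abs-ti"  # A·exp(-exp(-e·KU(t-Ti)/A))
    U_GOMPERTZ_ABS_W0 = "u-gompertz-abs-w0"  # A·(W0/A)^exp(-e·KU·t/A)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Native parameter names, in canonical order, for each form.
PARAM_NAMES: dict[GrowthForm, tuple[str, ...]] = {
    GrowthForm.GOMPERTZ_TI: ("A", "k_G", "T_i"),
    GrowthForm.GOMPERTZ_B: ("A", "k_G", "b"),
    GrowthForm.GOMPERTZ_C: ("A", "k_G", "c"),
    GrowthForm.GOMPERTZ_W0: ("A", "k_G", "W_0"),
    GrowthForm.FOUR_PARAM_COMPRESSED: ("B", "A", "k_G", "T_i"),
    GrowthForm.FOUR_PARAM_OFFSET: ("B", "A_scale", "k_G", "T_i"),
    GrowthForm.ZWIETERING: ("A", "K_Z", "T_lag"),
    GrowthForm.ZWEIFEL_LASKER: ("W_0", "m", "k_G"),
    GrowthForm.LAIRD: ("W_0", "L", "K"),
    GrowthForm.RICHARDS: ("A", "k_R", "T_i", "d"),
    GrowthForm.U_RICHARDS_TI: ("A", "k_U", "T_i", "d"),
    GrowthForm.U_RICHARDS_W0: ("A", "k_U", "W_0", "d"),
    GrowthForm.U_GOMPERTZ_TI: ("A", "k_U", "T_i"),
    GrowthForm.U_GOMPERTZ_W0: ("A", "k_U", "W_0"),
    GrowthForm.U_GOMPERTZ_ABS_TI: ("A", "K_U", "T_i"),
    GrowthForm.U_GOMPERTZ_ABS_W0: ("A", "K_U", "W_0"),
}

#: Forms whose native parameters include the starting value W_0.
W0_FORMS = frozenset(
    {
        GrowthForm.GOMPERTZ_W0,
        GrowthForm.ZWEIFEL_LASKER,
        GrowthForm.LAIRD,
        GrowthForm.U_RICHARDS_W0,
        GrowthForm.U_GOMPERTZ_W0,
        GrowthForm.U_GOMPERTZ_ABS_W0,
    }
)

#: Forms with the four-parameter Richards shape exponent d.
RICHARDS_FORMS = frozenset(
    {GrowthForm.RICHARDS, GrowthForm.U_RICHARDS_TI, GrowthForm.U_RICHARDS_W0}
)

#: Four-parameter (lower-asymptote) Gompertz forms.
FOUR_PARAM_FORMS = frozenset(
    {GrowthForm.FOUR_PARAM_COMPRESSED, GrowthForm.FOUR_PARAM_OFFSET}
)

# Parameters that must be strictly positive, per form domain.
_POSITIVE = frozenset(
    {"A", "A_scale", "k_G", "k_U", "K_U", "K_Z", "K", "k_R", "W_0", "c", "m", "L", "d"}
)


def coerce_form(form: "GrowthForm | str") -> GrowthForm:
    """Accept either a :class:`GrowthForm` or its string name."""
    if isinstance(form, GrowthForm):
        return form
    try:
        return GrowthForm(form)
    except ValueError as exc:
        valid = ", ".join(f.value for f in GrowthForm)
        raise UnsupportedFormError(
            f"unknown growth form {form!r}; valid forms: {valid}"
        ) from exc


@dataclass(frozen=True)
class ParamVector:
    """A tagged parameter set: one model form plus its native parameter values.

    Parameters
    ----------
    form
        Which parameterization the values belong to.
    params
        Mapping from the form's native parameter names (see ``PARAM_NAMES``)
        to values.

    Raises
    ------
    DomainError
        If a parameter is missing, unexpected, or outside the form's domain.
    """

    form: GrowthForm
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", coerce_form(self.form))
        expected = PARAM_NAMES[self.form]
        got = set(self.params)
        if got != set(expected):
            raise DomainError(
                f"form {self.form.value!r} takes parameters {expected}, got {sorted(got)}"
            )
        clean = {k: float(self.params[k]) for k in expected}
        object.__setattr__(self, "params", clean)
        for name, value in clean.items():
            if not np.isfinite(value):
                raise DomainError(f"{name} must be finite, got {value}")
            if name in _POSITIVE and value <= 0:
                raise DomainError(f"{name} must be > 0, got {value}")
        # Increasing curves only: the starting value must sit below the
        # asymptote wherever both are native parameters.
        if "W_0" in clean and "A" in clean and clean["W_0"] >= clean["A"]:
            raise DomainError(
                f"W_0 must be < A for increasing curves "
                f"(got W_0={clean['W_0']}, A={clean['A']})"
            )
        if self.form in FOUR_PARAM_FORMS:
            if self.form is GrowthForm.FOUR_PARAM_COMPRESSED and (
                clean["B"] >= clean["A"]
            ):
                raise DomainError("four-param-compressed requires B < A")

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_array(self) -> np.ndarray:
        """Native parameter values in canonical order."""
        return np.array([self.params[k] for k in PARAM_NAMES[self.form]])

    @classmethod
    def from_array(cls, form: "GrowthForm | str", theta: np.ndarray) -> "ParamVector":
        form = coerce_form(form)
        names = PARAM_NAMES[form]
        if len(theta) != len(names):
            raise DomainError(
                f"form {form.value!r} takes {len(names)} parameters, got {len(theta)}"
            )
        return cls(form, dict(zip(names, map(float, theta))))

    def replace(self, **updates: float) -> "ParamVector":
        """A copy with some parameter values changed."""
        merged = {**self.params, **updates}
        return ParamVector(self.form, merged)


@dataclass(frozen=True)
class TimeSeries:
    """Paired time/measurement arrays for one growth trajectory.

    Times must be strictly increasing; values are non-negative measurements
    (mass, length, count or log-count — units are the caller's and are never
    rescaled internally).
    """

    times: np.ndarray
    values: np.ndarray
    n_clipped: int = 0  # noisy values clipped to the positivity floor

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or w.ndim != 1:
            raise DomainError("times and values must be one-dimensional")
        if t.shape != w.shape:
            raise DomainError(
                f"times ({t.size}) and values ({w.size}) must have equal length"
            )
        if t.size < 2:
            raise DomainError("a time series needs at least 2 points")
        if not (np.isfinite(t).all() and np.isfinite(w).all()):
            raise DomainError("times and values must be finite")
        dt = np.diff(t)
        if np.any(dt == 0):
            raise NonMonotoneTimeError("tied time values")
        if np.any(dt < 0):
            raise NonMonotoneTimeError("times must be strictly increasing")
        if np.any(w < 0):
            raise DomainError("negative measurement values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", w)

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.times, self.values))


@dataclass(frozen=True)
class InflectionPoint:
    """Time and value at which the absolute growth rate is maximal."""

    T_i: float
    W_i: float
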