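"""Nonlinear least-squares estimation of any form's parameters.

The loss is ordinary (homoscedastic) least squares on the measurement
scale, or on the log scale when ``log_response`` is set — the classical
choice for count-like data.  Minimization uses bounded trust-region least
squares (scipy ``least_squares``, method ``trf``) started from a
data-driven initial guess, optionally multistarted from seeded lognormal
perturbations of that guess to escape the plateaus that double-exponential
surfaces are known for.

Uncertainty is Wald: the parameter covariance is s²(JᵀJ)⁻¹ with s² the
residual variance on n − p degrees of freedom, and confidence intervals use
Student-t quantiles, matching standard NLS software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .curves import _eval_raw
from .errors import DegenerateDataError, DomainError, InsufficientDataError
from .forms import (
    FOUR_PARAM_FORMS,
    PARAM_NAMES,
    RICHARDS_FORMS,
    _POSITIVE,
    GrowthForm,
    ParamVector,
    TimeSeries,
    coerce_form,
)
from .reparam import CurveSummary, from_summary, to_summary

_E = math.e
_TINY = 1e-10

__all__ = [
    "FitOptions",
    "FitResult",
    "initial_guess",
    "fit",
    "confidence_intervals",
    "fit_all_forms",
]


@dataclass(frozen=True)
class FitOptions:
    """Controls for the least-squares fit.

    multistart > 1 reruns the optimizer from seeded ±30% lognormal
    perturbations of the initial guess and keeps the lowest residual sum of
    squares, breaking exact ties by the smaller parameter norm.
    """

    max_iterations: int = 200
    tolerance: float = 1e-12
    bounds: dict[str, tuple[float, float]] | None = None
    multistart: int = 5
    seed: int = 0
    log_response: bool = False
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise DomainError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise DomainError("tolerance must be > 0")
        if self.multistart < 1:
            raise DomainError("multistart must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise DomainError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class FitResult:
    """Estimates and diagnostics from one least-squares fit."""

    params: ParamVector
    rss: float
    sigma2: float
    covariance: np.ndarray
    converged: bool
    n_iter: int
    summary: CurveSummary | None
    ci: dict[str, tuple[float, float]]
    n_obs: int
    ci_level: float = 0.95
    singular: bool = False  # covariance was rank-deficient
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.params.params)

    @property
    def se(self) -> dict[str, float]:
        diag = np.sqrt(np.clip(np.diag(self.covariance), 0.0, np.inf))
        return dict(zip(PARAM_NAMES[self.params.form], diag))

    @property
    def aic(self) -> float:
        """Gaussian AIC: n·ln(rss/n) + 2(p+1)."""
        n = self.n_obs
        return n * math.log(max(self.rss, _TINY * _TINY) / n) + 2 * (self.n_params + 1)


def _min_points(form: GrowthForm) -> int:
    return 5 if (form in RICHARDS_FORMS or form in FOUR_PARAM_FORMS) else 4


def initial_guess(series: TimeSeries, form: GrowthForm | str) -> ParamVector:
    """Data-driven starting values, mapped into the target form.

    The asymptote is guessed 5% above the largest observation, the starting
    value from the first positive observation, the inflection time from the
    observation nearest A/e, and the growth coefficient from the slope of
    the double-log transform ln(-ln(W/A)) against time, which is linear with
    slope k_G on an exact Gompertz curve.
    """
    form = coerce_form(form)
    t, w = series.times, series.values
    if len(series) < _min_points(form):
        raise InsufficientDataError(
            f"{form.value} needs at least {_min_points(form)} points, got {len(series)}"
        )
    w_max = float(w.max())
    if w_max <= 0 or np.allclose(w, w[0]):
        raise DegenerateDataError("values are constant or have no positive maximum")

    A0 = 1.05 * w_max
    positive = w[w > 0]
    W00 = float(positive[0])
    T_i0 = float(t[np.argmin(np.abs(w - A0 / _E))])

    # mid-range points carry the slope information; near either asymptote
    # the double-log transform is dominated by the error in A0
    interior = (w > 0.02 * A0) & (w < 0.9 * A0)
    k_G0 = np.nan
    if interior.sum() >= 2:
        z = np.log(-np.log(w[interior] / A0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slope = np.polyfit(t[interior], z, 1)[0]
        k_G0 = -float(slope)  # z decreases at rate k_G
    t_range = float(t[-1] - t[0])
    if not np.isfinite(k_G0) or k_G0 <= 0:
        k_G0 = 2.0 / t_range

    W00 = min(W00, 0.95 * A0)
    B0 = 0.5 * float(w.min()) if form in FOUR_PARAM_FORMS else 0.0
    guess = CurveSummary(
        A=A0,
        W_0=W00,
        T_i=T_i0,
        W_i=A0 / _E,
        k_G=k_G0,
        k_U=k_G0 / _E,
        K_U=A0 * k_G0 / _E,
        d=1.0,
        B=B0,
    )
    return from_summary(guess, form)


def _default_bounds(series: TimeSeries, form: GrowthForm) -> list[tuple[float, float]]:
    t, w = series.times, series.values
    t_range = float(t[-1] - t[0])
    w_max = float(w.max())
    rate_hi = 100.0 / t_range
    time_lo, time_hi = float(t[0] - t_range), float(t[-1] + t_range)
    per_name = {
        "A": (_TINY, 10.0 * w_max),
        "A_scale": (_TINY, 10.0 * w_max),
        "B": (-10.0 * w_max, 10.0 * w_max),
        "W_0": (_TINY, 10.0 * w_max),
        "k_G": (_TINY, rate_hi),
        "k_U": (_TINY, rate_hi),
        "K": (_TINY, rate_hi),
        "k_R": (_TINY, rate_hi),
        "K_U": (_TINY, 10.0 * w_max * rate_hi),
        "K_Z": (_TINY, 10.0 * w_max * rate_hi),
        "T_i": (time_lo, time_hi),
        "T_lag": (time_lo, time_hi),
        "b": (-700.0, 700.0),
        "c": (_TINY, np.inf),
        "m": (_TINY, 200.0),
        "L": (_TINY, 200.0 * rate_hi),
        "d": (0.05, 10.0),
    }
    return [per_name[name] for name in PARAM_NAMES[form]]


def _perturb(
    theta0: np.ndarray,
    names: tuple[str, ...],
    lo: np.ndarray,
    hi: np.ndarray,
    scale_hint: float,
    rng: np.random.Generator,
) -> np.ndarray:
    theta = theta0.copy()
    for i, name in enumerate(names):
        if name in ("T_i", "T_lag", "b", "B"):
            theta[i] = theta0[i] + rng.normal(0.0, 0.3 * scale_hint)
        else:  # positive parameters: +/-30% lognormal
            theta[i] = theta0[i] * math.exp(rng.normal(0.0, 0.3))
    return np.clip(theta, lo + _TINY, hi - _TINY if np.all(np.isfinite(hi)) else hi)


def fit(
    series: TimeSeries,
    form: GrowthForm | str,
    opts: FitOptions | None = None,
) -> FitResult:
    """Least-squares fit of one form to a time series.

    Non-convergence is reported through ``converged=False``, never raised.
    A rank-deficient Jacobian at the optimum sets ``singular=True`` and
    produces infinite interval bounds for the affected parameters.
    """
    form = coerce_form(form)
    opts = opts or FitOptions()
    names = PARAM_NAMES[form]
    n, p = len(series), len(names)
    if n <= p:
        raise InsufficientDataError(
            f"{form.value} has {p} parameters; need more than {p} points, got {n}"
        )
    p0 = initial_guess(series, form)
    theta0 = p0.to_array()
    bounds_list = _default_bounds(series, form)
    if opts.bounds:
        for i, name in enumerate(names):
            if name in opts.bounds:
                bounds_list[i] = opts.bounds[name]
    lo = np.array([b[0] for b in bounds_list])
    hi = np.array([b[1] for b in bounds_list])
    theta0 = np.clip(theta0, lo + _TINY, np.where(np.isfinite(hi), hi - _TINY, hi))

    t, w = series.times, series.values
    if opts.log_response:
        if np.any(w <= 0):
            raise DomainError("log_response requires strictly positive values")
        y = np.log(w)

        def residuals(theta: np.ndarray) -> np.ndarray:
            model = _eval_raw(form, dict(zip(names, theta)), t)
            return np.log(np.maximum(model, 1e-300)) - y

    else:

        def residuals(theta: np.ndarray) -> np.ndarray:
            return _eval_raw(form, dict(zip(names, theta)), t) - w

    rng = np.random.default_rng(opts.seed)
    t_range = float(t[-1] - t[0])
    starts = [theta0]
    for _ in range(opts.multistart - 1):
        starts.append(_perturb(theta0, names, lo, hi, t_range, rng))

    # strictly positive parameters are optimized on the log scale: the
    # W0-forms in particular have starting values orders of magnitude below
    # the asymptote, and log coordinates keep their search direction
    # well conditioned
    logmask = np.array([name in _POSITIVE for name in names])

    def to_internal(theta: np.ndarray) -> np.ndarray:
        return np.where(logmask, np.log(np.maximum(theta, 1e-300)), theta)

    def to_natural(phi: np.ndarray) -> np.ndarray:
        return np.where(logmask, np.exp(phi), phi)

    def residuals_internal(phi: np.ndarray) -> np.ndarray:
        return residuals(to_natural(phi))

    lo_int, hi_int = to_internal(lo), to_internal(hi)

    best = None
    total_nfev = 0
    for start in starts:
        try:
            res = least_squares(
                residuals_internal,
                to_internal(start),
                bounds=(lo_int, hi_int),
                method="trf",
                ftol=opts.tolerance,
                xtol=opts.tolerance,
                gtol=1e-12,
                x_scale="jac",
                max_nfev=opts.max_iterations * (p + 1),
            )
        except Exception:  # pathological start; try the next one
            continue
        total_nfev += res.nfev
        rss = float(2.0 * res.cost)
        if best is None:
            best = (rss, res)
        else:
            best_rss = best[0]
            if rss < best_rss * (1.0 - 1e-12):
                best = (rss, res)
            elif abs(rss - best_rss) <= 1e-12 * max(best_rss, _TINY):
                # deterministic tie-break: smaller parameter norm
                if np.linalg.norm(to_natural(res.x)) < np.linalg.norm(
                    to_natural(best[1].x)
                ):
                    best = (rss, res)

    if best is None:
        params = ParamVector.from_array(form, theta0)
        return FitResult(
            params=params,
            rss=float(np.sum(residuals(theta0) ** 2)),
            sigma2=np.nan,
            covariance=np.full((p, p), np.nan),
            converged=False,
            n_iter=total_nfev,
            summary=None,
            ci={k: (-np.inf, np.inf) for k in names},
            n_obs=n,
            ci_level=opts.ci_level,
            singular=True,
            message="all optimizer starts failed",
        )

    rss, res = best
    theta_hat = to_natural(res.x)
    params = ParamVector.from_array(form, theta_hat)
    sigma2 = rss / (n - p)
    # chain rule back to natural coordinates: d r/d theta = d r/d ln(theta) / theta
    jac_nat = res.jac / np.where(logmask, theta_hat, 1.0)
    jtj = jac_nat.T @ jac_nat
    # judge rank on the correlation-scaled matrix so that parameters of very
    # different magnitudes (W_0 near zero vs A) do not masquerade as rank loss
    diag = np.sqrt(np.diag(jtj))
    ok = diag > 0
    scaled = jtj.copy()
    if ok.any():
        scaled[np.ix_(ok, ok)] = jtj[np.ix_(ok, ok)] / np.outer(diag[ok], diag[ok])
    rank = int(np.linalg.matrix_rank(scaled, tol=1e-12)) if ok.all() else int(ok.sum())
    singular = rank < p
    if singular:
        warnings.warn(
            f"rank-deficient Jacobian ({rank} < {p}) for {form.value}; "
            "covariance is a pseudo-inverse and some intervals are infinite",
            stacklevel=2,
        )
    covariance = sigma2 * np.linalg.pinv(jtj)
    covariance = 0.5 * (covariance + covariance.T)

    try:
        summary = to_summary(params)
    except (DomainError, ValueError):
        summary = None

    result = FitResult(
        params=params,
        rss=rss,
        sigma2=sigma2,
        covariance=covariance,
        converged=bool(res.success),
        n_iter=total_nfev,
        summary=summary,
        ci={},
        n_obs=n,
        ci_level=opts.ci_level,
        singular=singular,
        message=str(res.message),
    )
    return replace(result, ci=confidence_intervals(result, opts.ci_level))


def confidence_intervals(
    r: FitResult, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Per-parameter Wald intervals: estimate ± t_{level, n-p} · SE."""
    if not 0.0 < level < 1.0:
        raise DomainError("level must be in (0, 1)")
    names = PARAM_NAMES[r.params.form]
    dof = max(r.n_obs - r.n_params, 1)
    tq = float(stats.t.ppf(0.5 + level / 2.0, dof))
    out: dict[str, tuple[float, float]] = {}
    diag = np.diag(r.covariance)
    for i, name in enumerate(names):
        est = r.params[name]
        var = diag[i]
        if not np.isfinite(var) or var < 0 or (r.singular and var > 1e30):
            out[name] = (-np.inf, np.inf)
        else:
            half = tq * math.sqrt(var)
            out[name] = (est - half, est + half)
    return out


def fit_all_forms(
    series: TimeSeries,
    forms: list[GrowthForm | str],
    opts: FitOptions | None = None,
):
    """Fit several forms to the same data and tabulate the results.

    Returns a pandas DataFrame with one row per form (native estimates are
    in the attached FitResult objects, ``table.attrs["results"]``); fitting
    failures are recorded in the row's ``error`` column, not raised.  On
    Gompertz-generated data every Gompertz-family row attains the same RSS —
    the forms are coordinates on one model.
    """
    import pandas as pd

    rows = []
    results: dict[str, "FitResult | None"] = {}
    for raw in forms:
        form = coerce_form(raw)
        row: dict[str, object] = {"form": form.value}
        try:
            r = fit(series, form, opts)
            results[form.value] = r
            s = r.summary
            row.update(
                converged=r.converged,
                rss=r.rss,
                aic=r.aic,
                A=s.A if s else np.nan,
                W_0=s.W_0 if s else np.nan,
                T_i=s.T_i if s else np.nan,
                k_U=s.k_U if s else np.nan,
                K_U=s.K_U if s else np.nan,
                k_G=s.k_G if s else np.nan,
                d=s.d if s else np.nan,
                error="",
            )
        except Exception as exc:
            results[form.value] = None
            row.update(
                converged=False,
                rss=np.nan,
                aic=np.nan,
                A=np.nan,
                W_0=np.nan,
                T_i=np.nan,
                k_U=np.nan,
                K_U=np.nan,
                k_G=np.nan,
                d=np.nan,
                error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(row)
    columns = [
        "form", "converged", "rss", "aic",
        "A", "W_0", "T_i", "k_U", "K_U", "k_G", "d", "error",
    ]
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["results"] = results
    return table
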