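import numpy as np
import pytest

import growthfit as gf

#: The reference parameter set used throughout: upper asymptote 10.0,
#: maximum absolute growth rate 1.5 (so k_G = 1.5 in the traditional
#: Ti-form), inflection at t = 2.
REF = {"A": 10.0, "k_G": 1.5, "T_i": 2.0}


@pytest.fixture
def ref_ti() -> gf.ParamVector:
    return gf.ParamVector(gf.GrowthForm.GOMPERTZ_TI, REF)


@pytest.fixture
def ref_summary(ref_ti) -> gf.CurveSummary:
    return gf.to_summary(ref_ti)


@pytest.fixture
def design() -> gf.Design:
    return gf.Design(t_start=0.0, t_end=8.0, n_points=50)


@pytest.fixture
def noiseless_series(ref_ti, design) -> gf.TimeSeries:
    return gf.simulate_series(ref_ti, design)


def truth_in_form(summary: gf.CurveSummary, form: gf.GrowthForm) -> gf.ParamVector:
    """The reference curve expressed in ``form`` (d=1.3 for Richards forms,
    B=2 for four-parameter forms so every parameter is well identified)."""
    if form in gf.forms.RICHARDS_FORMS:
        return gf.from_summary(summary.replace(d=1.3), form)
    if form in gf.forms.FOUR_PARAM_FORMS:
        return gf.from_summary(summary.replace(B=2.0), form)
    return gf.from_summary(summary, form)


def random_gompertz_summary(rng: np.random.Generator) -> gf.CurveSummary:
    """A random well-scaled Gompertz curve summary (B=0, d=1)."""
    A = rng.uniform(0.5, 50.0)
    k_G = rng.uniform(0.2, 4.0)
    # keep k_G·T_i modest so W_0 = A·exp(-exp(k_G·T_i)) stays representable
    T_i = rng.uniform(-1.0, min(6.0, 5.0 / k_G))
    return gf.CurveSummary(
        A=A,
        W_0=gf.w0_from_ti(A, k_G / np.e, T_i),
        T_i=T_i,
        W_i=A / np.e,
        k_G=k_G,
        k_U=k_G / np.e,
        K_U=A * k_G / np.e,
        d=1.0,
        B=0.0,
    )
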