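"""Conversions between forms, the unified summary, and derived rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import growthfit as gf
from growthfit.errors import DomainError, UnsupportedFormError

from conftest import REF, random_gompertz_summary, truth_in_form

E = math.e
ALL_FORMS = list(gf.GrowthForm)


class TestToSummary:
    def test_c_parameter_identity(self):
        # T_i = ln(c)/k_G
        p = gf.ParamVector("gompertz-c", {"A": 10, "k_G": 1.5, "c": math.exp(3)})
        assert gf.to_summary(p).T_i == pytest.approx(2.0, rel=1e-12)

    def test_b_parameter_identity(self):
        # T_i = b/k_G
        p = gf.ParamVector("gompertz-b", {"A": 10, "k_G": 1.5, "b": 3.0})
        assert gf.to_summary(p).T_i == pytest.approx(2.0, rel=1e-12)

    def test_laird_asymptote(self):
        # A = W_0·exp(L/K); cross-checked by evaluating the curve far out
        p = gf.ParamVector("laird", {"W_0": 1, "L": 3.45388, "K": 1.5})
        s = gf.to_summary(p)
        assert s.A == pytest.approx(10.0, rel=1e-5)
        assert s.A == pytest.approx(gf.evaluate(p, 1e4), rel=1e-12)

    def test_zweifel_lasker_asymptote(self):
        # A = W_0·exp(m)
        p = gf.ParamVector("zweifel-lasker", {"W_0": 1, "m": 2.302585, "k_G": 1.5})
        assert gf.to_summary(p).A == pytest.approx(math.exp(2.302585), rel=1e-12)
        assert gf.to_summary(p).A == pytest.approx(10.0, rel=1e-6)

    def test_unified_rate_identities(self):
        # k_G = e·k_U and K_U = A·k_U
        p = gf.ParamVector("u-gompertz-ti", {"A": 10, "k_U": 0.15, "T_i": 2})
        s = gf.to_summary(p)
        assert s.k_G == pytest.approx(E * 0.15, rel=1e-12)
        assert s.K_U == pytest.approx(1.5, rel=1e-12)

    def test_zwietering_mapping(self):
        # k_U = K_Z/A; T_i = T_lag + A/(e·K_Z)
        p = gf.ParamVector("zwietering", {"A": 10, "K_Z": 1.5, "T_lag": 3})
        s = gf.to_summary(p)
        assert s.k_U == pytest.approx(0.15, rel=1e-12)
        assert s.T_i == pytest.approx(3 + 10 / (E * 1.5), rel=1e-12)

    def test_negative_inflection_time_is_flagged(self):
        # Laird fits to late-stage data can place the inflection before t=0
        p = gf.ParamVector("laird", {"W_0": 5, "L": 0.5, "K": 1.5})  # L < K
        s = gf.to_summary(p)
        assert s.T_i < 0
        assert s.past_inflection_at_start


class TestFromSummary:
    def test_b_target(self, ref_summary):
        p = gf.from_summary(ref_summary, "gompertz-b")
        assert p["b"] == pytest.approx(3.0, rel=1e-12)
        assert p["A"] == 10.0 and p["k_G"] == 1.5

    def test_reference_set_as_absolute_rate_form(self, ref_summary):
        # A=10.0, max absolute rate 1.5, inflection at 2.0
        p = gf.from_summary(
            gf.to_summary(
                gf.ParamVector("u-gompertz-abs-ti", {"A": 10.0, "K_U": 1.5, "T_i": 2.0})
            ),
            "u-gompertz-abs-ti",
        )
        assert p["A"] == pytest.approx(10.0)
        assert p["K_U"] == pytest.approx(1.5)
        assert p["T_i"] == pytest.approx(2.0)

    def test_four_param_requires_known_lower_asymptote(self, ref_summary):
        s = ref_summary.replace(B=None)
        with pytest.raises(UnsupportedFormError):
            gf.from_summary(s, "four-param-compressed")

    def test_three_param_rejects_nonzero_lower_asymptote(self, ref_summary):
        s = ref_summary.replace(B=2.0)
        with pytest.raises(UnsupportedFormError):
            gf.from_summary(s, "gompertz-ti")

    def test_gompertz_target_rejects_richards_shape(self, ref_summary):
        s = ref_summary.replace(d=2.0)
        with pytest.raises(UnsupportedFormError):
            gf.from_summary(s, "u-gompertz-ti")

    def test_round_trip_all_targets(self):
        # summary -> form -> summary reproduces the shared fields
        rng = np.random.default_rng(123)
        for _ in range(20):
            s = random_gompertz_summary(rng)
            for form in ALL_FORMS:
                p = truth_in_form(s, form)
                back = gf.to_summary(p)
                assert back.A == pytest.approx(s.A, rel=1e-10)
                assert back.T_i == pytest.approx(s.T_i, rel=1e-9, abs=1e-9)
                assert back.k_G == pytest.approx(s.k_G, rel=1e-10)
                if form not in gf.forms.FOUR_PARAM_FORMS:
                    # with B=0 the rate identities are form-independent
                    assert back.k_U == pytest.approx(s.k_U, rel=1e-10)
                    assert back.K_U == pytest.approx(s.K_U, rel=1e-10)
                if form not in gf.forms.FOUR_PARAM_FORMS | gf.forms.RICHARDS_FORMS:
                    # d=1.3 Richards truths share A/k_U/T_i but not W(0)
                    assert back.W_0 == pytest.approx(s.W_0, rel=1e-9, abs=1e-200)
                assert back.W_0 == pytest.approx(
                    gf.evaluate(p, 0.0), rel=1e-12, abs=1e-300
                )

    def test_curve_preservation_across_all_pairs(self):
        # f -> summary -> g traces the same curve to 1e-9·A in sup norm
        rng = np.random.default_rng(7)
        three_param = [
            f
            for f in ALL_FORMS
            if f not in gf.forms.FOUR_PARAM_FORMS
        ]
        for _ in range(5):
            s = random_gompertz_summary(rng)
            grid = np.linspace(s.T_i - 5 / s.k_U, s.T_i + 5 / s.k_U, 200)
            curves = {}
            for form in three_param:
                p = truth_in_form(s, form)
                # Richards truths here use d=1.3, a genuinely different curve
                if form in gf.forms.RICHARDS_FORMS:
                    continue
                curves[form] = np.asarray(gf.evaluate(p, grid))
            ref = curves[gf.GrowthForm.GOMPERTZ_TI]
            for form, w in curves.items():
                assert np.max(np.abs(w - ref)) < 1e-9 * s.A, form.value

    def test_richards_group_curve_preservation(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = random_gompertz_summary(rng).replace(d=1.7)
            grid = np.linspace(s.T_i - 5 / s.k_U, s.T_i + 5 / s.k_U, 200)
            reference = None
            for form in gf.forms.RICHARDS_FORMS:
                w = np.asarray(gf.evaluate(gf.from_summary(s, form), grid))
                if reference is None:
                    reference = w
                else:
                    assert np.max(np.abs(w - reference)) < 1e-9 * s.A, form.value


class TestW0TiBridge:
    def test_reference_starting_value(self):
        # A=10, k_U=0.15, T_i=2 -> W_0 = 1.0432... (rounds to 1.0)
        w0 = gf.w0_from_ti(10.0, 0.15, 2.0)
        assert w0 == pytest.approx(1.0432224946910118, rel=1e-12)
        assert round(w0, 1) == 1.0

    def test_inflection_on_y_axis(self):
        assert gf.w0_from_ti(10.0, 0.7, 0.0) == pytest.approx(10 / E, rel=1e-12)
        assert gf.ti_from_w0(10.0, 0.7, 10 / E) == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_reference(self):
        assert gf.ti_from_w0(10.0, 0.15, gf.w0_from_ti(10.0, 0.15, 2.0)) == pytest.approx(
            2.0, rel=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        A=st.floats(0.1, 1000),
        k_U=st.floats(0.01, 10),
        frac=st.floats(1e-6, 1 - 1e-6),
    )
    def test_mutual_inverses(self, A, k_U, frac):
        W_0 = frac * A
        t = gf.ti_from_w0(A, k_U, W_0)
        assert gf.w0_from_ti(A, k_U, t) == pytest.approx(W_0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            gf.ti_from_w0(10.0, 0.5, 10.0)  # W_0 = A: log of zero
        with pytest.raises(DomainError):
            gf.ti_from_w0(10.0, 0.5, 0.0)
        with pytest.raises(DomainError):
            gf.w0_from_ti(-1.0, 0.5, 1.0)

    def test_w0_matches_curve_at_origin(self):
        p = gf.ParamVector("u-gompertz-ti", {"A": 10, "k_U": 0.15, "T_i": 2})
        assert gf.w0_from_ti(10, 0.15, 2) == pytest.approx(gf.evaluate(p, 0.0), rel=1e-12)


class TestRates:
    def test_zweifel_lasker_initial_rates(self):
        # absolute W_0·k_G·m; relative k_G·m/exp(m)
        p = gf.ParamVector("zweifel-lasker", {"W_0": 1, "m": 2.302585, "k_G": 1.5})
        rates = gf.initial_rates(p)
        assert rates["absolute"] == pytest.approx(1 * 1.5 * 2.302585, rel=1e-12)
        assert rates["relative"] == pytest.approx(
            1.5 * 2.302585 / math.exp(2.302585), rel=1e-12
        )

    def test_laird_initial_rate(self):
        p = gf.ParamVector("laird", {"W_0": 2, "L": 3, "K": 1})
        assert gf.initial_rates(p)["absolute"] == pytest.approx(6.0, rel=1e-12)

    def test_initial_matches_derivative_all_forms(self, ref_summary):
        for form in ALL_FORMS:
            p = truth_in_form(ref_summary, form)
            assert gf.initial_rates(p)["absolute"] == pytest.approx(
                gf.derivative(p, 0.0, 1), rel=1e-10, abs=1e-300
            )

    def test_max_rates_reference(self, ref_ti):
        rates = gf.max_rates(ref_ti)
        assert rates["k_U"] == pytest.approx(1.5 / E, rel=1e-12)
        assert rates["K_U"] == pytest.approx(5.518191617571635, rel=1e-12)

    def test_zwietering_coefficient_is_max_absolute_rate(self):
        p = gf.ParamVector("zwietering", {"A": 10, "K_Z": 1.5, "T_lag": 0})
        assert gf.max_rates(p)["K_U"] == pytest.approx(1.5, rel=1e-12)

    def test_ku_relation_exact_all_forms(self, ref_summary):
        for form in ALL_FORMS:
            p = truth_in_form(ref_summary, form)
            rates = gf.max_rates(p)
            s = gf.to_summary(p)
            assert rates["K_U"] == s.A * rates["k_U"]

    def test_max_rate_matches_grid_argmax(self, ref_summary):
        for form in ALL_FORMS:
            p = truth_in_form(ref_summary, form)
            s = gf.to_summary(p)
            t = np.linspace(s.T_i - 6 / s.k_G, s.T_i + 6 / s.k_G, 400001)
            slope_max = np.max(np.gradient(np.asarray(gf.evaluate(p, t)), t))
            assert gf.max_rates(p)["K_U"] == pytest.approx(slope_max, rel=1e-4)


class TestRichardsShape:
    def test_logistic_inflection_at_half_asymptote(self):
        assert gf.richards_inflection_value(10.0, 2.0) == pytest.approx(5.0, rel=1e-12)

    def test_von_bertalanffy_inflection(self):
        assert gf.richards_inflection_value(27.0, 2 / 3) == pytest.approx(8.0, rel=1e-12)

    def test_continuous_at_gompertz_limit(self):
        for d in (1 + 1e-6, 1 - 1e-6):
            assert abs(gf.richards_inflection_value(10.0, d) - 10 / E) < 1e-5 * 10

    @pytest.mark.parametrize("d", [2.0, 2 / 3])
    def test_matches_grid_argmax_of_slope(self, d):
        p = gf.ParamVector("u-richards-ti", {"A": 10, "k_U": 0.4, "T_i": 2, "d": d})
        t = np.linspace(-20, 25, 400001)
        w = np.asarray(gf.evaluate(p, t))
        w_at_max_slope = w[np.argmax(np.gradient(w, t))]
        assert gf.richards_inflection_value(10.0, d) == pytest.approx(
            w_at_max_slope, rel=1e-4
        )
        assert gf.inflection(p).W_i == pytest.approx(w_at_max_slope, rel=1e-4)

    @pytest.mark.parametrize(
        "d, label",
        [
            (2.0, "logistic"),
            (2 / 3, "von Bertalanffy"),
            (1.0, "Gompertz (limit)"),
            (1.37, "Richards"),
        ],
    )
    def test_special_case_labels(self, d, label):
        assert gf.special_case_of(d) == label


class TestW0ParameterKinds:
    """Type IIa vs IIb: W_0 as location vs shape parameter."""

    def test_location_forms_keep_asymptote(self):
        # gompertz-w0 / u-gompertz-w0: changing W_0 shifts the curve along
        # the time axis; the asymptote A is untouched
        for form, key in [("gompertz-w0", "k_G"), ("u-gompertz-w0", "k_U")]:
            base = gf.ParamVector(form, {"A": 10, key: 0.8, "W_0": 1.0})
            moved = base.replace(W_0=2.5)
            assert gf.to_summary(base).A == gf.to_summary(moved).A == 10.0

    @pytest.mark.parametrize(
        "form, params",
        [
            ("zweifel-lasker", {"W_0": 1.0, "m": 2.3, "k_G": 1.5}),
            ("laird", {"W_0": 1.0, "L": 3.45, "K": 1.5}),
        ],
    )
    def test_shape_forms_rescale_asymptote_proportionally(self, form, params):
        base = gf.ParamVector(form, params)
        scaled = base.replace(W_0=2.5)
        ratio = gf.to_summary(scaled).A / gf.to_summary(base).A
        assert ratio == pytest.approx(2.5 / 1.0, rel=1e-12)
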