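"""Closed-form model evaluation against analytic limits and the ODE oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from photokinetics import (
    BiexpParams,
    ConversionParams,
    DegenerateParametersError,
    InvalidParameterError,
    InvalidSchemeError,
    KineticScheme,
    MonoexpParams,
    NormalizationUndefinedError,
    eval_biexp,
    eval_photoconversion,
    eval_relaxation,
    halflife,
    integrate_scheme,
    normalized_trace,
)

T600 = np.linspace(0.0, 600.0, 601)


def green_red_bleached(amp, k1, k2):
    return KineticScheme(
        states=("Green", "Red", "Bleached"),
        transitions=(("Green", "Red", k1), ("Red", "Bleached", k2)),
        initial_populations={"Green": amp},
        observable={"Red": 1.0},
    )


class TestPhotoconversion:
    def test_zero_at_t0_and_plateau_at_background(self):
        p = ConversionParams(1.0, 0.011, 0.002, c=0.25)
        y = eval_photoconversion(p, [0.0, 1e7])
        assert y[0] == pytest.approx(0.25)
        assert y[1] == pytest.approx(0.25, abs=1e-12)

    def test_output_never_below_background(self):
        p = ConversionParams(1.3, 0.011, 0.002, c=0.1)
        assert np.all(eval_photoconversion(p, T600) >= 0.1 - 1e-12)

    def test_matches_ode_oracle_at_measured_rates(self):
        # consecutive-reaction curve equals the integrated scheme observable
        p = ConversionParams(1.0, 0.011, 0.002, 0.0)
        y = eval_photoconversion(p, T600)
        res = integrate_scheme(green_red_bleached(1.0, 0.011, 0.002), T600)
        assert np.allclose(res.observable, y, rtol=1e-6, atol=1e-9 * y.max())

    def test_oracle_equivalence_random_rate_pairs(self, rng):
        for _ in range(20):
            k1, k2 = rng.uniform(1e-4, 1e-1, size=2)
            if abs(k1 - k2) < 1e-6:
                continue
            t = np.linspace(0.0, 5.0 / max(k1, k2), 201)
            p = ConversionParams(1.0, k1, k2, 0.0)
            y = eval_photoconversion(p, t)
            res = integrate_scheme(green_red_bleached(1.0, k1, k2), t)
            assert np.allclose(res.observable, y, rtol=1e-6, atol=1e-8 * y.max())

    def test_no_destruction_limit_plateaus_at_amplitude(self):
        p = ConversionParams(2.0, 0.011, 1e-9, c=0.5)
        assert eval_photoconversion(p, [1e6])[0] == pytest.approx(2.5, rel=1e-3)

    def test_equal_rates_error_and_explicit_limit(self):
        p = ConversionParams(1.0, 0.01, 0.01, 0.0)
        with pytest.raises(DegenerateParametersError):
            eval_photoconversion(p, T600)
        y_lim = eval_photoconversion(p, T600, allow_equal_rates=True)
        expected = 1.0 * 0.01 * T600 * np.exp(-0.01 * T600)
        assert np.allclose(y_lim, expected)
        # limit is continuous: nearby distinct rates give nearly the same curve
        y_near = eval_photoconversion(ConversionParams(1.0, 0.01, 0.0100001, 0.0), T600)
        assert np.allclose(y_lim, y_near, rtol=1e-3, atol=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ConversionParams(1.0, np.nan, 0.002, 0.0)
        with pytest.raises(InvalidParameterError):
            ConversionParams(1.0, -0.01, 0.002, 0.0)


class TestBiexp:
    def test_single_exponential_reduction_at_t0(self):
        p = BiexpParams(1.0, 0.0055, 0.0, 0.0055, 0.0, opposed=True)
        assert eval_biexp(p, [0.0])[0] == pytest.approx(1.0)

    def test_exact_cancellation_of_equal_components(self):
        p = BiexpParams(0.7, 0.003, 0.7, 0.003, c=0.2, opposed=True)
        assert np.allclose(eval_biexp(p, T600), 0.2)

    def test_first_cycle_curve_monotone_when_fast_term_small(self):
        # dI/dt(0) = -I1 k1 + I2 k2; 0.27*0.0098 < 1*0.0055 -> decreasing
        p = BiexpParams(1.0, 0.0055, 0.27, 0.0098, 0.0, opposed=True)
        y = eval_biexp(p, T600)
        assert np.all(np.diff(y) < 0)

    @given(
        i1=st.floats(0.0, 5.0),
        i2=st.floats(0.0, 5.0),
        k1=st.floats(1e-4, 0.1),
        k2=st.floats(1e-4, 0.1),
        c=st.floats(0.0, 1.0),
    )
    def test_same_sign_curve_never_increases(self, i1, i2, k1, k2, c):
        p = BiexpParams(i1, k1, i2, k2, c, opposed=False)
        y = eval_biexp(p, np.linspace(0.0, 600.0, 121))
        assert np.all(np.diff(y) <= 1e-12)


class TestRelaxation:
    def test_starts_at_offset_and_saturates_at_amplitude(self):
        p = MonoexpParams(1.0, 0.0179, 0.0)
        y = eval_relaxation(p, [0.0, 1e6])
        assert y[0] == pytest.approx(0.0)
        assert y[1] == pytest.approx(1.0)

    def test_monotone_rise(self):
        y = eval_relaxation(MonoexpParams(2.0, 0.005, 0.1), T600)
        assert np.all(np.diff(y) > 0)

    def test_half_rise_time_is_halflife(self):
        # A0/2 reached at ln2/k ~ 38.7 s for the fastest-relaxing variant
        k = 0.0179
        t_half = halflife(k)
        assert t_half == pytest.approx(38.72, abs=0.01)
        y = eval_relaxation(MonoexpParams(1.0, k, 0.0), [t_half])
        assert y[0] == pytest.approx(0.5, abs=1e-12)


class TestScheme:
    def test_empty_transitions_keep_populations_constant(self):
        s = KineticScheme(("A", "B"), (), {"A": 0.4, "B": 0.6}, {"A": 1.0})
        res = integrate_scheme(s, np.linspace(0, 100, 11))
        assert np.allclose(res.population("A"), 0.4, atol=1e-9)
        assert np.allclose(res.population("B"), 0.6, atol=1e-9)

    def test_two_state_reversible_reaches_detailed_balance(self):
        kon, koff = 0.02, 0.005
        s = KineticScheme(
            ("On", "Off"),
            (("On", "Off", kon), ("Off", "On", koff)),
            {"On": 1.0},
            {"On": 1.0},
        )
        res = integrate_scheme(s, np.linspace(0, 5000, 101))
        assert res.population("On")[-1] == pytest.approx(koff / (kon + koff), rel=1e-5)

    def test_mass_conserved_in_closed_schemes(self, rng):
        for _ in range(10):
            rates = rng.uniform(1e-4, 0.05, size=4)
            s = KineticScheme(
                ("On", "Off", "OxOn", "OxOff"),
                (
                    ("On", "Off", rates[0]),
                    ("On", "OxOn", rates[1]),
                    ("OxOn", "OxOff", rates[2]),
                    ("Off", "On", rates[3]),
                ),
                {"On": 1.0},
                {"On": 1.0, "OxOn": 0.6},
            )
            res = integrate_scheme(s, np.linspace(0, 600, 61))
            total = res.populations.sum(axis=0)
            assert np.allclose(total, 1.0, rtol=1e-8)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidSchemeError):
            KineticScheme(("A", "B"), (("A", "B", -0.1),), {"A": 1.0})

    def test_unknown_state_rejected(self):
        with pytest.raises(InvalidSchemeError):
            KineticScheme(("A",), (("A", "B", 0.1),), {"A": 1.0})


class TestNormalization:
    def test_reported_divisor_value(self):
        # I*(k1-k2)/k1 = (0.011-0.002)/0.011 = 9/11
        p = ConversionParams(1.0, 0.011, 0.002, 0.0)
        out = normalized_trace(p, np.array([9.0 / 11.0]))
        assert out[0] == pytest.approx(1.0)

    def test_no_destruction_reduces_to_amplitude(self):
        p = ConversionParams(2.0, 0.011, 0.0, 0.0)
        out = normalized_trace(p, np.array([2.0]))
        assert out[0] == pytest.approx(1.0)

    def test_zero_trace_stays_zero(self):
        p = ConversionParams(1.0, 0.011, 0.002, 0.0)
        assert np.all(normalized_trace(p, np.zeros(5)) == 0.0)

    def test_noise_free_curve_bounded_by_one(self):
        p = ConversionParams(1.0, 0.011, 0.002, 0.0)
        y = eval_photoconversion(p, T600)
        assert normalized_trace(p, y).max() <= 1.0 + 1e-9

    def test_destruction_faster_than_formation_is_undefined(self):
        p = ConversionParams(1.0, 0.002, 0.011, 0.0)
        with pytest.raises(NormalizationUndefinedError):
            normalized_trace(p, np.ones(4))
        # plateau normalisation stays available for that regime
        out = normalized_trace(p, np.ones(4), mode="plateau")
        assert np.allclose(out, 1.0)


class TestHalflife:
    def test_fifty_minutes_at_thermal_recovery_rate(self):
        assert halflife(np.log(2) / 3000.0) == pytest.approx(3000.0)  # 50 min

    def test_unit_rate(self):
        assert halflife(np.log(2)) == pytest.approx(1.0)

    def test_nonpositive_rate_invalid(self):
        with pytest.raises(InvalidParameterError):
            halflife(0.0)
        with pytest.raises(InvalidParameterError):
            halflife(-1.0)
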