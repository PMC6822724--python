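import cmath
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sappa.core import (
    FeedbackMode,
    OscillatorParams,
    StimulusKind,
    StimulusSpec,
    carrier,
    musician_params,
    nonmusician_params,
    profile_params,
    sappa_derivative,
    stimulus_input,
)
from sappa.errors import ConfigError, DegenerateInputError, SingularDenominatorError

TWO_PI = 2 * math.pi

finite_complex = st.builds(
    complex,
    st.floats(-1.5, 1.5, allow_nan=False),
    st.floats(-1.5, 1.5, allow_nan=False),
)


class TestOscillatorParams:
    def test_profile_presets(self):
        m = musician_params()
        n = nonmusician_params()
        for p in (m, n):
            assert p.alpha == 1.0 and p.beta1 == -1.0
            assert p.beta2 == 0.0 and p.epsilon == 0.0
            assert p.tau == 0.222 and p.A == -0.5
        assert m.D == 0.05 and n.D == 0.36
        assert profile_params("musician").D == m.D

    @pytest.mark.parametrize(
        "kwargs", [dict(f=0.0), dict(f=-1.0), dict(tau=-0.1), dict(D=-0.2)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            OscillatorParams(**kwargs)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigError):
            profile_params("virtuoso")


class TestDerivative:
    def test_origin_is_equilibrium_of_unforced_system(self):
        p = OscillatorParams(f=1.3, D=0.4, tau=0.2)
        assert sappa_derivative(0j, 0j, 0j, p) == 0j

    def test_pure_rotation_on_limit_cycle(self):
        # alpha + beta1*|z|^2 cancels at |z| = 1, leaving i*2*pi rotation.
        p = OscillatorParams(f=1.0, D=0.0, tau=0.0)
        d = sappa_derivative(1 + 0j, 0j, 0j, p)
        assert d == pytest.approx(1j * TWO_PI)

    def test_hand_evaluated_example(self):
        # 0.5*(0.75 + i*2*pi) + 1, halved by f, minus 0.36*i.
        p = OscillatorParams(f=0.5, D=0.36, tau=0.1)
        d = sappa_derivative(0.5 + 0j, 1j, 1 + 0j, p)
        assert d.real == pytest.approx(0.6875, abs=1e-12)
        assert d.imag == pytest.approx(1.2107963267948966, abs=1e-12)

    def test_detuning_scales_local_terms_not_delayed_feedback(self):
        p0 = OscillatorParams(f=1.0, D=0.5, tau=0.2, delta=0.0)
        p1 = OscillatorParams(f=1.0, D=0.5, tau=0.2, delta=0.25)
        z, zd, F = 0.3 + 0.4j, 0.1 - 0.2j, 0.8 + 0j
        local0 = sappa_derivative(z, zd, F, p0) + p0.D * zd
        local1 = sappa_derivative(z, zd, F, p1) + p1.D * zd
        assert local1 == pytest.approx(local0 * 1.25)

    def test_singular_denominator_raises(self):
        p = OscillatorParams(f=1.0, epsilon=1.0, beta2=1.0)
        with pytest.raises(SingularDenominatorError):
            sappa_derivative(1.2 + 0j, 0j, 0j, p)

    @given(F1=finite_complex, F2=finite_complex, a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_linearity_in_input(self, F1, F2, a, b):
        p = OscillatorParams(f=0.7, D=0.3, tau=0.1)
        z, zd = 0.4 - 0.3j, 0.2 + 0.1j
        lhs = sappa_derivative(z, zd, a * F1 + b * F2, p)
        base = sappa_derivative(z, zd, 0j, p)
        rhs = (
            a * (sappa_derivative(z, zd, F1, p) - base)
            + b * (sappa_derivative(z, zd, F2, p) - base)
            + base
        )
        assert cmath.isclose(lhs, rhs, rel_tol=1e-12, abs_tol=1e-12)

    @given(d1=finite_complex, d2=finite_complex, a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_linearity_in_delayed_state(self, d1, d2, a, b):
        p = OscillatorParams(f=0.7, D=0.3, tau=0.1)
        z, F = 0.4 - 0.3j, 0.5 + 0.5j
        lhs = sappa_derivative(z, a * d1 + b * d2, F, p)
        base = sappa_derivative(z, 0j, F, p)
        rhs = (
            a * (sappa_derivative(z, d1, F, p) - base)
            + b * (sappa_derivative(z, d2, F, p) - base)
            + base
        )
        assert cmath.isclose(lhs, rhs, rel_tol=1e-12, abs_tol=1e-12)


class TestStimulusInput:
    def test_sinusoid_at_zero_phase(self):
        spec = StimulusSpec(kind=StimulusKind.SINUSOID, fs=1.0)
        assert stimulus_input(0.0, spec, 0j, -0.5) == pytest.approx(1 + 0j)

    def test_combined_input_reduces_to_carrier_at_zero_state(self):
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=FeedbackMode.CONSTANT_SELF
        )
        assert stimulus_input(0.0, spec, 0j, -0.5) == pytest.approx(1 + 0j)

    def test_combined_input_hand_example(self):
        # (1 - 0.5i)/|1 - 0.5i| at t=0 with z = i and A = -0.5.
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=FeedbackMode.CONSTANT_SELF
        )
        F = stimulus_input(0.0, spec, 1j, -0.5)
        assert F.real == pytest.approx(2 / math.sqrt(5))
        assert F.imag == pytest.approx(-1 / math.sqrt(5))

    def test_antiphase_carrier_is_negated_sinusoid(self):
        s1 = StimulusSpec(kind=StimulusKind.SINUSOID, fs=0.8)
        s2 = StimulusSpec(kind=StimulusKind.ANTIPHASE_SINUSOID, fs=0.8)
        for t in (0.0, 0.3, 1.7):
            assert carrier(t, s2) == pytest.approx(-carrier(t, s1))

    def test_square_wave_peak_aligned_with_sinusoid(self):
        spec = StimulusSpec(kind=StimulusKind.SQUARE_WAVE, fs=1.0)
        assert stimulus_input(0.0, spec, 0j, -0.5) == 1 + 0j
        assert stimulus_input(0.5, spec, 0j, -0.5) == -1 + 0j
        assert stimulus_input(0.3, spec, 0j, -0.5).imag == 0.0

    @given(
        t=st.floats(0, 10, allow_nan=False),
        z=finite_complex,
        fs=st.floats(0.2, 3.0),
    )
    def test_normalized_input_has_unit_magnitude(self, t, z, fs):
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID, fs=fs, feedback_mode=FeedbackMode.CONSTANT_SELF
        )
        try:
            F = stimulus_input(t, spec, z, -0.5)
        except DegenerateInputError:
            return
        assert abs(F) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_normalization_raises(self):
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=FeedbackMode.CONSTANT_SELF
        )
        # A*z exactly cancels the unit carrier at t = 0.
        with pytest.raises(DegenerateInputError):
            stimulus_input(0.0, spec, -2 + 0j, 0.5)

    @given(t=st.floats(0, 8, allow_nan=False), z=finite_complex)
    def test_half_cycle_matches_carrier_then_combined(self, t, z):
        fs = 1.0
        base = StimulusSpec(kind=StimulusKind.SINUSOID, fs=fs)
        half = base.with_feedback(FeedbackMode.HALF_CYCLE_SELF)
        full = base.with_feedback(FeedbackMode.CONSTANT_SELF)
        got = None
        try:
            got = stimulus_input(t, half, z, -0.5)
            want = (
                stimulus_input(t, base, z, -0.5)
                if (fs * t) % 1.0 < 0.5
                else stimulus_input(t, full, z, -0.5)
            )
        except DegenerateInputError:
            return
        assert got == want

    def test_duet_alternation_toggles_twice_per_period(self):
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID,
            fs=1.0,
            feedback_mode=FeedbackMode.DUET_ALTERNATING,
            normalize=False,
        )
        z_self, z_partner = 0.5 + 0j, 0j
        # Self slot in the first half-cycle, partner slot in the second.
        feedback = [
            stimulus_input(t, spec, z_self, -0.5, z_partner=z_partner)
            - carrier(t, spec)
            for t in np.arange(0.0, 2.0, 0.125)
        ]
        slots = [abs(f) > 1e-12 for f in feedback]
        assert slots == [True] * 4 + [False] * 4 + [True] * 4 + [False] * 4

    def test_turn_taking_roles(self):
        spec = StimulusSpec(
            kind=StimulusKind.NONE, feedback_mode=FeedbackMode.TURN_TAKING
        )
        z_self, z_partner = 0.3 + 0.1j, -0.2 + 0.5j
        active = stimulus_input(0.0, spec, z_self, -0.5, z_partner=z_partner, active=True)
        passive = stimulus_input(0.0, spec, z_self, -0.5, z_partner=z_partner, active=False)
        assert active == -0.5 * z_self
        assert passive == z_partner

    def test_partner_required_for_coupled_modes(self):
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=FeedbackMode.DUET_ALTERNATING
        )
        with pytest.raises(ConfigError):
            stimulus_input(0.0, spec, 0.1 + 0j, -0.5)

    def test_latency_only_valid_for_turn_taking(self):
        with pytest.raises(ConfigError):
            StimulusSpec(kind=StimulusKind.SINUSOID, fs=1.0, tl=0.05)
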