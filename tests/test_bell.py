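"""Bell ramp kinetics: closed forms vs quadrature, mode, exact sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest

from g4tweezers import (
    BellState,
    DEFAULT_PROTOCOL,
    RampProtocol,
    hazard,
    modal_force,
    ramp_pdf,
    ramp_survival,
    sample_force,
    state_from_modal_force,
)

STATE = BellState(k_unfold=1e-5, dx=1.0, step_nt=16, label="full")


class TestHazard:
    def test_zero_force_gives_k_unfold(self):
        assert hazard(0.0, STATE) == pytest.approx(1e-5)

    def test_arithmetic_example(self):
        # exponent F*dx/kBT = 41.1/4.11 = 10
        assert hazard(41.1, STATE, kBT=4.11) == pytest.approx(1e-5 * np.e**10, rel=1e-12)

    def test_log_linear_in_force(self):
        f = np.linspace(0, 60, 20)
        logk = np.log(hazard(f, STATE, kBT=4.11))
        slopes = np.diff(logk) / np.diff(f)
        assert np.allclose(slopes, STATE.dx / 4.11)


class TestRampSurvival:
    def test_one_at_ramp_start(self):
        assert ramp_survival(DEFAULT_PROTOCOL.f_start, STATE, DEFAULT_PROTOCOL) == 1.0

    @pytest.mark.parametrize("dx", [0.7, 1.0, 1.2])
    @pytest.mark.parametrize("k0", [1e-6, 1e-4, 1e-2])
    def test_matches_hazard_quadrature(self, k0, dx):
        """Closed form equals exp(-Integral k(f)/r df) to 1e-10 relative."""
        state = BellState(k_unfold=k0, dx=dx)
        proto = DEFAULT_PROTOCOL
        for force in (10.0, 25.0, 40.0, 55.0):
            integral, _ = quad(
                lambda f: hazard(f, state, proto.kBT) / proto.loading_rate,
                proto.f_start,
                force,
                epsabs=1e-14,
                epsrel=1e-13,
            )
            closed = ramp_survival(force, state, proto)
            assert closed == pytest.approx(np.exp(-integral), rel=1e-10)

    def test_vanishing_rate_means_certain_survival(self):
        state = BellState(k_unfold=1e-300, dx=1.0)
        assert ramp_survival(60.0, state, DEFAULT_PROTOCOL) == pytest.approx(1.0)

    def test_non_increasing(self):
        f = np.linspace(1.0, 60.0, 200)
        s = ramp_survival(f, STATE, DEFAULT_PROTOCOL)
        assert np.all(np.diff(s) <= 0)

    def test_below_ramp_start_rejected(self):
        with pytest.raises(ValueError):
            ramp_survival(0.5, STATE, DEFAULT_PROTOCOL)


class TestRampPdf:
    def test_integrates_to_one(self):
        total, _ = quad(
            lambda f: ramp_pdf(f, STATE, DEFAULT_PROTOCOL),
            DEFAULT_PROTOCOL.f_start,
            200.0,
            epsabs=1e-10,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_value_at_ramp_start(self):
        proto = DEFAULT_PROTOCOL
        assert ramp_pdf(proto.f_start, STATE, proto) == pytest.approx(
            hazard(proto.f_start, STATE, proto.kBT) / proto.loading_rate
        )


class TestModalForce:
    @pytest.mark.parametrize("k0,dx", [(1e-5, 1.0), (1e-6, 0.8), (2e-3, 1.2)])
    def test_matches_grid_argmax(self, k0, dx):
        state = BellState(k_unfold=k0, dx=dx)
        grid = np.arange(DEFAULT_PROTOCOL.f_start, 80.0, 0.002)
        pdf = ramp_pdf(grid, state, DEFAULT_PROTOCOL)
        assert modal_force(state, DEFAULT_PROTOCOL) == pytest.approx(
            grid[np.argmax(pdf)], abs=0.01
        )

    def test_increases_with_loading_rate(self):
        fast = DEFAULT_PROTOCOL.with_(loading_rate=20.0)
        assert modal_force(STATE, fast) > modal_force(STATE, DEFAULT_PROTOCOL)

    def test_decreases_with_k_unfold(self):
        weaker = BellState(k_unfold=1e-3, dx=1.0)
        assert modal_force(weaker, DEFAULT_PROTOCOL) < modal_force(
            STATE, DEFAULT_PROTOCOL
        )

    def test_monotone_decreasing_density_returns_ramp_start(self):
        state = BellState(k_unfold=100.0, dx=1.0)  # ruptures immediately
        assert modal_force(state, DEFAULT_PROTOCOL) == DEFAULT_PROTOCOL.f_start

    def test_inversion_constructor_reproduces_peak(self):
        for peak in (22.0, 36.0, 47.0, 55.0):
            state = state_from_modal_force(peak, dx=1.0)
            assert modal_force(state, DEFAULT_PROTOCOL) == pytest.approx(peak)

    def test_stable_peak_implies_slow_zero_force_rate(self):
        """Peaks near 55 pN at 2 pN/s map to zero-force rates in the slow
        1e-7..1e-5 s^-1 regime for transition distances around 1 nm, falling
        monotonically (and staying within an order of magnitude of that
        band) across the 0.7-1.2 nm box."""
        for dx in (0.8, 1.0, 1.15):
            assert 1e-7 <= state_from_modal_force(55.0, dx=dx).k_unfold <= 1e-5
        rates = [state_from_modal_force(55.0, dx=dx).k_unfold
                 for dx in (0.7, 0.8, 1.0, 1.2)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert all(1e-8 <= r <= 1e-4 for r in rates)


class TestSampleForce:
    def test_u_near_zero_approaches_ramp_start(self):
        f = sample_force(STATE, DEFAULT_PROTOCOL, 1e-14)
        assert f == pytest.approx(DEFAULT_PROTOCOL.f_start, abs=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(u=st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_inverse_of_survival(self, u):
        f = sample_force(STATE, DEFAULT_PROTOCOL, u)
        assert ramp_survival(f, STATE, DEFAULT_PROTOCOL) == pytest.approx(
            1 - u, abs=1e-9
        )

    def test_empirical_cdf_matches_closed_form(self):
        rng = np.random.default_rng(12345)
        samples = sample_force(STATE, DEFAULT_PROTOCOL, rng.uniform(size=100_000))
        d = kstest(
            samples, lambda f: 1.0 - ramp_survival(f, STATE, DEFAULT_PROTOCOL)
        ).statistic
        assert d < 0.01

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_rejects_u_outside_open_interval(self, bad):
        with pytest.raises(ValueError):
            sample_force(STATE, DEFAULT_PROTOCOL, bad)


def test_invalid_state_and_protocol():
    with pytest.raises(ValueError):
        BellState(k_unfold=0.0, dx=1.0)
    with pytest.raises(ValueError):
        BellState(k_unfold=1e-5, dx=-1.0)
    with pytest.raises(ValueError):
        RampProtocol(f_start=60.0, f_end=1.0)
    with pytest.raises(ValueError):
        RampProtocol(loading_rate=0.0)
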