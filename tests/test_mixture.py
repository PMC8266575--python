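"""Mixture MLE: parameter recovery, censoring, model selection, bootstrap."""

import numpy as np
import pytest

from g4tweezers import (
    BellState,
    DEFAULT_PROTOCOL,
    bootstrap_cis,
    fit_bell_mixture,
    population_fractions,
    responsibilities,
    sample_force,
    select_K,
    state_from_modal_force,
)
from g4tweezers.mixture import fit_bell_histogram


def _draw(state, n, seed, protocol=DEFAULT_PROTOCOL):
    rng = np.random.default_rng(seed)
    f = sample_force(state, protocol, rng.uniform(size=n))
    censored = int(np.sum(f > protocol.f_end))
    return f[f <= protocol.f_end], censored


class TestSingleState:
    def test_parameter_recovery(self):
        truth = BellState(k_unfold=1e-6, dx=1.0)
        forces, n_cens = _draw(truth, 5000, seed=21)
        fit = fit_bell_mixture(forces, n_cens, DEFAULT_PROTOCOL, K=1, seed=1)
        comp = fit.components[0]
        assert abs(np.log(comp.k_unfold) - np.log(1e-6)) < 0.5
        assert comp.dx == pytest.approx(1.0, rel=0.10)
        assert fit.converged

    def test_censoring_informs_fit(self):
        """Dropping the censored cycles from the likelihood biases the peak
        of a near-ceiling state downward; including them does not."""
        truth = state_from_modal_force(58.0, dx=1.0)
        forces, n_cens = _draw(truth, 8000, seed=22)
        assert n_cens > 100  # the state genuinely straddles the ceiling
        with_cens = fit_bell_mixture(forces, n_cens, DEFAULT_PROTOCOL, K=1, seed=1)
        without = fit_bell_mixture(forces, 0, DEFAULT_PROTOCOL, K=1, seed=1)
        assert abs(with_cens.components[0].modal_force - 58.0) < abs(
            without.components[0].modal_force - 58.0
        )
        assert with_cens.components[0].modal_force == pytest.approx(58.0, abs=1.0)

    def test_histogram_least_squares_agrees_with_mle(self):
        truth = BellState(k_unfold=1e-5, dx=1.0)
        forces, _ = _draw(truth, 100_000, seed=23)
        mle = fit_bell_mixture(forces, 0, DEFAULT_PROTOCOL, K=1, seed=1)
        hist = fit_bell_histogram(forces, DEFAULT_PROTOCOL, K=1, bin_width=1.0)
        assert abs(mle.components[0].modal_force - hist.components[0].modal_force) < 1.0


class TestThreeStateRecovery:
    def test_tb1_weights_and_peaks(self, tb1_scenario, tb1_sim_fit):
        _, _, fit = tb1_sim_fit
        truth_w = tb1_scenario.truth_event_weights
        for comp, w_true, f_true in zip(
            fit.components, truth_w, tb1_scenario.truth_modal_forces
        ):
            assert comp.weight == pytest.approx(w_true, abs=0.05)
            assert comp.modal_force == pytest.approx(f_true, abs=2.0)

    def test_posterior_assignment_tracks_truth_labels(self, tb1_sim_fit):
        cycles, forces, fit = tb1_sim_fit
        resp = responsibilities(fit, forces)
        assert resp.shape == (len(forces), 3)
        assert np.allclose(resp.sum(axis=1), 1.0)
        labels = np.argmax(resp, axis=1)
        truth = np.array(
            [c.state_label_truth for c in cycles if c.ruptured]
        )
        order = {"gvbq_5p": 0, "intermediate": 1, "full": 2}
        agreement = np.mean(labels == np.vectorize(order.get)(truth))
        assert agreement > 0.85


class TestSelectK:
    def test_single_state_data_prefers_one_component(self):
        truth = BellState(k_unfold=1e-5, dx=1.0)
        chosen = []
        for rep in range(5):
            forces, n_cens = _draw(truth, 2000, seed=100 + rep)
            fit = select_K(forces, n_cens, DEFAULT_PROTOCOL, K_max=3, seed=rep)
            chosen.append(fit.K)
        assert chosen.count(1) >= 4

    def test_three_state_scenario_selects_three(self, tb1_sim_fit):
        _, forces, _ = tb1_sim_fit
        fit = select_K(forces, 0, DEFAULT_PROTOCOL, K_max=4, seed=7)
        assert fit.K == 3

    def test_two_state_scenario_selects_two(self, tb8_sim_fit):
        _, forces, fit3 = tb8_sim_fit
        fit = select_K(forces, 0, DEFAULT_PROTOCOL, K_max=3, seed=7)
        assert fit.K == 2


class TestDegenerateInputs:
    def test_censored_only_has_no_mle(self):
        with pytest.raises(ValueError, match="censored-only"):
            fit_bell_mixture([], 500, DEFAULT_PROTOCOL, K=1)

    def test_too_few_events_for_k(self):
        with pytest.raises(ValueError, match="at least"):
            fit_bell_mixture([20.0, 25.0, 30.0], 0, DEFAULT_PROTOCOL, K=2)

    def test_out_of_range_forces_rejected(self):
        with pytest.raises(ValueError):
            fit_bell_mixture([0.2] * 20, 0, DEFAULT_PROTOCOL, K=1)


class TestFractions:
    def test_all_below_threshold(self):
        state = state_from_modal_force(20.0, dx=1.0)
        forces, n_cens = _draw(state, 500, seed=31)
        fit = fit_bell_mixture(forces, n_cens, DEFAULT_PROTOCOL, K=1, seed=1)
        frac = population_fractions(fit, threshold=40.0)
        assert frac["fraction_above"] == pytest.approx(0.0)
        assert frac["fraction_below"] == pytest.approx(1.0)

    def test_tb8_stable_mass(self, tb8_scenario, tb8_sim_fit):
        _, forces, fit = tb8_sim_fit
        frac = population_fractions(fit, threshold=40.0, forces=forces)
        truth_stable = tb8_scenario.truth_event_weights[1]
        assert frac["fraction_above"] == pytest.approx(truth_stable, abs=0.05)
        assert frac["empirical_above"] + frac["empirical_below"] == pytest.approx(1.0)


class TestBootstrap:
    def test_intervals_cover_truth_and_are_reproducible(self):
        truth = BellState(k_unfold=1e-5, dx=1.0)
        forces, n_cens = _draw(truth, 600, seed=41)
        fit = fit_bell_mixture(forces, n_cens, DEFAULT_PROTOCOL, K=1, seed=1)
        ci_a = bootstrap_cis(forces, n_cens, DEFAULT_PROTOCOL, fit, n_boot=100, seed=5)
        ci_b = bootstrap_cis(forces, n_cens, DEFAULT_PROTOCOL, fit, n_boot=100, seed=5)
        assert ci_a == ci_b
        from g4tweezers import modal_force

        truth_mode = modal_force(truth, DEFAULT_PROTOCOL)  # ~44.4 pN
        lo, hi = ci_a["modal_force"]["lo"][0], ci_a["modal_force"]["hi"][0]
        assert lo < truth_mode < hi
        assert hi - lo < 5.0

    def test_requires_minimum_replicates(self):
        truth = BellState(k_unfold=1e-5, dx=1.0)
        forces, n_cens = _draw(truth, 200, seed=42)
        fit = fit_bell_mixture(forces, n_cens, DEFAULT_PROTOCOL, K=1, seed=1)
        with pytest.raises(ValueError):
            bootstrap_cis(forces, n_cens, DEFAULT_PROTOCOL, fit, n_boot=10)


def test_histogram_plot_smoke(tb1_sim_fit, tmp_path):
    """The histogram-with-curves figure renders and saves."""
    from g4tweezers.plots import plot_force_histogram

    _, forces, fit = tb1_sim_fit
    fig = plot_force_histogram(forces, fit, path=tmp_path / "hist.png")
    assert (tmp_path / "hist.png").exists()
    assert len(fig.axes) == 1
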