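"""Observer inference, belief updating and trial execution."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from dvbelief.beliefs import (dv_grid, gaussian_belief, bounded_density,
                              stimulus_grid, uniform_dv_belief)
from dvbelief.errors import (DegeneratePriorError, InvalidArgumentError,
                             OutOfSupportError)
from dvbelief.gridsearch import mid_grid_params, simulate_joint_session
from dvbelief.observer import (ObserverParams, adaptation_gain, classify_dv,
                               condition_stimulus_prior_on_choice,
                               infer_dv, infer_stimulus, initial_state,
                               run_trial, simulate_session,
                               stimulus_to_dv_measurement,
                               update_dv_prior, update_stimulus_prior)
from dvbelief.synth import make_schedule


def conjugate_posterior(mu0, s0, m, s):
    var = 1 / (1 / s0 ** 2 + 1 / s ** 2)
    mean = var * (mu0 / s0 ** 2 + m / s ** 2)
    return mean, np.sqrt(var)


class TestStimulusInference:
    def test_conjugate_closed_form(self):
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        assert infer_stimulus(1.0, prior, 1.0) == pytest.approx(0.5, abs=1e-4)

    def test_flat_prior_returns_measurement(self):
        prior = gaussian_belief(0.0, 40.0, np.linspace(-240, 240, 4001))
        assert infer_stimulus(0.3, prior, 1.0) == pytest.approx(0.3, abs=1e-3)

    def test_general_conjugate_case(self):
        mean, _ = conjugate_posterior(0.4, 0.8, -0.2, 0.5)
        prior = gaussian_belief(0.4, 0.8, np.linspace(-5, 5.8, 2001))
        assert infer_stimulus(-0.2, prior, 0.5) == pytest.approx(mean, abs=1e-4)

    def test_out_of_support(self):
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        with pytest.raises(OutOfSupportError):
            infer_stimulus(9.0, prior, 1.0)


class TestDvMeasurement:
    def test_symmetry(self):
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        assert stimulus_to_dv_measurement(0.0, prior) == pytest.approx(
            0.5, abs=1e-6)

    def test_cdf_limits(self):
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        assert stimulus_to_dv_measurement(-100.0, prior) == 0.0
        assert stimulus_to_dv_measurement(100.0, prior) == 1.0

    def test_against_normal_cdf(self):
        prior = gaussian_belief(0.2, 1.0, np.linspace(-5.8, 6.2, 2001))
        assert stimulus_to_dv_measurement(0.0, prior) == pytest.approx(
            norm.cdf(-0.2), abs=1e-4)


class TestDvInference:
    def test_flat_prior_map_is_measurement(self):
        u = uniform_dv_belief()
        for mv in (0.2, 0.5, 0.83):
            assert infer_dv(mv, u, 0.05) == pytest.approx(mv, abs=2e-3)

    def test_concentrated_prior_attracts(self):
        grid = dv_grid()
        half = np.where(grid <= 0.5, 1.0, 0.0)
        from dvbelief.beliefs import GridBelief, leak_convolve
        prior = leak_convolve(GridBelief(grid, half, "dv").normalized(), 0.05)
        assert infer_dv(0.7, prior, 0.05) < 0.7

    def test_dense_grid_product_oracle(self):
        grid = dv_grid()
        prior = bounded_density(0.5, 0.1, grid)
        like = bounded_density(0.9, 0.1, grid).density  # symmetric profile
        oracle = grid[np.argmax(like * prior.density)]
        assert infer_dv(0.9, prior, 0.1) == pytest.approx(
            oracle, abs=grid[1] - grid[0])

    def test_bad_measurement(self):
        with pytest.raises(InvalidArgumentError):
            infer_dv(1.2, uniform_dv_belief(), 0.1)


class TestClassification:
    @pytest.mark.parametrize("v,G,expected", [
        (0.3, 4, 2),        # 0.25 < 0.3 <= 0.5
        (0.0, 8, 1), (1.0, 8, 8),
        (0.5, 2, 1),        # half-open (left] boundary convention
        (0.51, 2, 2),
    ])
    def test_examples(self, v, G, expected):
        assert classify_dv(v, G) == expected

    def test_invalid_granularity(self):
        with pytest.raises(InvalidArgumentError):
            classify_dv(0.5, 1)


class TestStimulusPriorUpdate:
    def test_one_back_conjugate(self):
        grid = np.linspace(-6, 6, 2001)
        base = gaussian_belief(0.0, 1.0, grid)
        state = initial_state(ObserverParams(
            variant="stim_prior_by_stimulus", sigma_s0=1.0, sigma_s=0.6,
            sigma_mms=0.8))
        out = update_stimulus_prior(state, 1.0, 1.0, mode="one_back",
                                    base_prior=base)
        mean = np.trapezoid(grid * out.density, grid)
        sd = np.sqrt(np.trapezoid((grid - mean) ** 2 * out.density, grid))
        assert mean == pytest.approx(0.5, abs=1e-4)
        assert sd == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_symmetric_evidence_keeps_mean(self):
        grid = np.linspace(-6, 6, 2001)
        base = gaussian_belief(0.0, 1.0, grid)
        state = initial_state(ObserverParams(
            variant="stim_prior_by_stimulus", sigma_s0=1.0, sigma_s=0.6,
            sigma_mms=0.8))
        out = update_stimulus_prior(state, 0.0, 1.0, mode="one_back",
                                    base_prior=base)
        mean = np.trapezoid(grid * out.density, grid)
        sd = np.sqrt(np.trapezoid(grid ** 2 * out.density, grid))
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sd < 1.0  # evidence shrinks the prior

    def test_recursive_equals_sequential_conjugate(self):
        # two chained updates equal one update on the precision-weighted pair
        grid = np.linspace(-6, 6, 2001)
        base = gaussian_belief(0.0, 1.0, grid)
        params = ObserverParams(variant="stim_prior_by_stimulus",
                                sigma_s0=1.0, sigma_s=0.6, sigma_mms=0.8,
                                stim_update_mode="recursive")
        state = initial_state(params)
        state.stimulus_prior = base
        sp = 1.0
        p1 = update_stimulus_prior(state, 0.8, sp, mode="recursive")
        state.stimulus_prior = p1
        p2 = update_stimulus_prior(state, -0.2, sp, mode="recursive")
        m1, s1 = conjugate_posterior(0.0, 1.0, 0.8, sp)
        m2, _ = conjugate_posterior(m1, s1, -0.2, sp)
        mean = np.trapezoid(grid * p2.density, grid)
        assert mean == pytest.approx(m2, abs=1e-4)


class TestDvPriorUpdate:
    def test_conditioning_on_half(self):
        u = uniform_dv_belief()
        out = update_dv_prior(u, choice=1, G=2, sigma_leak=1e-6)
        grid = out.support
        inside = out.density[grid < 0.49]
        outside = out.density[grid > 0.51]
        assert np.allclose(inside, 2.0, atol=1e-2)
        assert outside.max() < 1e-2

    def test_leak_always_spills(self):
        u = uniform_dv_belief()
        out = update_dv_prior(u, choice=3, G=8, sigma_leak=0.05)
        assert abs(out.integral() - 1) < 1e-8
        grid = out.support
        assert out.density[(grid < 0.2) | (grid > 0.45)].max() > 0

    def test_chosen_bin_interval(self):
        # choice 3 of 8 conditions on exactly [0.25, 0.375] before the leak
        u = uniform_dv_belief()
        tight = update_dv_prior(u, choice=3, G=8, sigma_leak=1e-6)
        grid = tight.support
        assert tight.density[(grid > 0.26) & (grid < 0.365)].min() > 7.5
        assert tight.density[(grid < 0.24) | (grid > 0.385)].max() < 0.1

    def test_invalid_choice(self):
        with pytest.raises(InvalidArgumentError):
            update_dv_prior(uniform_dv_belief(), choice=9, G=8,
                            sigma_leak=0.05)

    def test_degenerate_prior(self):
        from dvbelief.beliefs import GridBelief
        grid = dv_grid()
        dens = np.where(grid > 0.9, 1.0, 0.0)
        prior = GridBelief(grid, dens, "dv").normalized()
        with pytest.raises(DegeneratePriorError):
            update_dv_prior(prior, choice=1, G=8, sigma_leak=0.05)


class TestAdaptationGain:
    def test_zero_gain_identity(self):
        grid = np.linspace(-6, 6, 2001)
        assert np.allclose(adaptation_gain(grid, 0.0, 0.0, 1.0), 1.0)

    def test_dip_splits_peak(self):
        grid = np.linspace(-6, 6, 2001)
        gain = adaptation_gain(grid, 0.5, 1.0, 0.5)
        prior = gaussian_belief(0.0, 100.0, grid)  # effectively flat
        s_hat = infer_stimulus(0.5, prior, 0.5, gain=gain)
        assert abs(s_hat - 0.5) > 0.05  # argmax pushed off the dip centre

    def test_dense_grid_oracle(self):
        grid = np.linspace(-6, 6, 2001)
        gain = adaptation_gain(grid, 0.0, 0.5, 1.0)
        modified = gain * norm.pdf(grid, 0.5, 1.0)
        oracle = grid[np.argmax(modified)]
        prior = gaussian_belief(0.0, 1000.0, np.linspace(-6, 6, 2001))
        s_hat = infer_stimulus(0.5, prior, 1.0, gain=gain)
        assert s_hat == pytest.approx(oracle, abs=2 * (grid[1] - grid[0]))

    def test_clamped_at_zero(self):
        grid = np.linspace(-6, 6, 2001)
        gain = adaptation_gain(grid, 0.0, 1.0, 0.1)  # g*N peak = 4
        assert gain.min() == 0.0


class TestConditionStimulusPrior:
    def test_median_split(self):
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        out = condition_stimulus_prior_on_choice(prior, 1, 2, 1e-6)
        grid = out.support
        assert out.density[grid > 0.1].max() < 1e-3
        assert out.density[grid < -0.1].max() > 0

    def test_quartile_interval(self):
        # class 3 of 4 masks to [Q(0.5), Q(0.75)] of the prior itself
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        out = condition_stimulus_prior_on_choice(prior, 3, 4, 1e-6)
        grid = out.support
        hi = norm.ppf(0.75)
        assert out.density[(grid > 0.02) & (grid < hi - 0.02)].min() > 0.5
        assert out.density[(grid < -0.05) | (grid > hi + 0.05)].max() < 0.05

    def test_leak_and_normalization(self):
        prior = gaussian_belief(0.0, 1.0, np.linspace(-6, 6, 2001))
        out = condition_stimulus_prior_on_choice(prior, 1, 2, 0.5)
        assert abs(out.integral() - 1) < 1e-8
        assert out.density[out.support > 0.3].max() > 0


class TestRunTrial:
    def params(self, variant="standard"):
        kw = dict(sigma_s0=1.0, sigma_s=0.3)
        if variant in ("standard", "stim_prior_by_stimulus",
                       "stim_prior_by_choice"):
            kw["sigma_mms"] = 1.0
        if variant in ("standard", "stim_prior_by_choice",
                       "dv_prior_by_choice"):
            kw["sigma_leak"] = 0.1 if variant != "stim_prior_by_choice" else 0.5
        if variant in ("standard", "dv_prior_by_choice"):
            kw["sigma_v"] = 0.1
        return ObserverParams(variant=variant, **kw)

    def test_stim_by_stimulus_leaves_dv_prior_uniform(self, rng):
        p = self.params("stim_prior_by_stimulus")
        state = initial_state(p)
        _, new = run_trial(state, p, 0.4, "classification", 4, rng)
        assert np.allclose(new.dv_prior.density, state.dv_prior.density)

    def test_dv_by_choice_reproduction_keeps_stimulus_prior(self, rng):
        p = self.params("dv_prior_by_choice")
        state = initial_state(p)
        resp, new = run_trial(state, p, 0.4, "reproduction", 2, rng)
        assert resp.report == resp.s_hat
        assert np.allclose(new.stimulus_prior.density,
                           state.stimulus_prior.density)

    def test_scaling_report_is_v_hat(self, rng):
        p = self.params("standard")
        state = initial_state(p)
        resp, _ = run_trial(state, p, 0.1, "scaling", 2, rng)
        assert resp.report == resp.v_hat
        assert 0.0 <= resp.v_hat <= 1.0

    def test_unknown_task(self, rng):
        p = self.params()
        with pytest.raises(InvalidArgumentError):
            run_trial(initial_state(p), p, 0.0, "detection", 2, rng)

    def test_classification_commits_and_narrows_dv_prior(self, rng):
        p = self.params("standard")
        state = initial_state(p)
        resp, new = run_trial(state, p, 0.0, "classification", 8, rng)
        assert 1 <= resp.choice_class <= 8
        # conditioned prior concentrates around the chosen bin
        assert new.dv_prior.density.max() > state.dv_prior.density.max()


class TestSessionProperties:
    def test_determinism(self):
        p = ObserverParams(variant="dv_prior_by_choice", sigma_s0=1.0,
                           sigma_s=0.3, sigma_leak=0.1, sigma_v=0.1)
        sched = make_schedule("exp4", seed=3)
        sched = sched.__class__(sched.blocks[:2], sched.stimulus_distribution)
        a = simulate_session(p, sched, seed=99)
        b = simulate_session(p, sched, seed=99)
        assert a.equals(b)

    def test_above_chance_accuracy_and_noise_limit(self):
        from dvbelief.synth import class_of_stimulus
        for sigma_s, above in [(0.3, True), (25.0, False)]:
            p = ObserverParams(variant="stim_prior_by_stimulus",
                               sigma_s0=1.0, sigma_s=sigma_s, sigma_mms=3.9)
            trials = simulate_joint_session(p, 400, seed=5)
            correct = np.mean([
                c == class_of_stimulus(s, __import__("dvbelief").synth.
                                       StimulusDistribution(0, 1), g)
                for c, s, g in zip(trials.choice, trials.stimulus, trials.G)])
            chance = np.mean(1.0 / trials.G)
            if above:
                assert correct > chance + 0.1
            else:
                assert abs(correct - chance) < 3 * np.sqrt(chance / 400)

    def test_probability_integral_transform_uniform(self):
        # with a static prior equal to the true stimulus distribution and
        # tiny sensory noise, the DV measurements are uniform on [0, 1]
        p = ObserverParams(variant="sensory_adaptation", sigma_s0=1.0,
                           sigma_s=0.02, g=0.0)
        trials = simulate_joint_session(p, 600, seed=4)
        stat = kstest(trials["m_v"], "uniform")
        assert stat.pvalue > 0.01

    def test_prior_attraction_implies_dv_repulsion(self):
        # a large previous stimulus attracts the prior; the same estimate
        # then maps to a smaller DV measurement
        grid = np.linspace(-6, 6, 2001)
        base = gaussian_belief(0.0, 1.0, grid)
        state = initial_state(ObserverParams(
            variant="stim_prior_by_stimulus", sigma_s0=1.0, sigma_s=0.3,
            sigma_mms=0.5))
        updated = update_stimulus_prior(state, 1.5, 0.6, mode="one_back",
                                        base_prior=base)
        s_hat = 0.4
        assert stimulus_to_dv_measurement(s_hat, updated) < \
            stimulus_to_dv_measurement(s_hat, base)

    def test_granularity_monotonic_attraction(self):
        # a finer previous commitment pulls the next DV estimate harder
        # toward the chosen bin's centre
        u = uniform_dv_belief()
        prior_g2 = update_dv_prior(u, choice=2, G=2, sigma_leak=0.05)
        prior_g8 = update_dv_prior(u, choice=5, G=8, sigma_leak=0.05)
        m_v = 0.85
        v2 = infer_dv(m_v, prior_g2, 0.1)
        v8 = infer_dv(m_v, prior_g8, 0.1)
        # the wide G=2 bin leaves the measurement nearly untouched while
        # the narrow G=8 bin drags the estimate toward its centre
        assert abs(v2 - m_v) < 0.02
        assert m_v - v8 > 0.05
        assert v8 < v2


class TestParamsValidation:
    def test_variant_subsets_enforced(self):
        with pytest.raises(InvalidArgumentError):
            ObserverParams(variant="sensory_adaptation", sigma_s0=1.0,
                           sigma_s=0.3, g=0.5, sigma_v=0.1)  # sigma_v unused
        with pytest.raises(InvalidArgumentError):
            ObserverParams(variant="standard", sigma_s0=1.0, sigma_s=0.3,
                           sigma_mms=1.0, sigma_leak=0.1)  # sigma_v missing

    def test_sigma_s_prime_identity(self):
        p = ObserverParams(variant="standard", sigma_s0=1.0, sigma_s=0.3,
                           sigma_mms=0.4, sigma_leak=0.1, sigma_v=0.1)
        assert p.sigma_s_prime ** 2 == pytest.approx(0.3 ** 2 + 0.4 ** 2,
                                                     rel=1e-12)

    def test_positive_sds_required(self):
        with pytest.raises(InvalidArgumentError):
            ObserverParams(variant="standard", sigma_s0=-1.0, sigma_s=0.3,
                           sigma_mms=0.4, sigma_leak=0.1, sigma_v=0.1)
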