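"""Session measures, error partition, psychometric fit, and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import veridical_trials
from timeprior import (
    EstimationError,
    ObserverParams,
    cohens_d,
    context_dependency,
    error_components,
    fit_reproduction_line,
    likelihood_sd,
    posterior_mean,
    regression_index,
    session_measures,
    simulate_reproduction,
    split_half_regression,
    weber_fraction_from_2afc,
)


def _trials(stim, resp):
    return pd.DataFrame(
        {
            "session": "short",
            "trial_index": np.arange(len(stim)),
            "stimulus_ms": np.asarray(stim, dtype=float),
            "reproduced_ms": np.asarray(resp, dtype=float),
        }
    )


class TestReproductionLine:
    def test_veridical(self):
        slope, intercept = fit_reproduction_line(veridical_trials([1000, 1200, 1400]))
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_responses(self):
        t = _trials([1000, 1200, 1400], [1250, 1250, 1250])
        slope, intercept = fit_reproduction_line(t)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(1250.0)

    def test_hand_ols(self):
        slope, intercept = fit_reproduction_line(
            _trials([1000, 1200, 1400], [1100, 1200, 1300])
        )
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(600.0)

    def test_single_stimulus_is_an_error(self):
        with pytest.raises(EstimationError):
            fit_reproduction_line(_trials([1000, 1000], [900, 1100]))

    def test_regression_index_is_one_minus_slope(self):
        t = _trials([1000, 1200, 1400], [1100, 1200, 1300])
        assert regression_index(t) == pytest.approx(0.5)

    def test_regression_index_offset_invariant(self, short_session_trials):
        shifted = short_session_trials.copy()
        shifted["reproduced_ms"] += 150.0
        assert regression_index(shifted) == pytest.approx(
            regression_index(short_session_trials), abs=1e-12
        )


class TestErrorComponents:
    def test_unbiased_noiseless(self):
        t = veridical_trials([1000, 1200, 1400], trials_per_duration=3)
        assert error_components(t, 1200.0) == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_offset(self):
        t = veridical_trials([1000, 1200, 1400], trials_per_duration=3)
        t["reproduced_ms"] += 120.0
        bias, cv, total = error_components(t, 1200.0)
        assert (bias, cv, total) == pytest.approx((0.1, 0.0, 0.1))

    def test_quadratic_identity_on_random_data(self):
        rng = np.random.default_rng(0)
        stim = np.repeat([1000.0, 1200.0, 1400.0], 10)
        t = _trials(stim, stim + rng.normal(0, 80, stim.size))
        bias, cv, total = error_components(t, 1200.0)
        assert total**2 == pytest.approx(bias**2 + cv**2, abs=1e-12)

    def test_smaller_normaliser_inflates_error(self):
        rng = np.random.default_rng(1)
        stim = np.repeat([1000.0, 1200.0], 5)
        t = _trials(stim, stim + rng.normal(0, 50, stim.size))
        assert error_components(t, 600.0)[2] > error_components(t, 1200.0)[2]

    def test_requires_replicates_per_stimulus(self):
        with pytest.raises(EstimationError):
            error_components(_trials([1000, 1200], [1000, 1200]), 1100.0)

    def test_rejects_bad_normaliser(self):
        t = veridical_trials([1000, 1200], trials_per_duration=2)
        with pytest.raises(ValueError):
            error_components(t, 0.0)

    def test_session_measures_bundle(self, short_session_trials):
        m = session_measures(short_session_trials)
        assert m.regression_index == pytest.approx(1.0 - m.slope, abs=1e-12)
        assert m.total_error**2 == pytest.approx(m.bias**2 + m.cv**2, abs=1e-12)


class TestWeberFraction:
    def _step_data(self):
        comp = np.tile(np.linspace(300.0, 700.0, 9), 10)
        return pd.DataFrame(
            {
                "trial_index": np.arange(comp.size),
                "reference_ms": 500.0,
                "comparison_ms": comp,
                "chose_comparison_longer": comp > 500.0,
            }
        )

    def test_perfect_separation_returns_zero_with_flag(self):
        with pytest.warns(RuntimeWarning, match="separated"):
            assert weber_fraction_from_2afc(self._step_data()) == 0.0

    def test_degenerate_responses_rejected(self):
        d = self._step_data()
        d["chose_comparison_longer"] = True
        with pytest.raises(EstimationError):
            weber_fraction_from_2afc(d)

    def test_lapse_fit_close_to_probit(self):
        from timeprior import generate_discrimination_data

        d = generate_discrimination_data(0.3, n_trials=2000, seed=3)
        assert weber_fraction_from_2afc(d, lapse=0.02) == pytest.approx(
            weber_fraction_from_2afc(d), abs=0.05
        )


class TestContextDependency:
    def test_identical_sessions_give_zero(self):
        t = veridical_trials([1270, 1323, 1376], trials_per_duration=2)
        assert context_dependency(t, t) == pytest.approx(0.0)

    def test_constant_shift_recovered(self):
        short = veridical_trials([1271.0, 1324.0], trials_per_duration=2)
        long = veridical_trials([1270.0, 1323.0], trials_per_duration=2, session="long")
        long["reproduced_ms"] += 50.0
        # grids offset by 1 ms, matched within the 5 ms tolerance; the long
        # session reproduces the (1 ms shorter) matched stimulus + 50 ms
        assert context_dependency(short, long) == pytest.approx(49.0)

    def test_no_overlap_is_an_error(self):
        short = veridical_trials([1000.0, 1050.0], trials_per_duration=2)
        long = veridical_trials([1700.0, 1750.0], trials_per_duration=2)
        with pytest.raises(EstimationError):
            context_dependency(short, long)

    def test_bayesian_observer_shows_positive_context_effect(self, paradigm):
        """Session-mean priors pull common stimuli toward different centres,
        so the same duration is reproduced longer in the long session."""
        params = ObserverParams(400.0, 0.36, motor_noise_coef=0.0)
        rng = np.random.default_rng(11)
        short = pd.concat(
            [simulate_reproduction(params, paradigm.short_session, rng) for _ in range(40)]
        )
        long = pd.concat(
            [simulate_reproduction(params, paradigm.long_session, rng) for _ in range(40)]
        )
        observed = context_dependency(short, long)
        # analytic oracle: difference of posterior-mean responses per common pair
        expected = []
        for s_stim in paradigm.short_session.durations_ms:
            gaps = np.abs(np.array(paradigm.long_session.durations_ms) - s_stim)
            if gaps.min() <= 5.0:
                l_stim = paradigm.long_session.durations_ms[int(np.argmin(gaps))]
                e_short = posterior_mean(s_stim, 1271.0, 400.0, likelihood_sd(0.36, 1271.0))
                e_long = posterior_mean(l_stim, 1535.0, 400.0, likelihood_sd(0.36, 1535.0))
                expected.append(e_long - e_short)
        assert observed > 0
        assert observed == pytest.approx(np.mean(expected), abs=20.0)


class TestSplitHalf:
    def test_veridical_both_halves_zero(self):
        t = veridical_trials([1000, 1100, 1200, 1300], trials_per_duration=4)
        assert split_half_regression(t) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_piecewise_constructed_halves(self):
        stim = np.tile([1000.0, 1200.0, 1400.0], 4)
        first = stim[:6]  # slope 1
        second = 0.5 * stim[6:] + 600.0  # slope 0.5
        t = _trials(stim, np.concatenate([first, second]))
        r1, r2 = split_half_regression(t)
        assert r1 == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.5)

    def test_stationary_observer_has_equal_halves(self, paradigm):
        params = ObserverParams(400.0, 0.36)
        rng = np.random.default_rng(21)
        firsts, seconds = [], []
        for _ in range(60):
            t = simulate_reproduction(params, paradigm.short_session, rng)
            r1, r2 = split_half_regression(t)
            firsts.append(r1)
            seconds.append(r2)
        assert np.mean(firsts) == pytest.approx(np.mean(seconds), abs=0.05)

    def test_too_few_trials(self):
        with pytest.raises(EstimationError):
            split_half_regression(_trials([1000, 1200], [1000, 1200]))


class TestCohensD:
    def test_printed_weber_fraction_contrast(self):
        assert cohens_d(0.36, 0.21, 23, 0.22, 0.13, 23) == pytest.approx(0.80, abs=0.005)

    def test_equal_means(self):
        assert cohens_d(1.0, 0.5, 10, 1.0, 0.7, 10) == 0.0

    def test_unit_sds(self):
        assert cohens_d(1, 1, 30, 0, 1, 30) == pytest.approx(1.0)

    def test_zero_pooled_sd(self):
        with pytest.raises(ValueError):
            cohens_d(1, 0, 10, 0, 0, 10)


@given(
    offset=st.floats(-300, 300),
    noise_seed=st.integers(0, 10_000),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_error_decomposition_identity_property(offset, noise_seed):
    rng = np.random.default_rng(noise_seed)
    stim = np.repeat([1006.0, 1271.0, 1536.0], 7)
    t = _trials(stim, stim + offset + rng.normal(0, 60, stim.size))
    bias, cv, total = error_components(t, 1271.0)
    assert total**2 == pytest.approx(bias**2 + cv**2, abs=1e-12)
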