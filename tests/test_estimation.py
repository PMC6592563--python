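"""Censored-likelihood period estimation and rate extraction."""

import numpy as np
import pytest
from scipy import integrate, optimize

from tissuecorr import estimation, synthetic
from tissuecorr.errors import InsufficientDataError, NonIdentifiableError
from tissuecorr.estimation import DurationData
from tissuecorr.profiles import StepProfile, SwitchProfileSet


def step(times, levels, weight=1.0):
    return StepProfile(np.asarray(times, float), np.asarray(levels, float), weight)


class TestMergeConsecutiveSwitches:
    def test_run_of_up_switches_collapses_to_first(self):
        prof = step([0.0, 2.0, 5.0], [0.0, 1.0, 2.0, 0.5])  # up, up, down
        times, signs = estimation.merge_consecutive_switches(prof)
        assert np.allclose(times, [0.0, 5.0])
        assert np.array_equal(signs, [1, -1])

    def test_alternating_train_unchanged(self):
        prof = step([2.0, 7.0, 9.0], [0.0, 1.0, 0.2, 1.5])
        times, signs = estimation.merge_consecutive_switches(prof)
        assert np.allclose(times, [2.0, 7.0, 9.0])
        assert np.array_equal(signs, [1, -1, 1])

    def test_mixed_runs_example(self):
        # down@1, down@3, up@8, up@9, down@20 -> down@1, up@8, down@20
        prof = step([1.0, 3.0, 8.0, 9.0, 20.0], [2.0, 1.5, 1.0, 2.0, 3.0, 0.5])
        times, signs = estimation.merge_consecutive_switches(prof)
        assert np.allclose(times, [1.0, 8.0, 20.0])
        assert np.array_equal(signs, [-1, 1, -1])

    def test_zero_change_switches_dropped(self):
        prof = step([2.0, 5.0], [1.0, 1.0, 2.0])
        times, signs = estimation.merge_consecutive_switches(prof)
        assert np.allclose(times, [5.0])


class TestExtractDurations:
    def test_single_cycle_with_censored_tail(self):
        train = (np.array([0.5, 10.5]), np.array([1, -1]))  # up@0.5, down@10.5
        on, down = estimation.extract_durations([train], horizon=48.0)
        assert np.allclose(on.complete, [10.0])
        assert on.n_censored == 0
        assert down.n_complete == 0
        assert np.allclose(down.censored, [37.5])

    def test_no_switches_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning):
            on, down = estimation.extract_durations(
                [(np.empty(0), np.empty(0))], horizon=48.0
            )
        assert on.n_complete == on.n_censored == 0

    def test_counts_match_brute_force_scan(self):
        """Generated profiles: duration counts equal a direct hand count."""
        profs = synthetic.generate_switch_profiles(
            10, 3, 10, 0.1, 1.0, horizon=48.0, n_cells=30, n_candidates=1, seed=9
        )
        trains = [
            estimation.merge_consecutive_switches(p.candidates[0])
            for p in profs.values()
        ]
        on, down = estimation.extract_durations(trains, horizon=48.0)
        # brute force: count complete gaps by type, plus one censored tail per train
        n_on, n_down, n_cens = 0, 0, 0
        for times, signs in trains:
            if times.size == 0:
                continue
            n_cens += 1
            for s in signs[:-1]:
                if s > 0:
                    n_on += 1
                else:
                    n_down += 1
        assert on.n_complete == n_on
        assert down.n_complete == n_down
        assert on.n_censored + down.n_censored == n_cens


class TestExponentialMLE:
    def test_uncensored_is_sample_mean(self, rng):
        x = rng.exponential(5.0, 200)
        data = DurationData(x, np.empty(0), "on")
        assert estimation.mle_exponential_censored(data) == pytest.approx(x.mean())

    def test_closed_form_example(self):
        data = DurationData(np.array([2.0, 4.0]), np.array([3.0]), "on")
        assert estimation.mle_exponential_censored(data) == pytest.approx(4.5)

    def test_matches_numeric_optimiser_to_1e10(self):
        data = synthetic.generate_durations(11.605, 0.0, 2000, 0.1, seed=1, kind="on")

        # independent oracle: root of the score in the rate parameterisation,
        # d/d lam [n_c log lam - lam * (sum complete + sum censored)] = 0
        def score(lam):
            return data.n_complete / lam - (data.complete.sum() + data.censored.sum())

        lam_hat = optimize.brentq(score, 1e-6, 10.0, xtol=1e-15)
        closed = estimation.mle_exponential_censored(data)
        assert closed == pytest.approx(1.0 / lam_hat, abs=1e-10 * closed)

    def test_recovery_at_study_mean(self):
        data = synthetic.generate_durations(11.605, 0.0, 10_000, 0.1, seed=2, kind="on")
        est = estimation.mle_exponential_censored(data)
        se = est / np.sqrt(data.n_complete)
        assert abs(est - 11.605) < 3 * se

    def test_no_complete_durations_rejected(self):
        with pytest.raises(NonIdentifiableError):
            estimation.mle_exponential_censored(
                DurationData(np.empty(0), np.array([1.0]), "on")
            )


class TestHypoexponentialMLE:
    def test_pdf_integrates_to_one(self):
        for lam1, lam2 in [(1 / 3.5, 1 / 15.1), (0.5, 0.6), (2.0, 0.01)]:
            val, _ = integrate.quad(
                lambda t: np.exp(estimation.hypoexp_logpdf(t, lam1, lam2)),
                0, np.inf,
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_erlang_limit_continuity(self):
        t = np.linspace(0.1, 30, 50)
        near = estimation.hypoexp_logpdf(t, 0.2, 0.2000001)
        limit = 2 * np.log(0.2) + np.log(t) - 0.2 * t
        assert np.allclose(near, limit, atol=1e-4)

    def test_loglik_exchange_symmetric(self):
        data = synthetic.generate_durations(3.5, 15.1, 100, 0.1, seed=3)
        a = estimation._hypoexp_negloglik(np.log([3.5, 15.1]), data)
        b = estimation._hypoexp_negloglik(np.log([15.1, 3.5]), data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_survival_consistent_with_pdf(self):
        lam1, lam2 = 1 / 3.5, 1 / 15.1
        for t0 in [1.0, 10.0, 40.0]:
            tail, _ = integrate.quad(
                lambda t: np.exp(estimation.hypoexp_logpdf(t, lam1, lam2)),
                t0, np.inf,
            )
            assert np.exp(estimation.hypoexp_logsf(t0, lam1, lam2)) == pytest.approx(
                tail, rel=1e-8
            )

    def test_recovery_at_study_means(self):
        data = synthetic.generate_durations(3.5, 15.1, 2000, 0.1, seed=4)
        est = estimation.mle_hypoexponential_censored(data)
        assert est.T1 < est.T2
        assert est.T1 == pytest.approx(3.5, rel=0.25)
        assert est.T2 == pytest.approx(15.1, rel=0.15)
        assert not est.boundary

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimation.mle_hypoexponential_censored(
                DurationData(np.arange(1.0, 6.0), np.empty(0))
            )


class TestTranscriptionRates:
    def test_single_two_level_profile_returns_levels(self):
        profs = {"0": SwitchProfileSet([step([5.0, 20.0], [0.1, 2.0, 0.1])])}
        lo, hi = estimation.estimate_transcription_rates(profs)
        assert hi == pytest.approx(2.0)
        assert lo == pytest.approx(0.1)

    def test_exact_recovery_on_noiseless_synthetic(self):
        profs = synthetic.generate_switch_profiles(
            11.605, 3.5, 15.1, 0.275, 4.25, horizon=48.0, n_cells=50,
            n_candidates=3, seed=5,
        )
        lo, hi = estimation.estimate_transcription_rates(profs)
        assert lo == pytest.approx(0.275)
        assert hi == pytest.approx(4.25)

    def test_noisy_levels_recovered_within_5_percent(self, rng):
        profs = {}
        for i in range(200):
            lo = 0.275 * np.exp(rng.normal(0, 0.1))
            hi = 4.25 * np.exp(rng.normal(0, 0.1))
            profs[str(i)] = SwitchProfileSet([step([10.0, 25.0], [lo, hi, lo])])
        lo_hat, hi_hat = estimation.estimate_transcription_rates(profs)
        assert lo_hat == pytest.approx(0.275, rel=0.05)
        assert hi_hat == pytest.approx(4.25, rel=0.05)

    def test_one_sided_data_gives_partial_result(self):
        profs = {"0": SwitchProfileSet([step([5.0], [0.1, 2.0])])}  # up only
        with pytest.warns(UserWarning):
            lo, hi = estimation.estimate_transcription_rates(profs)
        assert lo is None and hi == pytest.approx(2.0)


class TestWeightedPooling:
    def test_durations_from_profiles_weights_follow_candidates(self):
        profs = {
            "0": SwitchProfileSet(
                [step([1.0, 4.0], [0.0, 1.0, 0.0], 0.25),
                 step([2.0, 9.0], [0.0, 1.0, 0.0], 0.75)]
            )
        }
        on, down = estimation.durations_from_profiles(profs, horizon=48.0)
        assert np.allclose(sorted(on.complete), [3.0, 7.0])
        assert np.allclose(sorted(on.weights_complete), [0.25, 0.75])
        assert down.n_censored == 2  # one open-ended low tail per candidate
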