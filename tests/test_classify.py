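"""Template matching, lagged correlation, LOOCV, and binomial chance level."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import attnbci as ab
from attnbci.classify import CLASS_LEFT, CLASS_RIGHT, TemplatePair
from attnbci.preprocess import EpochSet


def brute_force_lagged_pearson(x, t, max_lag):
    """Independent O(n*L) direct-sum oracle for the peak lagged correlation.

    Same overlap convention (x[i] vs t[i - lag], no padding) and the same
    tie rule (smaller |lag| first, then negative), but computed with plain
    running sums, not vectorised dot products.
    """
    n = len(x)
    best = (-np.inf, 0)
    lags = [0]
    for k in range(1, max_lag + 1):
        lags += [-k, k]
    for lag in lags:
        pairs = [(x[i], t[i - lag]) for i in range(n)
                 if 0 <= i - lag < n]
        m = len(pairs)
        sx = sum(p[0] for p in pairs) / m
        stv = sum(p[1] for p in pairs) / m
        num = sum((a - sx) * (b - stv) for a, b in pairs)
        dx = sum((a - sx) ** 2 for a, _ in pairs)
        dt = sum((b - stv) ** 2 for _, b in pairs)
        r = num / np.sqrt(dx * dt) if dx > 0 and dt > 0 else 0.0
        if r > best[0]:
            best = (r, lag)
    return best


def single_channel_epochs(trials, labels, fs=250.0):
    arr = np.asarray(trials, dtype=float)[:, None, :]
    return EpochSet(arr, list(labels), (0.0, arr.shape[2] / fs), fs, ["d"])


class TestBuildTemplates:
    def test_one_trial_per_class_returns_those_trials(self):
        a, b = np.sin(np.arange(50) / 3.0), np.cos(np.arange(50) / 3.0)
        epochs = single_channel_epochs([a, b], ["left", "right"])
        tp = ab.build_templates(epochs)
        assert np.array_equal(tp.left, a) and np.array_equal(tp.right, b)
        assert tp.n_train_left == tp.n_train_right == 1

    def test_opposite_trials_average_to_zero(self):
        a = np.sin(np.arange(50) / 3.0)
        epochs = single_channel_epochs([a, -a, a], ["left", "left", "right"])
        tp = ab.build_templates(epochs)
        assert np.allclose(tp.left, 0.0)

    def test_templates_are_class_means(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((40, 60))
        labels = ["left"] * 20 + ["right"] * 20
        tp = ab.build_templates(single_channel_epochs(trials, labels))
        assert np.allclose(tp.left, trials[:20].mean(axis=0))
        assert np.allclose(tp.right, trials[20:].mean(axis=0))
        assert tp.n_train_left == 20

    def test_missing_class_refused(self):
        epochs = single_channel_epochs([np.zeros(10)], ["left"])
        with pytest.raises(ValueError, match="per class"):
            ab.build_templates(epochs)


class TestLaggedXcorr:
    def test_identical_signals_peak_at_zero(self):
        x = np.sin(np.arange(100) / 4.0)
        r, lag = ab.lagged_xcorr(x, x, max_lag=8)
        assert r == pytest.approx(1.0) and lag == 0

    def test_shifted_signal_recovers_shift(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(200)
        x = np.roll(t, 2)  # x[i] = t[i-2] on the overlap
        x[:2] = rng.standard_normal(2)
        r, lag = ab.lagged_xcorr(x, t, max_lag=8)
        assert lag == 2 and r == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(30, 120))
            x, t = rng.standard_normal((2, n))
            L = int(rng.integers(0, 10))
            r, lag = ab.lagged_xcorr(x, t, max_lag=L)
            r_o, lag_o = brute_force_lagged_pearson(x, t, L)
            worst = max(worst, abs(r - r_o))
            assert lag == lag_o
        assert worst < 1e-10

    def test_degenerate_overlap_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            ab.lagged_xcorr(np.zeros(10), np.zeros(10), max_lag=8)

    def test_constant_overlap_scores_zero(self):
        x = np.ones(50)
        t = np.ones(50)
        r, lag = ab.lagged_xcorr(x, t, max_lag=3)
        assert r == 0.0 and lag == 0

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-20.0, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_and_offset_invariance(self, scale, offset):
        rng = np.random.default_rng(7)
        x, t = rng.standard_normal((2, 80))
        r0, lag0 = ab.lagged_xcorr(x, t, max_lag=5)
        r1, lag1 = ab.lagged_xcorr(scale * x + offset, t, max_lag=5)
        assert r1 == pytest.approx(r0, abs=1e-9) and lag1 == lag0


class TestClassifyTrial:
    @pytest.fixture
    def templates(self):
        rng = np.random.default_rng(3)
        return TemplatePair(left=rng.standard_normal(250),
                            right=rng.standard_normal(250),
                            n_train_left=5, n_train_right=5, channel="Cz-TP9")

    def test_trial_equal_to_left_template(self, templates):
        res = ab.classify_trial(templates.left, templates)
        assert res.label == CLASS_LEFT
        assert res.r_left == pytest.approx(1.0)
        assert res.max_lag == 8  # 32 ms at 250 Hz

    def test_delayed_right_template_still_right(self, templates):
        delayed = np.roll(templates.right, 2)  # 8 ms delay at 250 Hz
        res = ab.classify_trial(delayed, templates)
        assert res.label == CLASS_RIGHT
        assert res.best_lag_right == 2

    def test_exact_tie_goes_left(self):
        t = np.sin(np.arange(100) / 4.0)
        templates = TemplatePair(left=t, right=t, n_train_left=1,
                                 n_train_right=1, channel="d")
        res = ab.classify_trial(t, templates)
        assert res.r_left == res.r_right
        assert res.label == CLASS_LEFT

    def test_scale_invariance_of_decision(self, templates):
        trial = 0.7 * templates.right + 0.1
        for a, b in [(1.0, 0.0), (3.5, -2.0), (0.01, 10.0)]:
            res = ab.classify_trial(a * trial + b, templates)
            assert res.label == CLASS_RIGHT


class TestLoocv:
    def test_separable_session_is_perfect(self, clean_session, bandpass_spec):
        _, rec, markers, _ = clean_session
        epochs, _ = ab.extract_epochs(rec, markers, (-0.5, 3.5))
        report = ab.loocv(epochs, [("Cz", "TP9")], filter_spec=bandpass_spec)
        assert report.accuracies["Cz-TP9"] == 1.0
        assert report.best_channel == "Cz-TP9"

    def test_accuracy_is_exact_fraction(self):
        # 3 of 4 trials correct -> 0.75: the fourth trial is a mixture that
        # correlates more with the left template than with its own class
        rng = np.random.default_rng(9)
        L = rng.standard_normal(120)
        R = rng.standard_normal(120)
        trials = np.stack([L, L, R, L + 0.5 * R])
        arr = np.stack([trials, np.zeros_like(trials)], axis=1)
        epochs = EpochSet(arr, ["left", "left", "right", "right"],
                          (0.0, 120 / 250.0), 250.0, ["Cz", "REF"])
        report = ab.loocv(epochs, [("Cz", "REF")], filter_spec=None,
                          max_lag_s=0.0)
        assert report.accuracies["Cz-REF"] == 0.75

    def test_permuting_trial_order_leaves_accuracy(self, clean_session,
                                                   bandpass_spec):
        cfg, rec, markers, _ = clean_session
        epochs, _ = ab.extract_epochs(rec, markers, (-0.5, 3.5))
        rng = np.random.default_rng(13)
        perm = rng.permutation(epochs.n_trials)
        shuffled = EpochSet(epochs.trials[perm],
                            [epochs.labels[i] for i in perm],
                            epochs.window, epochs.fs, epochs.channel_labels)
        a = ab.loocv(epochs, [("Cz", "TP9")], filter_spec=bandpass_spec)
        b = ab.loocv(shuffled, [("Cz", "TP9")], filter_spec=bandpass_spec)
        assert a.accuracies == b.accuracies

    def test_null_session_accuracy_near_half(self, null_session, bandpass_spec):
        _, rec, markers, _ = null_session
        epochs, _ = ab.extract_epochs(rec, markers, (-0.5, 3.5))
        report = ab.loocv(epochs, [("Cz", "TP9")], filter_spec=bandpass_spec)
        n = report.n_trials
        lo, hi = scipy.stats.binom.interval(0.95, n, 0.5)
        assert lo / n <= report.accuracies["Cz-TP9"] <= hi / n

    def test_too_few_trials_refused(self):
        epochs = single_channel_epochs(np.zeros((2, 50)), ["left", "right"])
        with pytest.raises(ValueError, match="2 trials per class"):
            ab.loocv(EpochSet(np.zeros((2, 2, 50)), ["left", "right"],
                              (0, 0.2), 250.0, ["a", "b"]),
                     [("a", "b")])


class TestChanceLevel:
    def test_feedback_block_value(self):
        assert ab.chance_level(120, 2, 0.05).threshold_percent == 57.5

    def test_forty_trials_value(self):
        # exhaustive check of the definition for n = 40
        n, p, alpha = 40, 0.5, 0.05
        k_star = next(k for k in range(n + 1)
                      if scipy.stats.binom.cdf(k, n, p) >= 1 - alpha)
        assert 100 * k_star / n == 62.5
        assert ab.chance_level(40, 2, 0.05).threshold_percent == 62.5

    @given(n=st.integers(2, 400))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_above_guessing(self, n):
        cl = ab.chance_level(n, 2, 0.05)
        assert 50.0 <= cl.threshold_percent <= 100.0

    def test_non_increasing_in_n(self):
        values = [ab.chance_level(n, 2, 0.05).threshold_percent
                  for n in (10, 40, 120, 500, 2000, 10000)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[-1] < 52.0  # approaches 100/c from above

    def test_stricter_alpha_raises_threshold(self):
        loose = ab.chance_level(120, 2, 0.05).threshold_percent
        strict = ab.chance_level(120, 2, 0.001).threshold_percent
        assert strict >= loose

    @pytest.mark.parametrize("n,c,alpha", [(0, 2, 0.05), (10, 1, 0.05),
                                           (10, 2, 0.0), (10, 2, 1.0)])
    def test_invalid_parameters_refused(self, n, c, alpha):
        with pytest.raises(ValueError):
            ab.chance_level(n, c, alpha)
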