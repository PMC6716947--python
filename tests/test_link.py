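import itertools

import numpy as np
import pytest
from scipy import stats

from cannonlearn import (
    ClusterResult,
    EpochArray,
    binned_learning_rates,
    coefficient_timecourse_test,
    fit_link_regression,
    group_coefficient_test,
    sliding_window_strength,
    trial_signal_strength,
)


def _epochs(data, srate=500.0, tmin=-200.0):
    n_ch, n_t, _ = data.shape
    step = 1000.0 / srate
    return EpochArray(
        data=data,
        times=np.arange(tmin, tmin + step * n_t, step)[:n_t],
        srate=srate,
        channel_names=[f"C{i}" for i in range(n_ch)],
        channel_positions=np.column_stack([np.arange(n_ch, dtype=float), np.zeros(n_ch)]),
    )


def _cluster(channels, times, t_map):
    channels = np.asarray(channels)
    times = np.asarray(times)
    tvals = t_map[channels, times]
    peak = int(np.argmax(np.abs(tvals)))
    return ClusterResult(
        channels=channels,
        time_indices=times,
        sign=1,
        mass=float(np.abs(tvals).sum()),
        peak=(int(channels[peak]), int(times[peak])),
    )


class TestTrialSignalStrength:
    def test_data_equal_to_tmap_gives_sum_of_squares(self):
        rng = np.random.default_rng(0)
        t_map = rng.normal(size=(3, 20))
        members = ([0, 0, 1, 2], [4, 5, 4, 10])
        n_trials = 6
        data = np.zeros((3, 20, n_trials))
        data[:, :, 0] = t_map  # trial 0 replicates the map exactly
        cluster = _cluster(*members, t_map)
        epochs = _epochs(data)
        strength = trial_signal_strength(epochs, cluster, t_map)
        raw_expected = (t_map[members] ** 2).sum()
        raws = np.array([(t_map[members] * data[members[0], members[1], t]).sum() for t in range(n_trials)])
        np.testing.assert_allclose(strength, (raws - raws.mean()) / raws.std())
        assert raws[0] == pytest.approx(raw_expected)

    def test_orthogonal_data_gives_zero_raw_strength(self):
        t_map = np.zeros((2, 10))
        t_map[0, 3] = 1.0
        data = np.zeros((2, 10, 4))
        data[1, 7, :] = np.arange(4)  # energy entirely off the cluster support
        cluster = _cluster([0], [3], t_map)
        strength = trial_signal_strength(_epochs(data), cluster, t_map)
        np.testing.assert_allclose(strength, 0.0)

    def test_invariant_to_signal_off_cluster_support(self):
        rng = np.random.default_rng(1)
        t_map = rng.normal(size=(3, 15))
        data = rng.normal(size=(3, 15, 30))
        cluster = _cluster([0, 1], [2, 2], t_map)
        s1 = trial_signal_strength(_epochs(data), cluster, t_map)
        perturbed = data.copy()
        perturbed[2, :, :] += rng.normal(size=(15, 30))  # off-support channel
        s2 = trial_signal_strength(_epochs(perturbed), cluster, t_map)
        np.testing.assert_allclose(s1, s2)

    def test_zscore_normalization(self):
        rng = np.random.default_rng(2)
        t_map = rng.normal(size=(2, 8))
        data = rng.normal(size=(2, 8, 50))
        cluster = _cluster([0, 1, 1], [1, 1, 2], t_map)
        s = trial_signal_strength(_epochs(data), cluster, t_map)
        assert s.mean() == pytest.approx(0.0, abs=1e-8)
        assert s.std() == pytest.approx(1.0, abs=1e-8)

    def test_empty_cluster_rejected(self):
        t_map = np.zeros((2, 5))
        cluster = ClusterResult(
            channels=np.array([], int), time_indices=np.array([], int), sign=1, mass=0.0, peak=(0, 0)
        )
        with pytest.raises(ValueError):
            trial_signal_strength(_epochs(np.zeros((2, 5, 3))), cluster, t_map)


class TestFitLinkRegression:
    def _synthetic(self, g_direct=0.0, g_cond=0.0, n=480, seed=0):
        rng = np.random.default_rng(seed)
        delta = rng.uniform(-np.pi, np.pi, size=n)
        condition = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        strength = rng.normal(size=n)
        slope = 0.5 + g_direct * strength + g_cond * strength * condition
        update = slope * delta + rng.vonmises(0.0, 20.0, size=n)
        return update, delta, condition, strength

    def test_independent_strength_yields_null_coefficients(self):
        fits = []
        for seed in range(12):
            u, d, c, s = self._synthetic(seed=seed)
            fits.append(fit_link_regression(u, d, c, s, seed=seed))
        g = group_coefficient_test(fits).set_index("term")
        assert g.loc["pe_eeg", "p"] > 0.01
        assert g.loc["pe_condition_eeg", "p"] > 0.01

    def test_recovers_planted_conditional_coupling(self):
        fits = []
        for seed in range(12):
            u, d, c, s = self._synthetic(g_cond=0.1, seed=seed)
            fits.append(fit_link_regression(u, d, c, s, seed=seed))
        g = group_coefficient_test(fits).set_index("term")
        row = g.loc["pe_condition_eeg"]
        assert abs(row["mean"] - 0.1) < 2 * row["sem"] + 0.01
        assert abs(g.loc["pe_eeg", "mean"]) < 0.02

    def test_recovers_planted_direct_coupling(self):
        fits = []
        for seed in range(12):
            u, d, c, s = self._synthetic(g_direct=0.1, seed=seed)
            fits.append(fit_link_regression(u, d, c, s, seed=seed))
        g = group_coefficient_test(fits).set_index("term")
        assert g.loc["pe_eeg", "mean"] > 0.05
        assert abs(g.loc["pe_condition_eeg", "mean"]) < 0.02

    def test_pred_lr_term_absorbs_modeled_behavior(self):
        # behavior fully explained by the behavioral model leaves EEG terms null;
        # the 10x prior asymmetry hands shared variance to the behavioral term
        rng = np.random.default_rng(5)
        fits = []
        for seed in range(10):
            n = 480
            delta = rng.uniform(-np.pi, np.pi, size=n)
            condition = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            pred_lr = 0.4 + 0.3 * rng.random(n)
            strength = 0.7 * (pred_lr - pred_lr.mean()) / pred_lr.std() + 0.7 * rng.normal(size=n)
            update = pred_lr * delta + rng.vonmises(0.0, 20.0, size=n)
            fits.append(
                fit_link_regression(update, delta, condition, strength, pred_lr=pred_lr, seed=seed)
            )
        g = group_coefficient_test(fits).set_index("term")
        assert g.loc["pe_pred_lr", "mean"] > 0.8
        assert abs(g.loc["pe_eeg", "mean"]) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_link_regression(np.zeros(10), np.zeros(10), np.zeros(9), np.zeros(10))


class TestSlidingWindowStrength:
    def test_window_count_at_full_rate(self):
        # 40 ms windows, one-sample steps at 500 Hz over 300-700 ms: 181 windows
        data = np.random.default_rng(6).normal(size=(2, 600, 5))
        epochs = _epochs(data)
        t_map = np.ones((2, 600))
        strengths, starts = sliding_window_strength(epochs, t_map)
        assert len(starts) == 181
        assert strengths.shape == (181, 5)
        assert starts[0] == pytest.approx(300.0)
        assert starts[-1] == pytest.approx(660.0)

    def test_constant_data_identical_across_windows(self):
        # epochs constant in time after a zero baseline period: every window
        # sees the same pattern, so the z-scored strengths agree across windows
        rng = np.random.default_rng(7)
        trial_values = rng.normal(size=8)
        data = np.tile(trial_values, (1, 600, 1))
        times = np.arange(-200.0, 1000.0, 2.0)
        data[:, times < 0.0, :] = 0.0  # flat pre-outcome baseline
        epochs = _epochs(data)
        t_map = np.ones((1, 600))
        strengths, _ = sliding_window_strength(epochs, t_map, step_ms=40.0)
        np.testing.assert_allclose(strengths - strengths[0], 0.0, atol=1e-9)

    def test_template_peak_localized(self):
        rng = np.random.default_rng(8)
        n_trials = 60
        times = np.arange(-200, 1000, 2.0)
        bump = np.exp(-((times - 370.0) ** 2) / (2 * 10.0**2))  # 350-390 ms support
        gains = rng.normal(1.0, 0.5, size=n_trials)
        data = bump[None, :, None] * gains[None, None, :] + rng.normal(0, 0.05, size=(1, len(times), n_trials))
        epochs = _epochs(data)
        t_map = np.tile(bump, (1, 1))
        strengths, starts = sliding_window_strength(epochs, t_map, step_ms=10.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            discrimination = np.array([np.corrcoef(s, gains)[0, 1] for s in strengths])
        peak_windows = (starts >= 330.0) & (starts <= 390.0)
        assert discrimination[peak_windows].min() > 0.9
        # windows well past the template carry noise only (but stay clear of
        # the far range where the Gaussian weights underflow entirely)
        off = (starts >= 470.0) & (starts <= 520.0)
        assert np.abs(discrimination[off]).max() < 0.5

    def test_window_outside_epoch_rejected(self):
        epochs = _epochs(np.zeros((1, 100, 3)))  # ends at -200 + 99*2 = -2 ms
        with pytest.raises(ValueError):
            sliding_window_strength(epochs, np.zeros((1, 100)))


class TestCoefficientTimecourse:
    def test_constant_effect_spans_range_at_floor(self):
        rng = np.random.default_rng(9)
        series = rng.normal(1.0, 0.2, size=(15, 80))
        clusters, t_series = coefficient_timecourse_test(series, step_ms=2.0, n_perm=500, seed=0)
        top = clusters[0]
        assert top.size == 80  # spans the full analysis range
        assert top.p_perm == pytest.approx(1.0 / 501.0)

    def test_null_series_rarely_significant(self):
        rng = np.random.default_rng(10)
        n_sig = 0
        for _ in range(40):
            series = rng.normal(size=(10, 60))
            clusters, _ = coefficient_timecourse_test(series, step_ms=2.0, n_perm=150, seed=3)
            if clusters and clusters[0].p_perm <= 0.05:
                n_sig += 1
        # binomial(40, 0.05): >= 8 hits has probability ~2e-4
        assert n_sig <= 7

    def test_exact_enumeration_with_four_subjects(self):
        rng = np.random.default_rng(11)
        series = rng.normal(0.6, 0.3, size=(4, 30))
        clusters, _ = coefficient_timecourse_test(
            series, step_ms=2.0, smooth_sd_ms=0.0, n_perm=1000, seed=0
        )
        assert clusters
        sigma = 0.0
        smoothed = series
        maps = smoothed[:, None, :]
        from cannonlearn import find_clusters, group_tmap

        thresh = stats.t.ppf(1 - 0.05 / 2, 3)
        max_masses = []
        for signs in itertools.product([1.0, -1.0], repeat=4):
            t_f, _ = group_tmap(maps * np.array(signs)[:, None, None])
            cl = find_clusters(t_f, 3, 0.05, np.zeros((1, 1), bool))
            max_masses.append(max((c.mass for c in cl), default=0.0))
        max_masses = np.array(max_masses)
        for c in clusters:
            assert c.p_perm == pytest.approx((max_masses >= c.mass - 1e-9).sum() / 16.0)

    def test_smoothing_uses_given_kernel_width(self):
        series = np.zeros((5, 41))
        series[:, 20] = 1.0
        _, t_sharp = coefficient_timecourse_test(series + 1e-6, step_ms=2.0, smooth_sd_ms=0.0, n_perm=100, seed=0)
        # an impulse cannot produce a finite t (zero variance); smoothed it can
        series = np.random.default_rng(12).normal(size=(5, 41))
        _, t_smooth = coefficient_timecourse_test(series, step_ms=2.0, smooth_sd_ms=8.0, n_perm=100, seed=0)
        # 8 ms SD at 2 ms steps shrinks window-to-window variability
        assert np.std(np.diff(t_smooth)) < np.std(np.diff(coefficient_timecourse_test(series, step_ms=2.0, smooth_sd_ms=0.0, n_perm=100, seed=0)[1]))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            coefficient_timecourse_test(np.zeros((2, 10)), step_ms=2.0)


class TestBinnedLearningRates:
    def test_fixed_learning_rate_flat_profile(self):
        rng = np.random.default_rng(13)
        n = 600
        delta = rng.uniform(-np.pi, np.pi, size=n)
        update = 0.5 * delta
        strength = rng.normal(size=n)
        condition = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        table = binned_learning_rates(update, delta, strength, condition)
        np.testing.assert_allclose(table["slope"], 0.5, atol=1e-10)
        assert len(table) == 10  # 5 bins x 2 conditions

    def test_conditional_coupling_gives_opposite_trends(self):
        rng = np.random.default_rng(14)
        n = 4000
        delta = rng.uniform(-np.pi, np.pi, size=n)
        condition = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        strength = rng.normal(size=n)
        update = (0.5 + 0.2 * strength * condition) * delta + rng.normal(0, 0.05, size=n)
        table = binned_learning_rates(update, delta, strength, condition)
        cp = table[table["condition"] == 1.0].sort_values("bin")["slope"].to_numpy()
        odd = table[table["condition"] == -1.0].sort_values("bin")["slope"].to_numpy()
        assert cp[-1] > cp[0]
        assert odd[-1] < odd[0]

    def test_shuffled_strength_flat(self):
        rng = np.random.default_rng(15)
        n = 4000
        delta = rng.uniform(-np.pi, np.pi, size=n)
        condition = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        strength = rng.normal(size=n)
        update = (0.5 + 0.2 * strength * condition) * delta + rng.normal(0, 0.05, size=n)
        shuffled = rng.permutation(strength)
        table = binned_learning_rates(update, delta, shuffled, condition)
        spread = table.groupby("condition")["slope"].agg(lambda s: s.max() - s.min())
        assert (spread < 0.1).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            binned_learning_rates(np.zeros(20), np.zeros(20), np.zeros(20), np.ones(20))
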