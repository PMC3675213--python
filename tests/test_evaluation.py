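"""Cross-validation protocol: bookkeeping, determinism, leakage structure,
chance-level calibration and the paired tests."""

import numpy as np
import pytest

from sensebci import (CVReport, band_time_grid, baseline_vs_taskline,
                      chance_band, cv_chance_band, generate_null_session,
                      improvement_test, paired_accuracy_ttest, repeated_kfold,
                      ParadigmSpec)


class TestRepeatedKFold:
    def test_emits_25_accuracies(self, session_small_strong):
        rep = repeated_kfold(session_small_strong, seed=0)
        assert rep.accuracies.shape == (25,)
        assert rep.as_matrix().shape == (5, 5)
        assert np.all((rep.accuracies >= 0) & (rep.accuracies <= 1))

    def test_folds_partition_trials_without_leakage(self, session_small_strong):
        """Every fold's train and test sets are disjoint, the test sets of one
        repeat cover all trials exactly once, and folds stay class-balanced."""
        rep = repeated_kfold(session_small_strong, seed=1)
        n = session_small_strong.n_trials
        labels = session_small_strong.labels
        for r in range(rep.n_repeats):
            seen = []
            for f in range(rep.n_folds):
                k = r * rep.n_folds + f
                train = rep.fold_train_indices[k]
                test = rep.fold_test_indices[k]
                assert np.intersect1d(train, test).size == 0
                assert np.union1d(train, test).size == n
                # stratification: both classes present in proportion
                n_left = (labels[test] == "left").sum()
                assert abs(n_left - len(test) / 2) <= 1
                seen.append(test)
            assert np.array_equal(np.sort(np.concatenate(seen)), np.arange(n))

    def test_fixed_seed_reproducible(self, session_small_strong, session_small_null):
        a = repeated_kfold(session_small_strong, seed=7)
        b = repeated_kfold(session_small_strong, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)
        # seed changes the partitioning; visible on a chance-level session
        c = repeated_kfold(session_small_null, seed=7)
        d = repeated_kfold(session_small_null, seed=8)
        assert not np.array_equal(c.accuracies, d.accuracies)

    def test_strong_effect_recovered(self, session_small_strong):
        rep = repeated_kfold(session_small_strong, seed=0)
        assert rep.mean >= 0.9

    def test_null_session_at_chance(self, session_small_null):
        rep = repeated_kfold(session_small_null, seed=0)
        lo, hi = cv_chance_band(session_small_null.n_trials)
        assert lo <= rep.mean <= hi

    def test_too_few_trials_per_class_rejected(self, session_small_strong):
        with pytest.raises(ValueError, match="partitions"):
            repeated_kfold(session_small_strong, n_folds=13, seed=0)

    def test_chance_calibration_over_null_sessions(self):
        """Across independent null sessions the CV mean rarely leaves the 95%
        binomial chance band (fold correlation makes the bound loose)."""
        para = ParadigmSpec(n_channels=6, n_runs=2, trials_per_run=12)
        lo, hi = chance_band(para.n_trials)
        outside = 0
        n_rep = 25
        for r in range(n_rep):
            s = generate_null_session(para, 1000 + r)
            m = repeated_kfold(s, seed=r).mean
            outside += not (lo <= m <= hi)
        assert outside / n_rep <= 0.10


class TestBaselineVsTaskline:
    def test_effectful_session_beats_its_baseline(self, session_small_strong):
        comp = baseline_vs_taskline(session_small_strong, seed=0)
        lo, hi = cv_chance_band(session_small_strong.n_trials)
        assert comp.taskline.mean > comp.baseline.mean
        assert lo <= comp.baseline.mean <= hi
        assert comp.p_value < 0.01

    def test_null_session_flat_everywhere(self, session_small_null):
        comp = baseline_vs_taskline(session_small_null, seed=0)
        lo, hi = cv_chance_band(session_small_null.n_trials)
        assert lo <= comp.baseline.mean <= hi
        assert lo <= comp.taskline.mean <= hi

    def test_identical_windows_give_p_one(self, session_small_strong):
        comp = baseline_vs_taskline(session_small_strong, seed=0,
                                    task_window=(4.0, 7.0),
                                    baseline_window=(4.0, 7.0))
        assert comp.p_value == 1.0
        assert comp.mean_difference == 0.0


class TestGrid:
    def test_small_grid_shape_and_argmax(self, session_small_strong):
        result = band_time_grid(session_small_strong,
                                bands=["alpha", "beta"],
                                windows_post_cue=[(1, 2), (1, 4)],
                                n_repeats=2, seed=0)
        assert result.accuracy_matrix.shape == (2, 2)
        best = result.accuracy_matrix.max()
        i = [b.name for b in result.bands].index(result.best_band.name)
        j = result.windows_post_cue.index(result.best_window_post_cue)
        assert result.accuracy_matrix[i, j] == best

    def test_tie_breaks_prefer_longer_window_then_lower_band(self, session_small_null):
        # constant-accuracy degenerate case: force ties by evaluating a single
        # fold/repeat on a null session twice with the same window lengths
        result = band_time_grid(session_small_null, bands=["alpha", "beta"],
                                windows_post_cue=[(1, 2), (3, 4)],
                                n_repeats=1, seed=0)
        ties = np.isclose(result.accuracy_matrix, result.accuracy_matrix.max())
        if ties.sum() > 1:  # tie actually occurred: check preference order
            best_len = result.best_window_post_cue[1] - result.best_window_post_cue[0]
            for i, j in zip(*np.nonzero(ties)):
                w = result.windows_post_cue[j]
                assert best_len >= w[1] - w[0]

    def test_window_outside_trial_rejected(self, session_small_strong):
        with pytest.raises(ValueError):
            band_time_grid(session_small_strong, bands=["alpha"],
                           windows_post_cue=[(4, 6)], n_repeats=1, seed=0)


class TestPairedTests:
    def _report(self, accs):
        accs = np.asarray(accs, dtype=float)
        return CVReport(accuracies=accs, n_repeats=5, n_folds=5, seed=0)

    def test_identical_reports(self):
        a = self._report(np.linspace(0.6, 0.9, 25))
        res = improvement_test(a, self._report(a.accuracies.copy()))
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0

    def test_constant_shift(self):
        base = np.linspace(0.6, 0.9, 25)
        res = improvement_test(self._report(base + 0.05), self._report(base))
        assert res.mean_difference == pytest.approx(0.05)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            paired_accuracy_ttest(np.zeros(25), np.zeros(10))

    def test_p_uniform_under_null(self):
        """Independent same-distribution accuracy vectors: the paired p-value
        is uniform over repetitions (KS check, fixed seed)."""
        from scipy import stats
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            a = rng.normal(0.7, 0.05, size=25)
            b = rng.normal(0.7, 0.05, size=25)
            ps.append(paired_accuracy_ttest(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3
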