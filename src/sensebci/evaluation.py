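"""Offline evaluation: repeated cross-validation, the baseline-vs-task
control, and the time-segment x frequency-band optimization grid.

The canonical protocol is 5-repeat x 5-fold cross-validation: each
repeat randomly permutes the trials, splits them into five
class-stratified partitions, and scores each partition with a
band-pass -> window -> CSP -> LDA pipeline fit on the other four,
yielding 25 accuracies. CSP and LDA are refit inside every fold, so no
test trial ever influences its own model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .csp import features_from_covariances, fit_csp, normalized_covariance
from .lda import fit_lda, predict
from .preprocessing import BAND_PRESETS, BandSpec, bandpass, extract_window, get_band
from .session import CLASS_LABELS, EpochedSession

#: the ten analysis windows, in seconds after the cue
GRID_WINDOWS_POST_CUE: tuple[tuple[float, float], ...] = (
    (1, 2), (1, 3), (1, 4), (1, 5),
    (2, 3), (2, 4), (2, 5),
    (3, 4), (3, 5),
    (4, 5),
)

#: band presets evaluated by the grid, in canonical order
GRID_BANDS: tuple[str, ...] = (
    "lower_alpha", "upper_alpha", "alpha", "lower_beta", "upper_beta", "beta", "broad",
)


@dataclass
class CVReport:
    """The accuracies of one repeated k-fold run plus its bookkeeping."""

    accuracies: np.ndarray  # flat, length n_repeats * n_folds, repeat-major
    n_repeats: int
    n_folds: int
    seed: int
    fold_test_indices: list = field(default_factory=list, repr=False)
    fold_train_indices: list = field(default_factory=list, repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    def as_matrix(self) -> np.ndarray:
        return self.accuracies.reshape(self.n_repeats, self.n_folds)


def chance_band(n_test_trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided binomial band around 0.5 for an accuracy over
    ``n_test_trials`` independent chance-level decisions."""
    lo = stats.binom.ppf(alpha / 2, n_test_trials, 0.5) / n_test_trials
    hi = stats.binom.ppf(1 - alpha / 2, n_test_trials, 0.5) / n_test_trials
    return float(lo), float(hi)


def cv_chance_band(n_trials: int, n_folds: int = 5,
                   alpha: float = 0.05) -> tuple[float, float]:
    """Chance band for the *mean* of a repeated k-fold CV on null data.

    Fold accuracies are strongly correlated (they share training data and
    the classifier's noise-fit direction), so the appropriate loose bound
    uses the size of one test partition, not the whole session: the
    binomial band for ``n_trials / n_folds`` decisions. Empirically the
    session-to-session spread of the CV mean on exchangeable data lies
    between the per-session and per-fold binomial widths; this band is
    the conservative side for a single-session at-chance check.
    """
    return chance_band(max(int(round(n_trials / n_folds)), 1), alpha)


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Random class-stratified partition: a list of test-index arrays."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < n_folds:
            raise ValueError(
                f"class {c!r} has {idx.size} trials; cannot fill {n_folds} partitions"
            )
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def _trial_covariances(session: EpochedSession, band: BandSpec | str,
                       window: tuple[float, float]):
    """Filter + window once, then cache per-trial covariances.

    Returns (normalized covs for CSP fitting, raw /N covs for the
    log-variance features, labels).
    """
    win = extract_window(bandpass(session, band), *window)
    n = win.n_trials
    covs_norm = np.empty((n, win.n_channels, win.n_channels))
    covs_raw = np.empty_like(covs_norm)
    for i in range(n):
        X = win.data[i]
        Xc = X - X.mean(axis=1, keepdims=True)
        covs_raw[i] = (Xc @ Xc.T) / win.n_samples  # centered: row variances
        covs_norm[i] = normalized_covariance(X)
    return covs_norm, covs_raw, win.labels


def _fit_and_score(covs_norm, covs_raw, labels, train_idx, test_idx,
                   n_pairs: int) -> float:
    C1 = covs_norm[train_idx][labels[train_idx] == CLASS_LABELS[0]].mean(axis=0)
    C2 = covs_norm[train_idx][labels[train_idx] == CLASS_LABELS[1]].mean(axis=0)
    model = fit_csp(C1, C2, n_pairs=n_pairs)
    feats_train = features_from_covariances(model, covs_raw[train_idx])
    clf = fit_lda(feats_train, labels[train_idx])
    feats_test = features_from_covariances(model, covs_raw[test_idx])
    pred, _ = predict(clf, feats_test)
    return float(np.mean(pred == labels[test_idx]))


def repeated_kfold(session: EpochedSession, band: BandSpec | str = "broad",
                   window: tuple[float, float] = (4.0, 7.0),
                   n_folds: int = 5, n_repeats: int = 5, seed: int = 0,
                   n_pairs: int = 3) -> CVReport:
    """Repeated stratified k-fold CV of the full decoding pipeline.

    Every fold refits CSP and LDA on its own training partition only.
    Deterministic for a fixed seed; the defaults produce the 25
    accuracies (5 repeats x 5 folds) used for statistical evaluation.
    """
    covs_norm, covs_raw, labels = _trial_covariances(session, band, window)
    report = CVReport(
        accuracies=np.empty(n_repeats * n_folds),
        n_repeats=n_repeats, n_folds=n_folds, seed=int(seed),
    )
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                           spawn_key=(r,)))
        folds = _stratified_folds(labels, n_folds, rng)
        all_idx = np.arange(labels.shape[0])
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            acc = _fit_and_score(covs_norm, covs_raw, labels,
                                 train_idx, test_idx, n_pairs)
            report.accuracies[r * n_folds + f] = acc
            report.fold_train_indices.append(train_idx)
            report.fold_test_indices.append(test_idx)
    return report


@dataclass
class BaselineComparison:
    baseline: CVReport
    taskline: CVReport
    t_statistic: float
    p_value: float

    @property
    def mean_difference(self) -> float:
        return self.taskline.mean - self.baseline.mean


def paired_accuracy_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test over matched accuracy vectors.

    Zero-variance differences are guarded: identical vectors give
    (0, 1); a constant nonzero shift gives (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must have equal length")
    d = a - b
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def baseline_vs_taskline(session: EpochedSession, band: BandSpec | str = "broad",
                         seed: int = 0,
                         task_window: tuple[float, float] = (4.0, 7.0),
                         baseline_window: tuple[float, float] = (1.0, 3.0),
                         n_folds: int = 5, n_repeats: int = 5,
                         n_pairs: int = 3) -> BaselineComparison:
    """CV the pre-cue baseline window against the task window.

    The baseline should decode at chance (no task yet), the task window
    above it; the paired t-test quantifies the contrast over the 25
    matched fold accuracies (identical partitions in both runs).
    """
    base = repeated_kfold(session, band, baseline_window, n_folds=n_folds,
                          n_repeats=n_repeats, seed=seed, n_pairs=n_pairs)
    task = repeated_kfold(session, band, task_window, n_folds=n_folds,
                          n_repeats=n_repeats, seed=seed, n_pairs=n_pairs)
    t, p = paired_accuracy_ttest(task.accuracies, base.accuracies)
    return BaselineComparison(baseline=base, taskline=task,
                              t_statistic=t, p_value=p)


@dataclass
class GridResult:
    """Mean CV accuracy over every band x window cell."""

    bands: list[BandSpec]
    windows_post_cue: list[tuple[float, float]]
    accuracy_matrix: np.ndarray  # (n_bands, n_windows)
    best_band: BandSpec
    best_window_post_cue: tuple[float, float]
    cue_onset_s: float

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy_matrix.max())


def band_time_grid(session: EpochedSession,
                   bands: list[BandSpec | str] | None = None,
                   windows_post_cue: list[tuple[float, float]] | None = None,
                   n_folds: int = 5, n_repeats: int = 5, seed: int = 0,
                   n_pairs: int = 3, cue_onset_s: float | None = None) -> GridResult:
    """Evaluate mean CV accuracy over all band x time-window cells.

    Windows are given in seconds after the cue and mapped to trial time
    by adding the cue onset. The best cell attains the matrix maximum;
    ties are broken toward the longer window, then the lower band.
    """
    band_specs = [get_band(b) for b in (bands if bands is not None else GRID_BANDS)]
    windows = [tuple(w) for w in (windows_post_cue if windows_post_cue is not None
                                  else GRID_WINDOWS_POST_CUE)]
    if cue_onset_s is None:
        cue_onset_s = float(session.meta.get("paradigm", {}).get("cue_onset_s", 3.0))

    acc = np.empty((len(band_specs), len(windows)))
    for i, band in enumerate(band_specs):
        for j, (w0, w1) in enumerate(windows):
            rep = repeated_kfold(session, band,
                                 (w0 + cue_onset_s, w1 + cue_onset_s),
                                 n_folds=n_folds, n_repeats=n_repeats,
                                 seed=seed, n_pairs=n_pairs)
            acc[i, j] = rep.mean

    best = acc.max()
    candidates = [
        (i, j) for i in range(len(band_specs)) for j in range(len(windows))
        if acc[i, j] >= best - 1e-12
    ]
    candidates.sort(key=lambda ij: (
        -(windows[ij[1]][1] - windows[ij[1]][0]),  # longer window first
        band_specs[ij[0]].low_hz, band_specs[ij[0]].high_hz,
        ij[1],
    ))
    bi, bj = candidates[0]
    return GridResult(bands=band_specs, windows_post_cue=windows,
                      accuracy_matrix=acc, best_band=band_specs[bi],
                      best_window_post_cue=windows[bj], cue_onset_s=cue_onset_s)


@dataclass
class ImprovementTest:
    t_statistic: float
    p_value: float
    mean_difference: float


def improvement_test(selected: CVReport, common: CVReport) -> ImprovementTest:
    """Paired t-test: does the individually selected band/window beat the
    common 8-26 Hz, 1-4 s post-cue configuration?"""
    t, p = paired_accuracy_ttest(selected.accuracies, common.accuracies)
    return ImprovementTest(t_statistic=t, p_value=p,
                           mean_difference=float(np.mean(selected.accuracies)
                                                 - np.mean(common.accuracies)))
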