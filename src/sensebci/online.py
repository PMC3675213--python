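"""Simulated online feedback session with per-trial adaptation.

Reproduces the adaptive protocol of the feedback experiment: run 1 is
calibration only (no predictions); from run 2 onward every trial is
classified prospectively by a CSP + LDA pipeline retrained on all
trials of the previous run plus the already-revealed trials of the
current run. Prediction for trial k of run r therefore uses exactly
``trials_per_run + (k - 1)`` training trials, and can never depend on
the current or any future trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csp import features_from_covariances, fit_csp
from .evaluation import _trial_covariances
from .lda import fit_lda, predict
from .preprocessing import BandSpec
from .session import CLASS_LABELS, EpochedSession


@dataclass
class OnlineTrace:
    """Per-trial record of the simulated online session."""

    records: pd.DataFrame  # trial_index, run_index, k_in_run, training_set_size,
    #                        predicted_label, true_label, score
    run_accuracy: dict[int, float] = field(default_factory=dict)

    @property
    def n_predictions(self) -> int:
        return len(self.records)

    @property
    def overall_accuracy(self) -> float:
        return float((self.records.predicted_label == self.records.true_label).mean())


def simulate_online(session: EpochedSession, band: BandSpec | str = "broad",
                    window: tuple[float, float] = (4.0, 7.0),
                    n_pairs: int = 3) -> OnlineTrace:
    """Replay a session through the per-trial adaptation protocol.

    Trials are visited in chronological (run, within-run) order. The
    procedure is fully deterministic given the session: it involves no
    random choices. Raises if any training set lacks one of the two
    classes, naming the offending trial.
    """
    runs = session.runs
    if runs.size < 2:
        raise ValueError("online simulation needs at least two runs")
    run_trials = {r: np.flatnonzero(session.run_index == r) for r in runs}
    sizes = {r: idx.size for r, idx in run_trials.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"runs have unequal trial counts: {sizes}")

    covs_norm, covs_raw, labels = _trial_covariances(session, band, window)

    rows = []
    for ri in range(1, runs.size):
        run = runs[ri]
        prev = run_trials[runs[ri - 1]]
        cur = run_trials[run]
        for k, trial in enumerate(cur):
            train_idx = np.concatenate([prev, cur[:k]])
            for c in CLASS_LABELS:
                if not np.any(labels[train_idx] == c):
                    raise ValueError(
                        f"training set for trial {trial} (run {run}) has no "
                        f"{c!r} trials"
                    )
            C1 = covs_norm[train_idx][labels[train_idx] == CLASS_LABELS[0]].mean(axis=0)
            C2 = covs_norm[train_idx][labels[train_idx] == CLASS_LABELS[1]].mean(axis=0)
            model = fit_csp(C1, C2, n_pairs=n_pairs)
            clf = fit_lda(features_from_covariances(model, covs_raw[train_idx]),
                          labels[train_idx])
            pred, score = predict(clf, features_from_covariances(
                model, covs_raw[trial:trial + 1]))
            rows.append({
                "trial_index": int(trial),
                "run_index": int(run),
                "k_in_run": k + 1,
                "training_set_size": int(train_idx.size),
                "predicted_label": str(pred[0]),
                "true_label": str(labels[trial]),
                "score": float(score[0]),
            })

    records = pd.DataFrame(rows)
    run_accuracy = {
        int(r): float((grp.predicted_label == grp.true_label).mean())
        for r, grp in records.groupby("run_index")
    }
    return OnlineTrace(records=records, run_accuracy=run_accuracy)
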