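"""Epoched EEG session container.

The whole pipeline operates on :class:`EpochedSession`: a dense
``trials x channels x samples`` tensor with per-trial class labels
("left" / "right"), per-trial run indices, the sampling rate and a
trial-relative time axis. Sessions are produced by the synthetic
generator (:mod:`sensebci.synthetic`) or read from disk
(:mod:`sensebci.io`); preprocessing steps return new sessions and never
mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CLASS_LEFT = "left"
CLASS_RIGHT = "right"
CLASS_LABELS = (CLASS_LEFT, CLASS_RIGHT)


@dataclass
class EpochedSession:
    """Labeled trial tensor with its acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitudes in arbitrary microvolt-scale units.
    labels : ndarray of str, shape (n_trials,)
        Per-trial class, each ``"left"`` or ``"right"``.
    run_index : ndarray of int, shape (n_trials,)
        Which run each trial belongs to (1-based, chronological).
    fs_hz : float
        Sampling rate.
    times_s : ndarray, shape (n_samples,)
        Trial-relative time of every sample.
    channel_names : list of str
    meta : dict
        Provenance (generator config, seed, processing history).
    """

    data: np.ndarray
    labels: np.ndarray
    run_index: np.ndarray
    fs_hz: float
    times_s: np.ndarray
    channel_names: Sequence[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.run_index = np.asarray(self.run_index, dtype=int)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        n_trials, n_channels, n_samples = self.data.shape
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length does not match trial count")
        if self.run_index.shape != (n_trials,):
            raise ValueError("run_index length does not match trial count")
        if self.times_s.shape != (n_samples,):
            raise ValueError("times_s length does not match sample count")
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length does not match channel count")
        bad = set(np.unique(self.labels)) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def runs(self) -> np.ndarray:
        """Sorted unique run indices."""
        return np.unique(self.run_index)

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def copy(self) -> "EpochedSession":
        return EpochedSession(
            data=self.data.copy(),
            labels=self.labels.copy(),
            run_index=self.run_index.copy(),
            fs_hz=self.fs_hz,
            times_s=self.times_s.copy(),
            channel_names=list(self.channel_names),
            meta=dict(self.meta),
        )

    def with_data(self, data: np.ndarray, times_s: np.ndarray | None = None) -> "EpochedSession":
        """New session sharing labels/metadata but holding different samples."""
        return replace(
            self,
            data=data,
            times_s=self.times_s if times_s is None else times_s,
            meta=dict(self.meta),
        )
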