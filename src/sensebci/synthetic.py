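"""Paradigm-faithful synthetic EEG generator.

Emulates a two-class selective-sensation / motor-imagery style session:
8 s trials sampled at 250 Hz, cue at 3 s, task window 4-7 s, baseline
1-3 s, four runs of 40 class-balanced trials (80 per class). The
discriminative signal is event-related desynchronization (ERD): during
the task window the narrow-band oscillatory source contralateral to the
attended side is attenuated by a fractional depth, while the baseline
carries no class information.

Generative model
----------------
Two band-limited oscillatory sources (one per hemisphere; band-pass
filtered white noise in the effect band) are mixed linearly to channels
through fixed Gaussian spatial profiles centered on configurable
"source channels" (synthetic analogs of C3/C4), on top of independent
1/f^beta background noise per channel. ERD is a multiplicative
amplitude scaling ``1 - erd_depth`` of the contralateral source inside
the task window, with 100 ms cosine ramps to avoid spectral splatter.
This is the minimal structure under which CSP is the matched decoder.

Randomness: a single integer seed expands into independent per-trial
streams (``SeedSequence`` spawn keys), so changing the trial count never
shifts the noise realization of earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import CLASS_LEFT, CLASS_RIGHT, EpochedSession

_STREAM_LABELS = 1
_STREAM_TRIAL = 2

#: width (in channel-index units) of the Gaussian spatial mixing profile
_MIX_SIGMA = 2.0
#: cosine ramp length applied to the ERD envelope, seconds
_ERD_RAMP_S = 0.1


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and counting structure of one recording session.

    Defaults mirror the vibrotactile selective-sensation paradigm:
    250 Hz sampling, 8 s trials with the directional cue at 3 s, the
    decoded task interval 4-7 s, a 1-3 s pre-cue baseline, and four runs
    of 40 class-balanced trials.
    """

    sampling_rate_hz: float = 250.0
    trial_len_s: float = 8.0
    cue_onset_s: float = 3.0
    task_window_s: tuple[float, float] = (4.0, 7.0)
    baseline_window_s: tuple[float, float] = (1.0, 3.0)
    n_runs: int = 4
    trials_per_run: int = 40
    n_channels: int = 22

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.trial_len_s <= 0:
            raise ValueError("sampling rate and trial length must be positive")
        t0, t1 = self.task_window_s
        b0, b1 = self.baseline_window_s
        if not (0 <= t0 < t1 <= self.trial_len_s):
            raise ValueError(f"task window {self.task_window_s} outside trial [0, {self.trial_len_s}]")
        if not (0 <= b0 < b1):
            raise ValueError(f"baseline window {self.baseline_window_s} is not an ordered pair")
        if b1 > self.cue_onset_s:
            raise ValueError("baseline window must end no later than the cue onset")
        if self.n_runs < 1 or self.trials_per_run < 2:
            raise ValueError("need at least one run of at least two trials")
        if self.trials_per_run % 2:
            raise ValueError("trials_per_run must be even so every run is class-balanced")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")

    @property
    def n_samples(self) -> int:
        n = self.trial_len_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_len_s * sampling_rate_hz must be an integer sample count")
        return int(round(n))

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


def default_source_channels(n_channels: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Default left-/right-hemisphere source channel indices (C3/C4 analogs)."""
    return ((n_channels // 4,), (3 * n_channels // 4,))


@dataclass(frozen=True)
class EffectSpec:
    """Class-dependent ERD effect injected into the synthetic session.

    ``erd_depth`` is the fractional amplitude attenuation of the source
    contralateral to the attended side during the task window; 0 yields
    a null session in which labels are exchangeable. ``snr_scale``
    scales the oscillatory sources relative to the unit-variance 1/f^beta
    channel noise.
    """

    effect_band_hz: tuple[float, float] = (10.0, 13.0)
    erd_depth: float = 0.6
    source_channels: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    noise_exponent: float = 1.0
    snr_scale: float = 1.0
    #: optional slow linear gain drift across the session (+/- half this
    #: fraction at the first/last trial) to stress online adaptation
    amplitude_drift: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.effect_band_hz
        if not (0 < lo < hi):
            raise ValueError(f"effect band {self.effect_band_hz} is not an ordered positive pair")
        if not (0 <= self.erd_depth < 1):
            raise ValueError(f"erd_depth must lie in [0, 1), got {self.erd_depth}")
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be positive")

    def resolved_sources(self, n_channels: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
        src = self.source_channels
        if src is None:
            src = default_source_channels(n_channels)
        for side in src:
            for c in side:
                if not 0 <= c < n_channels:
                    raise ValueError(f"source channel {c} out of range for {n_channels} channels")
        return src


def _trial_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, index)))


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise per channel via spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-beta / 2.0)
    shape[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _mixing_matrix(n_channels: int,
                   sources: tuple[tuple[int, ...], tuple[int, ...]]) -> np.ndarray:
    """(n_channels x 2) Gaussian spatial profiles, one column per hemisphere."""
    chan = np.arange(n_channels)[:, None]
    cols = []
    for side in sources:
        centers = np.asarray(side)[None, :]
        prof = np.exp(-((chan - centers) ** 2) / (2.0 * _MIX_SIGMA**2)).sum(axis=1)
        cols.append(prof / prof.max())
    return np.stack(cols, axis=1)


def _erd_envelope(times: np.ndarray, window: tuple[float, float],
                  depth: float, fs: float) -> np.ndarray:
    """Amplitude envelope: 1 outside the task window, 1-depth inside, cosine ramps."""
    env = np.ones_like(times)
    if depth == 0:
        return env
    t0, t1 = window
    ramp = _ERD_RAMP_S
    inside = (times >= t0) & (times < t1)
    env[inside] = 1.0 - depth
    for t_edge, rising in ((t0, True), (t1, False)):
        sel = (times >= t_edge - ramp / 2) & (times < t_edge + ramp / 2)
        phase = (times[sel] - (t_edge - ramp / 2)) / ramp  # 0..1 across the ramp
        half = 0.5 * (1 + np.cos(np.pi * phase))  # 1 -> 0
        env[sel] = 1.0 - depth * (1 - half if rising else half)
    return env


def _band_sos(band: tuple[float, float], fs: float):
    return signal.butter(4, band, btype="bandpass", fs=fs, output="sos")


def generate_session(paradigm: ParadigmSpec, effect: EffectSpec, seed: int) -> EpochedSession:
    """Generate one epoched session with a known ERD class contrast.

    Deterministic for a fixed seed; per-trial noise streams are
    independent of the total trial count. The effect is applied only
    inside the task window, so baseline segments carry no class
    information by construction.
    """
    fs = paradigm.sampling_rate_hz
    n_samples = paradigm.n_samples
    times = np.arange(n_samples) / fs
    sources = effect.resolved_sources(paradigm.n_channels)
    A = _mixing_matrix(paradigm.n_channels, sources)
    sos = _band_sos(effect.effect_band_hz, fs)
    env_att = _erd_envelope(times, paradigm.task_window_s, effect.erd_depth, fs)

    labels = np.empty(paradigm.n_trials, dtype="U5")
    run_index = np.empty(paradigm.n_trials, dtype=int)
    data = np.empty((paradigm.n_trials, paradigm.n_channels, n_samples))

    half = paradigm.trials_per_run // 2
    for run in range(paradigm.n_runs):
        run_labels = np.array([CLASS_LEFT] * half + [CLASS_RIGHT] * half)
        _trial_rng(seed, _STREAM_LABELS, run).shuffle(run_labels)
        sl = slice(run * paradigm.trials_per_run, (run + 1) * paradigm.trials_per_run)
        labels[sl] = run_labels
        run_index[sl] = run + 1

    # sources are filtered with 1 s padding on both sides and cropped, so
    # their band power is stationary across the whole trial (no filter
    # warm-up transients at the epoch edges)
    pad = int(round(fs))
    for t in range(paradigm.n_trials):
        rng = _trial_rng(seed, _STREAM_TRIAL, t)
        raw = rng.standard_normal((2, n_samples + 2 * pad))
        src = signal.sosfiltfilt(sos, raw, axis=-1)[:, pad:pad + n_samples]
        src /= src.std(axis=-1, keepdims=True)
        # attend left -> ERD in the right hemisphere source (index 1) and
        # vice versa: the contralateral source is attenuated.
        att_src = 1 if labels[t] == CLASS_LEFT else 0
        env = np.ones((2, n_samples))
        env[att_src] = env_att
        noise = _one_over_f_noise(rng, paradigm.n_channels, n_samples, fs,
                                  effect.noise_exponent)
        gain = 1.0
        if effect.amplitude_drift and paradigm.n_trials > 1:
            frac = t / (paradigm.n_trials - 1) - 0.5
            gain = 1.0 + effect.amplitude_drift * frac
        data[t] = gain * (effect.snr_scale * (A @ (src * env)) + noise)

    return EpochedSession(
        data=data,
        labels=labels,
        run_index=run_index,
        fs_hz=fs,
        times_s=times,
        channel_names=[f"ch{i:02d}" for i in range(paradigm.n_channels)],
        meta={
            "generator": "sensebci.synthetic.generate_session",
            "seed": int(seed),
            "paradigm": paradigm.__dict__ | {},
            "effect": {
                "effect_band_hz": list(effect.effect_band_hz),
                "erd_depth": effect.erd_depth,
                "source_channels": [list(s) for s in sources],
                "noise_exponent": effect.noise_exponent,
                "snr_scale": effect.snr_scale,
            },
        },
    )


def generate_null_session(paradigm: ParadigmSpec, seed: int,
                          effect: EffectSpec | None = None) -> EpochedSession:
    """Session with zero ERD depth: labels carry no information about the data."""
    base = effect if effect is not None else EffectSpec()
    null = EffectSpec(
        effect_band_hz=base.effect_band_hz,
        erd_depth=0.0,
        source_channels=base.source_channels,
        noise_exponent=base.noise_exponent,
        snr_scale=base.snr_scale,
        amplitude_drift=base.amplitude_drift,
    )
    return generate_session(paradigm, null, seed)


def inject_burst(session: EpochedSession, channel: int, f0_hz: float,
                 t_window_s: tuple[float, float], amplitude: float) -> EpochedSession:
    """Add a pure sinusoidal burst to every trial at one channel.

    A ground-truth fixture for time-frequency localization tests: the
    burst occupies exactly ``t_window_s`` at frequency ``f0_hz``. The
    operation is linear in ``amplitude`` and leaves the input untouched.
    """
    if not 0 <= channel < session.n_channels:
        raise ValueError(f"channel {channel} out of range")
    if f0_hz >= session.fs_hz / 2:
        raise ValueError(f"burst frequency {f0_hz} Hz is at or above Nyquist "
                         f"({session.fs_hz / 2} Hz)")
    t0, t1 = t_window_s
    times = session.times_s
    if not (times[0] <= t0 < t1 <= times[-1] + 1.0 / session.fs_hz):
        raise ValueError(f"burst window {t_window_s} outside trial span")
    out = session.copy()
    sel = (times >= t0) & (times < t1)
    burst = amplitude * np.sin(2 * np.pi * f0_hz * times[sel])
    out.data[:, channel, sel] += burst[None, :]
    return out
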