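"""Event-related spectral perturbation (ERSP) with bootstrap masking.

Power is estimated every 200 ms by complex convolution with
Hanning-tapered sinusoid wavelets whose cycle count grows linearly with
frequency (short wavelets at low frequencies for time resolution,
longer ones at high frequencies for frequency resolution). Trial-mean
power is expressed relative to the mean pre-cue baseline power per
frequency, in dB by default:

    ERSP(t, f) = 10 log10( P(t, f) / mean_{t' in baseline} P(t', f) ).

Significance is assessed per frequency by a surrogate bootstrap: for
each resample, one baseline time point is drawn per resampled trial and
the surrogate trial-mean powers form a null distribution; observed
cells outside its central 1 - alpha quantile band are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .session import EpochedSession

_MIN_TRIALS_BOOT = 10


@dataclass
class ERSPMap:
    """Time x frequency relative power change for one channel."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power_change: np.ndarray  # (n_times, n_freqs), dB or ratio
    sig_mask: np.ndarray | None
    channel: int
    baseline_window_s: tuple[float, float]
    mode: str = "dB"
    alpha: float | None = None
    n_boot: int | None = None
    # per-trial power at the grid points, kept for the bootstrap
    trial_power: np.ndarray | None = field(default=None, repr=False)  # (n_trials, n_times, n_freqs)

    @property
    def baseline_columns(self) -> np.ndarray:
        b0, b1 = self.baseline_window_s
        return np.flatnonzero((self.times_s >= b0) & (self.times_s < b1))


def _wavelet_bank(freqs: np.ndarray, fs: float, cycles_at_fmin: float,
                  cycles_at_fmax: float, n_samples: int):
    """Hanning-tapered complex sinusoid per frequency; cycle count
    interpolates linearly from the lowest to the highest frequency."""
    fmin, fmax = freqs[0], freqs[-1]
    if fmax > fmin:
        cycles = cycles_at_fmin + (freqs - fmin) * (cycles_at_fmax - cycles_at_fmin) / (fmax - fmin)
    else:
        cycles = np.full_like(freqs, cycles_at_fmin)
    bank = []
    for f, c in zip(freqs, cycles):
        n = int(round(c / f * fs))
        n += (n + 1) % 2  # odd length, symmetric support
        if n > n_samples:
            raise ValueError(
                f"wavelet at {f} Hz ({c:.1f} cycles, {n} samples) is longer than "
                f"the trial ({n_samples} samples); raise the lowest frequency or "
                "reduce the cycle count"
            )
        t = (np.arange(n) - n // 2) / fs
        taper = np.hanning(n)
        kern = taper * np.exp(2j * np.pi * f * t)
        kern /= np.abs(kern).sum()
        bank.append(kern)
    return bank, cycles


def compute_ersp(session: EpochedSession, channel: int, freqs_hz: np.ndarray,
                 step_s: float = 0.2, cycles_at_fmin: float = 3.0,
                 cycles_at_fmax: float = 8.0,
                 baseline_window_s: tuple[float, float] = (1.0, 3.0),
                 mode: str = "dB") -> ERSPMap:
    """Trial-averaged time-frequency power change at one channel.

    The time grid covers only instants where the longest wavelet fits
    entirely inside the trial, so edge effects never contaminate the
    map. ``mode`` is ``"dB"`` (10 log10 ratio) or ``"ratio"``.
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= session.fs_hz / 2):
        raise ValueError("frequencies must lie strictly between 0 and Nyquist")
    if mode not in ("dB", "ratio"):
        raise ValueError(f"mode must be 'dB' or 'ratio', got {mode!r}")
    fs = session.fs_hz
    bank, _ = _wavelet_bank(freqs, fs, cycles_at_fmin, cycles_at_fmax,
                            session.n_samples)
    half_max_s = max(len(k) // 2 for k in bank) / fs
    t0, t1 = session.times_s[0], session.times_s[-1]
    k_lo = int(np.ceil((t0 + half_max_s) / step_s))
    k_hi = int(np.floor((t1 - half_max_s) / step_s))
    if k_hi < k_lo:
        raise ValueError("trial too short for the requested wavelets and step")
    times = np.arange(k_lo, k_hi + 1) * step_s
    cols = np.round((times - t0) * fs).astype(int)

    b0, b1 = baseline_window_s
    if not np.any((times >= b0) & (times < b1)):
        raise ValueError(f"no grid time points fall in the baseline window {baseline_window_s}")

    x = session.data[:, channel, :]  # (n_trials, n_samples)
    n_trials = x.shape[0]
    trial_power = np.empty((n_trials, times.size, freqs.size))
    for j, kern in enumerate(bank):
        conv = signal.fftconvolve(x, kern[None, :], mode="same", axes=-1)
        trial_power[:, :, j] = np.abs(conv[:, cols]) ** 2

    mean_power = trial_power.mean(axis=0)  # (n_times, n_freqs)
    base_cols = (times >= b0) & (times < b1)
    baseline = mean_power[base_cols].mean(axis=0)  # per frequency
    ratio = mean_power / baseline[None, :]
    change = 10.0 * np.log10(ratio) if mode == "dB" else ratio

    return ERSPMap(times_s=times, freqs_hz=freqs, power_change=change,
                   sig_mask=None, channel=channel,
                   baseline_window_s=(b0, b1), mode=mode,
                   trial_power=trial_power)


def bootstrap_mask(ersp: ERSPMap, alpha: float = 0.01, n_boot: int = 1000,
                   seed: int = 0) -> np.ndarray:
    """Two-sided surrogate-bootstrap significance mask at level ``alpha``.

    Per resample and per trial, one baseline grid time is drawn (with
    trial resampling) and the surrogate trial-mean power per frequency
    is recorded; the observed trial-mean power is compared against the
    alpha/2 and 1 - alpha/2 quantiles of the ``n_boot`` surrogates.
    Sets ``ersp.sig_mask`` and returns it.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if ersp.trial_power is None:
        raise ValueError("ERSPMap does not carry per-trial power; recompute with compute_ersp")
    n_trials = ersp.trial_power.shape[0]
    if n_trials < _MIN_TRIALS_BOOT:
        raise ValueError(f"need at least {_MIN_TRIALS_BOOT} trials for the bootstrap, "
                         f"got {n_trials}")
    base_cols = ersp.baseline_columns
    rng = np.random.default_rng(seed)

    surrogate = np.empty((n_boot, ersp.freqs_hz.size))
    for b in range(n_boot):
        tr = rng.integers(0, n_trials, size=n_trials)
        tc = base_cols[rng.integers(0, base_cols.size, size=n_trials)]
        surrogate[b] = ersp.trial_power[tr, tc, :].mean(axis=0)

    lo = np.quantile(surrogate, alpha / 2, axis=0)
    hi = np.quantile(surrogate, 1 - alpha / 2, axis=0)
    observed = ersp.trial_power.mean(axis=0)
    mask = (observed < lo[None, :]) | (observed > hi[None, :])
    ersp.sig_mask = mask
    ersp.alpha = alpha
    ersp.n_boot = n_boot
    return mask
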