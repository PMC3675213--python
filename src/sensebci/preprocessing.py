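"""Band-pass filtering and analysis-window extraction.

The decoding pipeline filters whole 8 s epochs with a 4th-order
Butterworth band-pass (zero-phase by default) and only then cuts the
analysis window, so IIR edge transients fall outside the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import EpochedSession


@dataclass(frozen=True)
class BandSpec:
    """A Butterworth band-pass specification."""

    low_hz: float
    high_hz: float
    order: int = 4
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low < high, got [{self.low_hz}, {self.high_hz}]")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, fs_hz: float):
        if self.high_hz >= fs_hz / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({fs_hz / 2} Hz)"
            )
        return signal.butter(self.order, (self.low_hz, self.high_hz),
                             btype="bandpass", fs=fs_hz, output="sos")


#: The analysis bands: the canonical alpha/beta subdivisions plus the
#: broad 8-26 Hz band covering both rhythms.
BAND_PRESETS: dict[str, BandSpec] = {
    "lower_alpha": BandSpec(8.0, 10.0, name="lower_alpha"),
    "upper_alpha": BandSpec(10.0, 13.0, name="upper_alpha"),
    "alpha": BandSpec(8.0, 13.0, name="alpha"),
    "lower_beta": BandSpec(13.0, 20.0, name="lower_beta"),
    "upper_beta": BandSpec(20.0, 26.0, name="upper_beta"),
    "beta": BandSpec(13.0, 26.0, name="beta"),
    "broad": BandSpec(8.0, 26.0, name="broad"),
}


def get_band(band: BandSpec | str) -> BandSpec:
    """Resolve a band preset name, or pass a BandSpec through."""
    if isinstance(band, BandSpec):
        return band
    try:
        return BAND_PRESETS[band]
    except KeyError:
        raise KeyError(
            f"unknown band preset {band!r}; available: {sorted(BAND_PRESETS)}"
        ) from None


def bandpass(session: EpochedSession, band: BandSpec | str,
             causal: bool = False) -> EpochedSession:
    """Band-pass filter every trial and channel.

    Zero-phase forward-backward filtering by default (all analysis here
    is post hoc on complete epochs); ``causal=True`` switches to a
    single forward pass.
    """
    band = get_band(band)
    sos = band.sos(session.fs_hz)
    if causal:
        filtered = signal.sosfilt(sos, session.data, axis=-1)
    else:
        filtered = signal.sosfiltfilt(sos, session.data, axis=-1)
    out = session.with_data(np.ascontiguousarray(filtered))
    out.meta["band"] = {"low_hz": band.low_hz, "high_hz": band.high_hz,
                        "order": band.order, "name": band.name, "causal": causal}
    return out


def extract_window(session: EpochedSession, t_start_s: float,
                   t_end_s: float) -> EpochedSession:
    """Restrict every trial to the half-open window [t_start, t_end).

    Boundary sample indices are ``round(t * fs)`` relative to the
    session's own time axis, so window lengths are exact and nested
    extractions compose.
    """
    if t_end_s <= t_start_s:
        raise ValueError(f"empty window [{t_start_s}, {t_end_s})")
    fs = session.fs_hz
    t0 = session.times_s[0]
    i0 = int(round((t_start_s - t0) * fs))
    i1 = int(round((t_end_s - t0) * fs))
    if i0 < 0 or i1 > session.n_samples:
        span = (t0, t0 + session.n_samples / fs)
        raise ValueError(f"window [{t_start_s}, {t_end_s}) outside trial span {span}")
    out = session.with_data(session.data[:, :, i0:i1].copy(),
                            times_s=session.times_s[i0:i1].copy())
    out.meta["window_s"] = [t_start_s, t_end_s]
    return out
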