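"""Event-related spectral perturbation with bootstrap significance.

Power is computed every 200 ms with Hanning-tapered wavelets whose cycle
count rises linearly with frequency, expressed in dB relative to the
1-3 s pre-cue baseline, and masked at p = 0.01 by a surrogate bootstrap.
A synthetic 20 Hz burst at 4-5 s serves as ground truth.
"""

import numpy as np

from sensebci import (ParadigmSpec, bootstrap_mask, compute_ersp,
                      generate_null_session, inject_burst)

freqs = np.arange(8.0, 28.0, 2.0)
base = generate_null_session(ParadigmSpec(n_channels=6, n_runs=1,
                                          trials_per_run=40), seed=50)
session = inject_burst(base, channel=2, f0_hz=20.0, t_window_s=(4.0, 5.0),
                       amplitude=3.0)

ersp = compute_ersp(session, channel=2, freqs_hz=freqs)
mask = bootstrap_mask(ersp, alpha=0.01, n_boot=1000, seed=0)

i, j = np.unravel_index(np.argmax(ersp.power_change), ersp.power_change.shape)
print(f"map: {ersp.power_change.shape[0]} time points x "
      f"{ersp.power_change.shape[1]} frequencies, dB vs baseline")
print(f"peak power change: {ersp.power_change[i, j]:.1f} dB at "
      f"t={ersp.times_s[i]:.1f} s, f={ersp.freqs_hz[j]:g} Hz "
      "(the injected burst: 4-5 s, 20 Hz)")
print(f"significant cells at p=0.01: {mask.mean() * 100:.1f}% of the map")
burst_rows = (ersp.times_s >= 4.0) & (ersp.times_s <= 5.0)
print(f"burst cells flagged: {mask[burst_rows, j].mean() * 100:.0f}% -- "
      "away from the burst only ~1% of cells should be flagged (type-I)")
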