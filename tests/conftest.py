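"""Shared fixtures: one full-size session pair (the paradigm's study
conditions) and a small fast session pair for structural tests.

Session-scoped so the expensive full-size generations run once.
"""

import numpy as np
import pytest

from sensebci import (EffectSpec, EpochedSession, ParadigmSpec,
                      generate_null_session, generate_session, simulate_online)


@pytest.fixture(scope="session")
def paradigm_default() -> ParadigmSpec:
    return ParadigmSpec()


@pytest.fixture(scope="session")
def session_strong(paradigm_default) -> EpochedSession:
    """Full 160-trial session with a clear upper-alpha ERD contrast."""
    return generate_session(paradigm_default,
                            EffectSpec(effect_band_hz=(10.0, 13.0), erd_depth=0.6),
                            seed=1)


@pytest.fixture(scope="session")
def session_null(paradigm_default) -> EpochedSession:
    """Full 160-trial session with zero effect: labels are exchangeable."""
    return generate_null_session(paradigm_default, seed=2)


@pytest.fixture(scope="session")
def paradigm_small() -> ParadigmSpec:
    return ParadigmSpec(n_channels=8, n_runs=2, trials_per_run=12)


@pytest.fixture(scope="session")
def session_small_strong(paradigm_small) -> EpochedSession:
    return generate_session(paradigm_small, EffectSpec(erd_depth=0.6), seed=3)


@pytest.fixture(scope="session")
def session_small_null(paradigm_small) -> EpochedSession:
    return generate_null_session(paradigm_small, seed=4)


@pytest.fixture(scope="session")
def online_trace_strong(session_strong):
    return simulate_online(session_strong)


def make_session(data: np.ndarray, fs: float = 250.0,
                 labels=None, runs=None) -> EpochedSession:
    """Hand-built session around a raw tensor, for oracle tests."""
    n_trials, n_channels, n_samples = data.shape
    if labels is None:
        labels = np.array(["left", "right"] * (n_trials // 2 + 1))[:n_trials]
    if runs is None:
        runs = np.ones(n_trials, dtype=int)
    return EpochedSession(
        data=data, labels=np.asarray(labels), run_index=runs, fs_hz=fs,
        times_s=np.arange(n_samples) / fs,
        channel_names=[f"ch{i:02d}" for i in range(n_channels)],
    )
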