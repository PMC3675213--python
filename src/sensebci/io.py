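"""Session container I/O, run configuration and the end-to-end workflow.

Sessions round-trip through a single ``.npz`` array container with a
JSON metadata record embedded alongside the arrays (self-describing: the
generating config and seed travel with the data). Run configurations
are flat key-value YAML/JSON files mirroring the paradigm and effect
specs; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
import zlib
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erds import ERSPMap, bootstrap_mask, compute_ersp
from .evaluation import (BaselineComparison, CVReport, GridResult,
                         band_time_grid, baseline_vs_taskline, cv_chance_band,
                         repeated_kfold)
from .online import OnlineTrace, simulate_online
from .preprocessing import BandSpec, get_band
from .session import EpochedSession
from .synthetic import EffectSpec, ParadigmSpec, generate_session


class SessionIOError(RuntimeError):
    """Raised when a session container cannot be parsed."""


_FORMAT = "sensebci-session-v1"


def write_session(session: EpochedSession, path: str | Path) -> Path:
    """Write a session to a single-file array container (.npz)."""
    path = Path(path)
    meta = {
        "format": _FORMAT,
        "version": __version__,
        "fs_hz": session.fs_hz,
        "channel_names": list(session.channel_names),
        **{k: v for k, v in session.meta.items()},
    }
    np.savez(
        path,
        data=session.data,
        labels=session.labels.astype("U5"),
        run_index=session.run_index,
        times_s=session.times_s,
        meta_json=np.array(json.dumps(meta)),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_session(path: str | Path) -> EpochedSession:
    """Read a session container; lossless inverse of :func:`write_session`."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as archive:
            required = {"data", "labels", "run_index", "times_s", "meta_json"}
            missing = required - set(archive.files)
            if missing:
                raise SessionIOError(
                    f"{path}: not a session container (missing {sorted(missing)})"
                )
            meta = json.loads(str(archive["meta_json"]))
            if meta.get("format") != _FORMAT:
                raise SessionIOError(f"{path}: unknown container format {meta.get('format')!r}")
            fs = float(meta.pop("fs_hz"))
            names = meta.pop("channel_names")
            meta.pop("format", None)
            meta.pop("version", None)
            return EpochedSession(
                data=archive["data"], labels=archive["labels"],
                run_index=archive["run_index"], fs_hz=fs,
                times_s=archive["times_s"], channel_names=names, meta=meta,
            )
    except SessionIOError:
        raise
    except (OSError, EOFError, ValueError, KeyError, json.JSONDecodeError,
            zlib.error, zipfile.BadZipFile) as exc:
        raise SessionIOError(f"{path}: malformed session container ({exc})") from exc


def session_table(session: EpochedSession) -> pd.DataFrame:
    """Per-trial label/run table for CSV export."""
    return pd.DataFrame({
        "trial_index": np.arange(session.n_trials),
        "run_index": session.run_index,
        "label": session.labels,
    })


# ---------------------------------------------------------------------------
# run configuration

_PARADIGM_KEYS = {f.name for f in fields(ParadigmSpec)}
_EFFECT_KEYS = {f.name for f in fields(EffectSpec)}
_RUN_KEYS = {"band", "window", "seed", "n_pairs", "n_folds", "n_repeats",
             "n_boot", "ersp_alpha", "ersp_channel"}


@dataclass
class RunConfig:
    """Everything needed to reproduce one full synthetic-session analysis."""

    paradigm: ParadigmSpec
    effect: EffectSpec
    band: BandSpec | str = "broad"
    window: str | tuple[float, float] = "task"
    seed: int = 0
    n_pairs: int = 3
    n_folds: int = 5
    n_repeats: int = 5
    n_boot: int = 1000
    ersp_alpha: float = 0.01
    ersp_channel: int | None = None

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        unknown = set(raw) - _PARADIGM_KEYS - _EFFECT_KEYS - _RUN_KEYS
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        para = {k: _as_tuple(v) for k, v in raw.items() if k in _PARADIGM_KEYS}
        eff = {k: _as_tuple(v) for k, v in raw.items() if k in _EFFECT_KEYS}
        run = {k: v for k, v in raw.items() if k in _RUN_KEYS}
        if "window" in run and not isinstance(run["window"], str):
            run["window"] = tuple(run["window"])
        return cls(paradigm=ParadigmSpec(**para), effect=EffectSpec(**eff), **run)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_mapping(raw)

    def to_mapping(self) -> dict:
        out: dict = {}
        for f in fields(ParadigmSpec):
            out[f.name] = _jsonable(getattr(self.paradigm, f.name))
        for f in fields(EffectSpec):
            out[f.name] = _jsonable(getattr(self.effect, f.name))
        band = self.band if isinstance(self.band, str) else self.band.name or \
            [self.band.low_hz, self.band.high_hz]
        out.update(band=band,
                   window=self.window if isinstance(self.window, str) else list(self.window),
                   seed=self.seed, n_pairs=self.n_pairs, n_folds=self.n_folds,
                   n_repeats=self.n_repeats, n_boot=self.n_boot,
                   ersp_alpha=self.ersp_alpha, ersp_channel=self.ersp_channel)
        return out

    def resolve_window(self) -> tuple[float, float]:
        if self.window == "task":
            return tuple(self.paradigm.task_window_s)
        if self.window == "baseline":
            return tuple(self.paradigm.baseline_window_s)
        if isinstance(self.window, str):
            raise ValueError(f"unknown named window {self.window!r}")
        return tuple(self.window)


def _as_tuple(v):
    if isinstance(v, list):
        return tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return v


def _jsonable(v):
    if isinstance(v, tuple):
        return [_jsonable(x) for x in v]
    return v


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_mapping(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Named deterministic substream below 2**31 for one workflow stage."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# model serialization

def save_models(path: str | Path, csp_model=None, lda_model=None,
                extra: dict | None = None) -> Path:
    """CSP and/or LDA model round-trip container (.npz + embedded JSON)."""
    path = Path(path)
    arrays: dict = {}
    meta: dict = {"format": "sensebci-models-v1", "version": __version__,
                  **(extra or {})}
    if csp_model is not None:
        arrays.update(csp_filters=csp_model.filters, csp_patterns=csp_model.patterns,
                      csp_eigvals=csp_model.eigvals_class1)
        meta["csp_n_pairs"] = csp_model.n_pairs
    if lda_model is not None:
        arrays.update(lda_weights=lda_model.weights, lda_means=lda_model.class_means,
                      lda_pooled_cov=lda_model.pooled_covariance)
        meta["lda_bias"] = lda_model.bias
        meta["lda_class_labels"] = list(lda_model.class_labels)
    np.savez(path, meta_json=np.array(json.dumps(meta)), **arrays)
    return path


def load_models(path: str | Path):
    """Inverse of :func:`save_models`; returns (CSPModel | None, LDAModel | None, meta)."""
    from .csp import CSPModel
    from .lda import LDAModel
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta_json"]))
        csp_model = lda_model = None
        if "csp_filters" in archive.files:
            csp_model = CSPModel(filters=archive["csp_filters"],
                                 patterns=archive["csp_patterns"],
                                 eigvals_class1=archive["csp_eigvals"],
                                 n_pairs=int(meta["csp_n_pairs"]))
        if "lda_weights" in archive.files:
            lda_model = LDAModel(weights=archive["lda_weights"],
                                 bias=float(meta["lda_bias"]),
                                 class_labels=tuple(meta["lda_class_labels"]),
                                 class_means=archive["lda_means"],
                                 pooled_covariance=archive["lda_pooled_cov"])
    return csp_model, lda_model, meta


# ---------------------------------------------------------------------------
# report writers

def write_cv_report(report: CVReport, csv_path: str | Path,
                    json_path: str | Path | None = None,
                    extra: dict | None = None) -> None:
    mat = report.as_matrix()
    rows = [{"repeat": r + 1, "fold": f + 1, "accuracy": mat[r, f]}
            for r in range(report.n_repeats) for f in range(report.n_folds)]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {"mean": report.mean, "sd": report.sd,
                   "n_repeats": report.n_repeats, "n_folds": report.n_folds,
                   "seed": report.seed, **(extra or {})}
        Path(json_path).write_text(json.dumps(summary, indent=2))


def write_grid(grid: GridResult, csv_path: str | Path) -> None:
    cols = [f"{w0:g}-{w1:g}s" for (w0, w1) in grid.windows_post_cue]
    idx = [b.name or f"{b.low_hz:g}-{b.high_hz:g}Hz" for b in grid.bands]
    pd.DataFrame(grid.accuracy_matrix, index=idx, columns=cols).to_csv(
        csv_path, index_label="band")


def write_online_trace(trace: OnlineTrace, csv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    trace.records.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps({
            "run_accuracy": {str(k): v for k, v in trace.run_accuracy.items()},
            "overall_accuracy": trace.overall_accuracy,
            "n_predictions": trace.n_predictions,
        }, indent=2))


def write_ersp(ersp: ERSPMap, path: str | Path) -> None:
    np.savez(Path(path), times_s=ersp.times_s, freqs_hz=ersp.freqs_hz,
             power_change=ersp.power_change,
             sig_mask=(ersp.sig_mask if ersp.sig_mask is not None
                       else np.zeros_like(ersp.power_change, dtype=bool)),
             meta_json=np.array(json.dumps({
                 "channel": ersp.channel, "mode": ersp.mode,
                 "alpha": ersp.alpha, "n_boot": ersp.n_boot,
                 "baseline_window_s": list(ersp.baseline_window_s)})))


# ---------------------------------------------------------------------------
# workflow

def run_workflow(config: RunConfig, out_dir: str | Path) -> dict:
    """simulate -> cv/baseline -> grid -> online -> ersp, plus a manifest.

    Every stage seeds its randomness from a named substream of the
    top-level seed, so rerunning the same config reproduces every output
    byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    band = get_band(config.band)
    window = config.resolve_window()
    stages: dict[str, dict] = {}

    session = generate_session(config.paradigm, config.effect,
                               stage_seed(config.seed, "simulate"))
    write_session(session, out / "session.npz")
    session_table(session).to_csv(out / "trials.csv", index=False)
    stages["simulate"] = {"outputs": ["session.npz", "trials.csv"],
                          "n_trials": session.n_trials,
                          "class_counts": session.class_counts()}

    comparison: BaselineComparison = baseline_vs_taskline(
        session, band, seed=stage_seed(config.seed, "cv"),
        task_window=window,
        baseline_window=tuple(config.paradigm.baseline_window_s),
        n_folds=config.n_folds, n_repeats=config.n_repeats,
        n_pairs=config.n_pairs)
    cv = comparison.taskline
    lo, hi = cv_chance_band(session.n_trials, config.n_folds)
    write_cv_report(cv, out / "cv_accuracies.csv", out / "cv_summary.json", extra={
        "baseline_mean": comparison.baseline.mean,
        "baseline_t": comparison.t_statistic,
        "baseline_p": comparison.p_value,
        "chance_band_95": [lo, hi],
        "at_chance_level": bool(lo <= cv.mean <= hi),
    })
    stages["cv"] = {"outputs": ["cv_accuracies.csv", "cv_summary.json"],
                    "mean_accuracy": cv.mean,
                    "at_chance_level": bool(lo <= cv.mean <= hi)}

    grid = band_time_grid(session, n_folds=config.n_folds,
                          n_repeats=config.n_repeats,
                          seed=stage_seed(config.seed, "grid"),
                          n_pairs=config.n_pairs,
                          cue_onset_s=config.paradigm.cue_onset_s)
    write_grid(grid, out / "grid.csv")
    stages["grid"] = {"outputs": ["grid.csv"],
                      "best_band": grid.best_band.name,
                      "best_window_post_cue": list(grid.best_window_post_cue),
                      "best_accuracy": grid.best_accuracy}

    trace = simulate_online(session, band, window, n_pairs=config.n_pairs)
    write_online_trace(trace, out / "online_trace.csv", out / "online_summary.json")
    stages["online"] = {"outputs": ["online_trace.csv", "online_summary.json"],
                        "overall_accuracy": trace.overall_accuracy}

    sources = config.effect.resolved_sources(config.paradigm.n_channels)
    channel = config.ersp_channel if config.ersp_channel is not None else sources[0][0]
    freqs = np.arange(8.0, 28.0, 2.0)
    ersp = compute_ersp(session, channel, freqs,
                        baseline_window_s=tuple(config.paradigm.baseline_window_s))
    bootstrap_mask(ersp, alpha=config.ersp_alpha, n_boot=config.n_boot,
                   seed=stage_seed(config.seed, "bootstrap"))
    write_ersp(ersp, out / "ersp.npz")
    stages["ersp"] = {"outputs": ["ersp.npz"], "channel": int(channel),
                      "significant_fraction": float(np.mean(ersp.sig_mask))}

    manifest = {
        "package": "sensebci",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_mapping(),
        "config_hash": config_hash(config),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "cv", "grid", "bootstrap")},
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
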