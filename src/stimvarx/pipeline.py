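"""End-to-end pipeline configuration and orchestration.

Chains preprocess -> outlier rejection -> cross-validated order selection
-> OLS fit on merged contiguous segments -> residual whiteness test ->
fit metrics -> integrated-information profile, writing each stage's
output as plain text so any stage can be inspected or re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, integration, order_selection, outliers, preprocessing
from .core import EpochSet, fit_ols, one_step_predict
from .io import read_session
from .synthdata import SessionData

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, text-serializable configuration for the whole pipeline."""

    input_path: str = ""
    output_dir: str = "stimvarx_out"
    analysis_fs: float = 100.0
    # cleaning / downsampling
    median_order: int = 19
    flat_top_ms: float = 10.0
    taper_ms: float = 9.0
    passband_hz: float = 48.0
    stopband_hz: float = 49.9
    downsample_factor: int = 10
    binary_trigger: bool = True
    # epoching
    epoch_pre: int = 12
    epoch_length: int = 100
    # outlier rejection
    n_sd: float = 60.0
    # model orders / CV
    p_min: int = 1
    p_max: int = 30
    ell: int = 10
    n_partitions: int = 0  # 0 => automatic (test blocks of ~3 epochs)
    # diagnostics
    alpha: float = 0.1
    # integrated information
    tau_min: int = 1
    tau_max: int = 30
    seed: int = 0

    def to_text(self) -> str:
        return "".join(
            f"{f.name}={getattr(self, f.name)}\n" for f in dataclasses.fields(self)
        )

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected key=value, got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"line {ln}: unknown config key {key!r}")
            kwargs[key] = value
        cfg = cls()
        for key, value in kwargs.items():
            cur = getattr(cfg, key)
            if isinstance(cur, bool):
                setattr(cfg, key, value.lower() in {"1", "true", "yes"})
            elif isinstance(cur, int):
                setattr(cfg, key, int(value))
            elif isinstance(cur, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def preprocess_session(session: SessionData, cfg: PipelineConfig) -> tuple[SessionData, np.ndarray]:
    """Clean + downsample if the session is above the analysis rate.

    Returns the analysis-rate session and the stimulus sample indices.
    """
    if session.fs > cfg.analysis_fs:
        trig = preprocessing.trigger_times(session.x)
        cleaned = preprocessing.tukey_median_clean(
            session, trig,
            preprocessing.CleaningConfig(
                median_order=cfg.median_order,
                flat_top_ms=cfg.flat_top_ms,
                taper_ms=cfg.taper_ms,
            ),
        )
        ds_cfg = preprocessing.DownsampleConfig(
            passband_hz=cfg.passband_hz,
            stopband_hz=cfg.stopband_hz,
            factor=cfg.downsample_factor,
        )
        down = preprocessing.antialias_downsample(
            cleaned, ds_cfg, binary_trigger=cfg.binary_trigger
        )
        stim = trig // cfg.downsample_factor
        return down, stim
    stim = preprocessing.trigger_times(session.x)
    if stim.size == 0 and session.truth and "train" in session.truth:
        stim = np.asarray(session.truth["train"].pulse_times)
    return session, stim


def run_pipeline(config: PipelineConfig, session: SessionData | None = None) -> dict:
    """Execute the full analysis chain, writing stage outputs to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash()}

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("pipeline stage: %s", name)

    try:
        if session is None:
            stage("load")
            session = read_session(config.input_path)

        stage("preprocess")
        analysis, stim = preprocess_session(session, config)
        if stim.size == 0:
            raise ValueError("no stimulus triggers found in session input")

        stage("segment")
        epochs = preprocessing.segment_epochs(
            analysis.y, analysis.x, stim,
            pre=config.epoch_pre, length=config.epoch_length,
            fs=analysis.fs, channel_names=analysis.channel_names,
        )

        stage("reject")
        kept, report = outliers.reject_outliers(epochs, n_sd=config.n_sd)
        pd.DataFrame({
            "epoch": np.arange(epochs.J),
            "d2": report.d2,
            "threshold": report.threshold,
            "rejected": [j in set(report.rejected) for j in range(epochs.J)],
        }).to_csv(out / "outliers.tsv", sep="\t", index=False)
        results["rejected_epochs"] = report.rejected

        stage("cv")
        M = config.n_partitions or order_selection.default_n_partitions(kept.J)
        grid = list(range(config.p_min, config.p_max + 1))
        cv = order_selection.select_order(kept, p_grid=grid, ell=config.ell, M=M)
        pd.DataFrame({
            "p": cv.p_grid,
            "score": cv.score,
            "cv_e_mean": cv.cv_e.mean(axis=0),
            "cv_eps_mean": cv.cv_eps.mean(axis=0),
        }).to_csv(out / "cv.tsv", sep="\t", index=False)
        results["selected_p"] = cv.selected_p

        stage("fit")
        segments = outliers.merge_contiguous(kept)
        model = fit_ols(segments, p=cv.selected_p, ell=config.ell)
        model.save(out / "model.json")

        stage("whiteness")
        _, resids = one_step_predict(model, segments)
        white = diagnostics.whiteness_test(resids, alpha=config.alpha)
        results["whiteness"] = {
            "T": white.T, "L": white.L, "N_c": white.N_c,
            "alpha": white.alpha, "reject": white.reject,
        }

        stage("metrics")
        part = order_selection.partition_cv(kept.J, M)
        cv_models = [
            fit_ols(kept.subset(tr), p=cv.selected_p, ell=config.ell)
            for tr in part.train_sets
        ]
        y_bar, y_hat_bar = diagnostics.average_cv_responses(kept, cv_models, part)
        metrics = diagnostics.fit_metrics(y_bar, y_hat_bar, resids, segments)
        pd.DataFrame({
            "channel": analysis.channel_names,
            "nmsd": metrics.nmsd,
            "rrms": metrics.rrms,
        }).to_csv(out / "metrics_channels.tsv", sep="\t", index=False)
        results["metrics"] = {"nmrd": metrics.nmrd, "nmse": metrics.nmse}

        stage("phi")
        profile = integration.phi_profile(
            model, tau_grid=range(config.tau_min, config.tau_max + 1)
        )
        pd.DataFrame({
            "tau_samples": profile.taus,
            "tau_ms": profile.taus * 1000.0 / model.fs,
            "phi_bits": profile.phi,
            "mib": [f"{b.M1}|{b.M2}" for b in profile.mib],
        }).to_csv(out / "phi.tsv", sep="\t", index=False)
        results["phi_max"] = profile.phi_max
        results["tau_argmax"] = profile.tau_argmax
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{current['stage']}': {exc}"
        ) from exc

    (out / "results.json").write_text(json.dumps(_jsonable(results), indent=2))
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
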