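"""End-to-end orchestration: simulate → preprocess → select → train → count.

Holds the run configuration (paths, seeds, model and sweep parameters, a
fast/full profile switch), the cohort-preparation helpers shared by the
command-line interface and the experiments, and the single-split
experiment used to validate the whole chain: train on 18 simulated
subjects, hold out 3, sweep the rest delay, report MAPE_G.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import EvalReport, Subject, cross_validate, make_folds
from .feature_select import select_channels
from .footflat_model import (
    FootFlatClassifier,
    ModelConfig,
    WindowedDataset,
    WindowNormalizer,
    make_windows,
    predict_status,
)
from .gait_synth import GroundTruth, simulate_cohort
from .recording_io import (
    AnnotationTable,
    ImuRecording,
    align_annotations,
    detect_sync_strikes,
    rebase,
)
from .step_count import default_rd_grid, sweep_rd

__all__ = ["RunConfig", "prepare_subject", "prepare_cohort", "run_pipeline",
           "single_split_experiment"]


@dataclass
class RunConfig:
    """Full-run configuration with provenance-friendly defaults."""

    out_dir: str = "solestep_run"
    seed: int = 0
    n_subjects: int = 21
    fs: float = 200.0
    correlation_threshold: float = 0.1
    model: ModelConfig = field(default_factory=ModelConfig)
    k_folds: int = 7
    fold_size: int = 3
    train_stride: int = 1
    epochs: int = 100
    patience: int = 10
    max_minutes: float = 5.0
    profile: str = "full"        # "full" | "fast"

    def __post_init__(self) -> None:
        if self.profile not in ("full", "fast"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "fast":
            self.train_stride = max(self.train_stride, 4)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = ModelConfig.from_dict(raw.pop("model", {}))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(model=model, **known)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def manifest(self) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return {
            "config": self.to_dict(),
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "solestep_version": __version__,
        }


def prepare_subject(rec: ImuRecording, ann: AnnotationTable, truth: GroundTruth,
                    subject_id: int) -> Subject:
    """Synchronize, re-base and fuse one recording into a cohort Subject."""
    t0 = detect_sync_strikes(rec)
    enriched = align_annotations(rebase(rec, t0), ann)
    return Subject(subject_id, enriched, int(len(truth.step_event_times)), truth)


def prepare_cohort(raw: list[tuple[ImuRecording, AnnotationTable, GroundTruth]]
                   ) -> list[Subject]:
    return [prepare_subject(rec, ann, truth, sid)
            for sid, (rec, ann, truth) in enumerate(raw)]


def single_split_experiment(seed: int = 1, n_subjects: int = 21,
                            n_test: int = 3, config: ModelConfig | None = None,
                            train_stride: int = 4, epochs: int = 100,
                            patience: int = 10, max_minutes: float = 5.0,
                            script=None) -> dict:
    """Full-chain check on one subject-wise split (default 18 train / 3 test).

    Simulates the default cohort, ranks channels on the training subjects,
    trains the default model (held-out subjects double as the validation
    set for early stopping), predicts per-sample foot status for the test
    subjects, sweeps the rest delay on the 25–1000 ms grid and reports the
    best mean MAPE_G together with the channel ranking.
    """
    cfg = config or ModelConfig()
    raw = simulate_cohort(n_subjects, seed=seed, script=script)
    cohort = prepare_cohort(raw)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    test_ids = set(int(i) for i in order[:n_test])
    train_subjects = [s for s in cohort if s.subject_id not in test_ids]
    test_subjects = [s for s in cohort if s.subject_id in test_ids]
    assert not ({s.subject_id for s in train_subjects} & test_ids)

    ranking = select_channels([s.enriched for s in train_subjects])
    channels = ranking.retained

    train_ds = WindowedDataset.concatenate([
        make_windows(s.enriched, channels, cfg.input_window_ms, stride=train_stride)
        for s in train_subjects])
    val_ds = WindowedDataset.concatenate([
        make_windows(s.enriched, channels, cfg.input_window_ms, stride=4)
        for s in test_subjects])
    norm = WindowNormalizer().fit(train_ds)
    clf = FootFlatClassifier.from_config(
        cfg, epochs=epochs, patience=patience, max_minutes=max_minutes)
    tds = norm.transform(train_ds)
    vds = norm.transform(val_ds)
    clf.fit(tds.X, tds.y, validation_data=(vds.X, vds.y))

    streams, counts = [], []
    for s in test_subjects:
        # deployment-style stream: one prediction per IMU sample
        ds = norm.transform(make_windows(s.enriched, channels, cfg.input_window_ms,
                                         include_undetermined=True))
        streams.append(predict_status(clf, ds))
        counts.append(s.n_true_steps)
    sweep = sweep_rd(streams, cohort[0].enriched.fs, counts, default_rd_grid())
    return {
        "mape_g": sweep.best_mape_g,
        "rd_ms": sweep.best_rd_ms,
        "rd_curve": sweep.mape_g_curve,
        "ranking": ranking,
        "test_subjects": sorted(test_ids),
        "n_true_steps": counts,
        "history": clf.history_,
    }


def run_pipeline(cfg: RunConfig) -> EvalReport:
    """Execute every stage in order and persist intermediates under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        raw = simulate_cohort(cfg.n_subjects, seed=cfg.seed, fs=cfg.fs)
        stage = "preprocess"
        cohort = prepare_cohort(raw)
        stage = "select"
        ranking = select_channels([s.enriched for s in cohort],
                                  cfg.correlation_threshold)
        stage = "evaluate"
        plan = make_folds([s.subject_id for s in cohort], cfg.k_folds,
                          cfg.fold_size, seed=cfg.seed)
        report = cross_validate(
            cohort, cfg.model, plan, ranking.retained,
            train_stride=cfg.train_stride, epochs=cfg.epochs,
            patience=cfg.patience, max_minutes=cfg.max_minutes)
        stage = "report"
        payload = {
            "manifest": cfg.manifest(),
            "channel_ranking": {k: float(v)
                                for k, v in ranking.correlations.items()},
            "retained_channels": ranking.retained,
            "report": report.to_dict(),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
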