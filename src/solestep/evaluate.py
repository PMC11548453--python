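"""Subject-wise k-fold cross-validation and aggregate reporting.

Subjects (not samples) are partitioned into folds so that no individual
contributes to both training and evaluation of the same model — the
leakage guard human-movement models require.  The default plan is 7 folds
of 3 subjects from a 21-subject cohort; at each step one fold is held out
and, by default, doubles as the early-stopping validation set (a
``nested_val`` option instead carves validation subjects out of the
training folds).  The rest delay is selected once, by a sweep on the
pooled held-out predictions, and per-fold metrics are reported at that
single rest delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .footflat_model import (
    FootFlatClassifier,
    ModelConfig,
    WindowedDataset,
    WindowNormalizer,
    make_windows,
    predict_status,
)
from .recording_io import EnrichedRecording
from .step_count import count_steps, mape_dl, mape_g, sweep_rd

__all__ = ["FoldPlan", "Subject", "EvalReport", "make_folds", "cross_validate"]


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint partition of subject ids into k folds of equal size."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def all_subjects(self) -> set[int]:
        return {sid for fold in self.folds for sid in fold}


@dataclass
class Subject:
    """One preprocessed cohort member.

    ``truth`` optionally keeps the simulator's exact ground truth around
    for oracle plumbing and diagnostics; evaluation itself only consumes
    the enriched recording and the true step count.
    """

    subject_id: int
    enriched: EnrichedRecording
    n_true_steps: int
    truth: object | None = None


def make_folds(subject_ids, k: int = 7, fold_size: int = 3, seed: int = 0) -> FoldPlan:
    """Uniformly random disjoint partition into k folds of fold_size subjects."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) != k * fold_size:
        raise ValueError(
            f"need exactly k × fold_size = {k * fold_size} subjects, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = tuple(
        tuple(ids[j] for j in perm[i * fold_size:(i + 1) * fold_size])
        for i in range(k)
    )
    return FoldPlan(folds, seed)


@dataclass
class EvalReport:
    """Per-fold and aggregate MAPE_DL / MAPE_G with the selected rest delay."""

    folds: list[dict]
    mean_mape_dl: float
    sd_mape_dl: float
    mean_mape_g: float
    sd_mape_g: float
    rd_ms: float
    rd_grid: np.ndarray
    rd_curve: np.ndarray
    config: ModelConfig
    incomplete: bool = False

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "mean_mape_dl": self.mean_mape_dl,
            "sd_mape_dl": self.sd_mape_dl,
            "mean_mape_g": self.mean_mape_g,
            "sd_mape_g": self.sd_mape_g,
            "rd_ms": self.rd_ms,
            "rd_grid": [float(x) for x in self.rd_grid],
            "rd_curve": [float(x) for x in self.rd_curve],
            "config": self.config.to_dict(),
            "incomplete": self.incomplete,
        }


def _train_and_predict(train_subjects: list[Subject], test_subjects: list[Subject],
                       cfg: ModelConfig, channels: list[str], train_stride: int,
                       epochs: int, patience: int, max_minutes: float,
                       nested_val: bool):
    """Fit one model and return per-test-subject binary status streams."""
    if nested_val and len(train_subjects) > 1:
        val_subjects = train_subjects[-1:]
        fit_subjects = train_subjects[:-1]
    else:
        val_subjects = test_subjects
        fit_subjects = train_subjects
    fs = fit_subjects[0].enriched.fs
    train_ds = WindowedDataset.concatenate([
        make_windows(s.enriched, channels, cfg.input_window_ms, stride=train_stride)
        for s in fit_subjects])
    val_ds = WindowedDataset.concatenate([
        make_windows(s.enriched, channels, cfg.input_window_ms, stride=max(train_stride, 4))
        for s in val_subjects])
    norm = WindowNormalizer().fit(train_ds)
    train_ds = norm.transform(train_ds)
    val_ds = norm.transform(val_ds)
    clf = FootFlatClassifier.from_config(
        cfg, epochs=epochs, patience=patience, max_minutes=max_minutes)
    clf.fit(train_ds.X, train_ds.y, validation_data=(val_ds.X, val_ds.y))

    streams = {}
    for s in test_subjects:
        # deployment-style stream: predict at every sample; undetermined
        # labels only mask the MAPE_DL comparison, never the counting
        ds = make_windows(s.enriched, channels, cfg.input_window_ms, stride=1,
                          include_undetermined=True)
        ds = norm.transform(ds)
        streams[s.subject_id] = (predict_status(clf, ds), ds.y, fs)
    return streams, clf


def cross_validate(cohort: list[Subject], cfg: ModelConfig, plan: FoldPlan,
                   channels: list[str], train_stride: int = 1,
                   rd_grid: np.ndarray | None = None, epochs: int = 100,
                   patience: int = 10, max_minutes: float = 5.0,
                   nested_val: bool = False, predictor=None) -> EvalReport:
    """Run the k-step subject-wise cross-validation.

    ``predictor``, if given, replaces model training: a callable mapping a
    :class:`Subject` to a (pred_status, obs_status) pair — used to pipe
    ground truth or an external model through the same evaluation path.
    """
    by_id = {s.subject_id: s for s in cohort}
    if plan.all_subjects != set(by_id):
        raise ValueError("fold plan does not match cohort subject ids")

    streams: dict[int, tuple] = {}
    fold_errors: list[str | None] = []
    for fold in plan.folds:
        test_ids = set(fold)
        train_subjects = [s for s in cohort if s.subject_id not in test_ids]
        test_subjects = [by_id[sid] for sid in fold]
        # subject-wise leakage guard
        overlap = {s.subject_id for s in train_subjects} & test_ids
        assert not overlap, f"subject leakage across train/test: {overlap}"
        try:
            if predictor is not None:
                for s in test_subjects:
                    pred, obs = predictor(s)
                    streams[s.subject_id] = (pred, obs, s.enriched.fs)
            else:
                fold_streams, _ = _train_and_predict(
                    train_subjects, test_subjects, cfg, channels, train_stride,
                    epochs, patience, max_minutes, nested_val)
                streams.update(fold_streams)
            fold_errors.append(None)
        except (ValueError, RuntimeError) as exc:  # training failure: report per fold
            fold_errors.append(str(exc))

    # single rest delay selected on pooled held-out predictions
    evaluated_ids = [sid for fold in plan.folds for sid in fold if sid in streams]
    sweep = sweep_rd([streams[sid][0] for sid in evaluated_ids],
                     cohort[0].enriched.fs,
                     [by_id[sid].n_true_steps for sid in evaluated_ids],
                     rd_grid)

    folds_out = []
    for fold, err in zip(plan.folds, fold_errors):
        entry: dict = {"subjects": list(fold)}
        if err is not None or any(sid not in streams for sid in fold):
            entry["error"] = err or "missing predictions"
            folds_out.append(entry)
            continue
        pred_cat = np.concatenate([streams[sid][0] for sid in fold])
        obs_cat = np.concatenate([streams[sid][1] for sid in fold])
        determined = obs_cat != 2
        pred_cat, obs_cat = pred_cat[determined], obs_cat[determined]
        n_pred = sum(count_steps(streams[sid][0], streams[sid][2],
                                 sweep.best_rd_ms).n_steps for sid in fold)
        n_obs = sum(by_id[sid].n_true_steps for sid in fold)
        entry["mape_dl"] = mape_dl(pred_cat, obs_cat)
        entry["mape_g"] = mape_g(n_pred, n_obs)
        entry["n_steps_pred"] = int(n_pred)
        entry["n_steps_obs"] = int(n_obs)
        folds_out.append(entry)

    ok = [f for f in folds_out if "error" not in f]
    dl = np.array([f["mape_dl"] for f in ok]) if ok else np.array([np.nan])
    g = np.array([f["mape_g"] for f in ok]) if ok else np.array([np.nan])
    return EvalReport(
        folds=folds_out,
        mean_mape_dl=float(dl.mean()), sd_mape_dl=float(dl.std(ddof=0)),
        mean_mape_g=float(g.mean()), sd_mape_g=float(g.std(ddof=0)),
        rd_ms=sweep.best_rd_ms, rd_grid=sweep.rd_grid, rd_curve=sweep.mape_g_curve,
        config=cfg, incomplete=len(ok) < plan.k,
    )
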