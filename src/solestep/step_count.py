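"""Refractory-period step extraction and the two MAPE criteria.

A step is registered at each onset (0→1 transition) of a detected
foot-flat phase; after a registration, further onsets within the "rest
delay" (RD) refractory window are suppressed, preventing double counting
of flickery detections within one stance.  The refractory clock starts at
the registered onset; suppressed onsets do not restart it.

Two error criteria:

* MAPE_DL — on the classifier output itself: |n_flat,pred − n_flat,obs| /
  n_flat,obs, counting flat-labeled samples.
* MAPE_G — on the final step counts: |n_steps,pred − n_steps,obs| /
  n_steps,obs.

Both are fractions; reports usually render them as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepCountResult",
    "MetricReport",
    "default_rd_grid",
    "count_steps",
    "sweep_rd",
    "mape_g",
    "mape_dl",
]


def default_rd_grid() -> np.ndarray:
    """The standard rest-delay grid: 25 ms to 1000 ms in 25 ms steps (40 points)."""
    return np.arange(25.0, 1000.0 + 1e-9, 25.0)


@dataclass
class StepCountResult:
    n_steps: int
    event_times: np.ndarray      # s
    rd_ms: float


@dataclass
class MetricReport:
    mape_dl: float               # fraction
    mape_g: float                # fraction

    @property
    def mape_dl_percent(self) -> float:
        return 100.0 * self.mape_dl

    @property
    def mape_g_percent(self) -> float:
        return 100.0 * self.mape_g


def count_steps(status: np.ndarray, fs: float, rd_ms: float) -> StepCountResult:
    """Count foot-flat onsets under the rest-delay refractory rule.

    The stream start counts as a preceding 0, so a stream beginning at 1
    registers an onset at its first sample.
    """
    if rd_ms < 0:
        raise ValueError("rest delay must be >= 0")
    status = np.asarray(status)
    if status.size == 0:
        return StepCountResult(0, np.empty(0), rd_ms)
    onsets = np.flatnonzero(np.diff(np.concatenate([[0], status])) == 1)
    rd_samples = rd_ms * fs / 1000.0  # compare in samples: exact for integer gaps
    events = []
    last = None
    for idx in onsets:
        if last is None or (idx - last) >= rd_samples:
            events.append(idx / fs)
            last = idx
    return StepCountResult(len(events), np.asarray(events), rd_ms)


def mape_g(n_pred: int, n_obs: int) -> float:
    """Global step-count error |n_pred − n_obs| / n_obs (fraction)."""
    if n_obs <= 0:
        raise ValueError("observed step count must be > 0")
    return abs(n_pred - n_obs) / n_obs


def mape_dl(pred_status: np.ndarray, obs_status: np.ndarray) -> float:
    """Classifier-output error on flat-sample counts (fraction).

    Streams must be aligned with undetermined samples already excluded.
    """
    pred = np.asarray(pred_status)
    obs = np.asarray(obs_status)
    if pred.shape != obs.shape:
        raise ValueError(f"stream length mismatch: {pred.shape} vs {obs.shape}")
    n_obs = int(np.count_nonzero(obs == 1))
    if n_obs == 0:
        raise ValueError("no observed flat samples: MAPE_DL undefined")
    n_pred = int(np.count_nonzero(pred == 1))
    return abs(n_pred - n_obs) / n_obs


@dataclass
class RdSweepResult:
    best_rd_ms: float
    best_mape_g: float           # fraction, mean over streams
    rd_grid: np.ndarray
    mape_g_curve: np.ndarray     # mean MAPE_G per grid point


def sweep_rd(status, fs: float, true_step_count,
             rd_grid: np.ndarray | None = None) -> RdSweepResult:
    """Select the rest delay minimizing mean MAPE_G over one or more streams.

    ``status`` may be a single binary stream or a list of streams, with
    ``true_step_count`` a count or matching list.  Ties break toward the
    smaller rest delay.
    """
    if rd_grid is None:
        rd_grid = default_rd_grid()
    rd_grid = np.asarray(rd_grid, dtype=float)
    if rd_grid.size == 0:
        raise ValueError("empty rest-delay grid")
    if isinstance(status, (list, tuple)):
        streams = list(status)
        counts = list(true_step_count)
    else:
        streams = [status]
        counts = [true_step_count]
    curve = np.empty(rd_grid.size)
    for k, rd in enumerate(rd_grid):
        errs = [mape_g(count_steps(s, fs, rd).n_steps, n)
                for s, n in zip(streams, counts)]
        curve[k] = float(np.mean(errs))
    best = int(np.argmin(curve))  # argmin takes the first minimum: smaller rd
    return RdSweepResult(float(rd_grid[best]), float(curve[best]), rd_grid, curve)
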