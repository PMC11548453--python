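"""Two-stage hyperparameter search over the model design space.

The design space enumerates nine hyperparameters (units, layers, dense
flag and width, input window, dropout, activation, learning rate, batch
size) as explicit grids totalling 3,150,000 combinations.  The search
spends the first ~25% of its trial budget on uniform random exploration
and the remainder on local sampling around the incumbent best: each
parameter jumps to an adjacent grid value with probability equal to a
temperature that decays linearly from 1.0 to 0.2, gradually focusing the
search.  Every trial is scored by validation loss after training with the
standard early-stopping rules, typically on a 25% subsample of the
training windows; the final configuration is then refit on everything.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .evaluate import EvalReport, FoldPlan, Subject, cross_validate
from .footflat_model import (
    FootFlatClassifier,
    ModelConfig,
    WindowedDataset,
    WindowNormalizer,
)

__all__ = [
    "SearchSpace",
    "TuneResult",
    "default_search_space",
    "count_combinations",
    "subsample_windows",
    "two_stage_search",
    "finalize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Explicit per-parameter candidate grids."""

    grids: dict[str, tuple]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grids",
                           {k: tuple(v) for k, v in self.grids.items()})


def default_search_space() -> SearchSpace:
    """The nine-parameter design space (3,150,000 combinations)."""
    return SearchSpace({
        "n_lstm_units": (16, 32, 64, 96, 128),
        "n_lstm_layers": (1, 2, 3),
        "dense_layer_active": (False, True),
        "n_dense_units": (8, 16, 32, 48, 64),
        "input_window_ms": tuple(float(v) for v in range(25, 251, 25)),
        "dropout": (0.1, 0.2, 0.3, 0.4, 0.5),
        "lstm_activation": ("relu", "sigmoid", "tanh"),
        "learning_rate": tuple(float(v) for v in np.logspace(-4, -2, 20)),
        "batch_size": (64, 128, 192, 256, 512, 1024, 2048),
    })


def count_combinations(space: SearchSpace) -> int:
    """Cardinality of the full design of experiments (product of grid sizes)."""
    total = 1
    for name, grid in space.grids.items():
        if len(grid) == 0:
            warnings.warn(f"empty grid for {name!r}: design space is empty",
                          stacklevel=2)
            return 0
        total *= len(grid)
    return total


def subsample_windows(data: WindowedDataset, fraction: float = 0.25,
                      seed: int = 0) -> WindowedDataset:
    """Uniform random subset of round(fraction × N) windows, reproducible per seed."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    n = len(data)
    if fraction == 1.0:
        return data
    rng = np.random.default_rng(seed)
    size = int(round(fraction * n))
    idx = rng.choice(n, size=size, replace=False)
    return data.subset(np.sort(idx))


@dataclass
class TuneResult:
    best_config: ModelConfig
    best_loss: float
    trials: list[dict]           # {"config": dict, "loss": float, "stage": str, ...}

    @property
    def running_minimum(self) -> np.ndarray:
        return np.minimum.accumulate([t["loss"] for t in self.trials])


def _random_config(space: SearchSpace, rng: np.random.Generator) -> dict:
    return {k: grid[rng.integers(len(grid))] for k, grid in space.grids.items()}


def _neighbor_config(space: SearchSpace, incumbent: dict, temperature: float,
                     rng: np.random.Generator) -> dict:
    """Perturb each parameter to an adjacent grid value with P = temperature."""
    prop = dict(incumbent)
    moved = False
    names = list(space.grids)
    for name in names:
        grid = space.grids[name]
        if len(grid) < 2 or rng.random() >= temperature:
            continue
        i = grid.index(prop[name])
        j = i + (1 if (i == 0 or (i < len(grid) - 1 and rng.random() < 0.5)) else -1)
        prop[name] = grid[j]
        moved = True
    if not moved:  # always propose something new
        name = names[rng.integers(len(names))]
        grid = space.grids[name]
        i = grid.index(prop[name])
        j = i + (1 if (i == 0 or (i < len(grid) - 1 and rng.random() < 0.5)) else -1)
        prop[name] = grid[j]
    return prop


def _default_objective(data, seed: int):
    """Train on the given (train, val) windowed datasets; score = best val loss.

    The datasets should be built at the widest window in the space; each
    trial keeps only the most recent samples its own window size asks for.
    """
    train_ds, val_ds = data

    def objective(cfg_dict: dict) -> float:
        cfg = ModelConfig.from_dict(cfg_dict)
        w = max(1, int(round(cfg.input_window_ms * train_ds.fs / 1000.0)))
        w = min(w, train_ds.window_samples)
        norm = WindowNormalizer().fit(train_ds)
        Xt = norm.transform(train_ds.X[:, -w:, :])
        Xv = norm.transform(val_ds.X[:, -w:, :])
        clf = FootFlatClassifier.from_config(cfg)
        clf.set_params(random_state=seed, epochs=100, patience=10, max_minutes=5.0)
        clf.fit(Xt, train_ds.y, validation_data=(Xv, val_ds.y))
        return clf.history_["best_loss"]

    return objective


def two_stage_search(space: SearchSpace, data=None, budget_trials: int = 40,
                     frac_random: float = 0.25, seed: int = 0,
                     objective=None, temperature_floor: float = 0.2) -> TuneResult:
    """Random exploration then temperature-annealed local search.

    ``objective`` maps a config dict to a loss; when omitted, ``data`` must
    be a (train, val) pair of :class:`WindowedDataset` and each trial
    trains the classifier with the standard early-stopping rules.
    """
    if budget_trials < 2:
        raise ValueError("budget_trials must be >= 2")
    if objective is None:
        if data is None:
            raise ValueError("either an objective or (train, val) data is required")
        objective = _default_objective(data, seed)
    rng = np.random.default_rng(seed)
    n_random = math.ceil(frac_random * budget_trials)
    n_local = budget_trials - n_random

    trials: list[dict] = []
    best_cfg: dict | None = None
    best_loss = np.inf

    for _ in range(n_random):
        cfg = _random_config(space, rng)
        loss = float(objective(cfg))
        trials.append({"config": cfg, "loss": loss, "stage": "random"})
        if loss < best_loss:
            best_loss, best_cfg = loss, cfg

    for j in range(n_local):
        frac = j / max(1, n_local - 1)
        temperature = 1.0 + (temperature_floor - 1.0) * frac
        cfg = _neighbor_config(space, best_cfg, temperature, rng)
        loss = float(objective(cfg))
        trials.append({"config": cfg, "loss": loss, "stage": "local",
                       "temperature": temperature})
        if loss < best_loss:
            best_loss, best_cfg = loss, cfg

    return TuneResult(ModelConfig.from_dict(best_cfg), best_loss, trials)


def finalize(best_cfg: ModelConfig, cohort: list[Subject], plan: FoldPlan,
             channels: list[str], **cv_kwargs) -> EvalReport:
    """Refit the tuned configuration on the full cohort with the rest-delay sweep."""
    return cross_validate(cohort, best_cfg, plan, channels, **cv_kwargs)
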