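"""Input-channel reduction by correlation with the foot-status label.

Each of the 8 candidate channels (3 accelerometer axes, 3 gyroscope axes
and the two Euclidean norms) is scored by its Pearson correlation with the
binary foot-flat label over the pooled cohort; channels whose correlation
magnitude falls below a threshold (default 0.1) are discarded.  On
realistic sole-IMU data this retains the gyroscope norm, the acceleration
norm and the vertical acceleration axis.

Note on sign: the gyroscope and acceleration norms are *low* during the
foot-flat phase, so their signed point-biserial correlations with the
flat=1 label are negative; rankings and reports quote the magnitude |r|,
as correlation-matrix figures conventionally do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .recording_io import CANDIDATE_CHANNELS, EnrichedRecording, drop_undetermined

__all__ = ["pearson_r", "ChannelRanking", "ChannelSelector", "select_channels"]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (with a warning) if not computable.

    A zero-variance input has no defined correlation: the channel is
    flagged not-computable rather than raising, so ranking can proceed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance input: correlation not computable", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ChannelRanking:
    """Correlation of every candidate channel with foot status."""

    correlations: pd.Series          # signed r per channel (NaN = not computable)
    threshold: float
    retained: list[str] = field(default_factory=list)

    @property
    def magnitudes(self) -> pd.Series:
        """|r| per channel, sorted descending (the conventional display)."""
        return self.correlations.abs().sort_values(ascending=False)


class ChannelSelector(BaseEstimator, TransformerMixin):
    """Retain channels whose |Pearson r| with the label is >= ``threshold``.

    Parameters
    ----------
    threshold : float, default 0.1
        Minimum correlation magnitude for a channel to be retained.

    Attributes
    ----------
    correlations_ : pd.Series
        Signed per-channel correlation with the fitted label vector.
    retained_ : list of str
        Channels with ``|r| >= threshold``, sorted by |r| descending.
    """

    def __init__(self, threshold: float = 0.1):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "ChannelSelector":
        X = pd.DataFrame(X)
        if len(X) == 0:
            raise ValueError("empty input")
        y = np.asarray(y, dtype=float)
        corrs = {}
        for col in X.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corrs[col] = pearson_r(X[col].to_numpy(), y)
        self.correlations_ = pd.Series(corrs)
        mags = self.correlations_.abs()
        dropped_nc = [c for c in X.columns if np.isnan(mags[c])]
        if dropped_nc:
            warnings.warn(f"channels not computable, excluded: {dropped_nc}", stacklevel=2)
        ok = mags.dropna()
        self.retained_ = list(ok[ok >= self.threshold].sort_values(ascending=False).index)
        if not self.retained_:
            warnings.warn("no channel reaches the correlation threshold", stacklevel=2)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]

    def ranking_(self) -> ChannelRanking:
        return ChannelRanking(self.correlations_, self.threshold, list(self.retained_))


def select_channels(enriched: EnrichedRecording | list[EnrichedRecording],
                    threshold: float = 0.1) -> ChannelRanking:
    """Rank the 8 candidate channels over a pooled cohort and apply the cut.

    Undetermined samples are dropped before correlating; pooling across
    subjects (rather than averaging per-subject correlations) mirrors a
    single cohort-level correlation matrix.
    """
    recs = enriched if isinstance(enriched, (list, tuple)) else [enriched]
    if len(recs) == 0:
        raise ValueError("empty cohort")
    frames = [drop_undetermined(r).frame for r in recs]
    pooled = pd.concat(frames, ignore_index=True)
    if len(pooled) == 0:
        raise ValueError("no determined samples in cohort")
    sel = ChannelSelector(threshold=threshold)
    sel.fit(pooled[CANDIDATE_CHANNELS], pooled["foot_status"].to_numpy())
    return sel.ranking_()
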