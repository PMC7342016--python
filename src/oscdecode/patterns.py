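"""Classifier weights -> interpretable sensor-space activation patterns.

A linear classifier's weight vector is not directly interpretable: weights on
noise channels can be large when they help cancel correlated noise.  The
standard remedy multiplies the weights with the feature covariance of the
training data, yielding the activation pattern of the source the classifier
extracts (for two-class Gaussian data with shared covariance this recovers
the class-mean difference up to scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ActivationPattern:
    """Channel-space activation pattern for one trained classifier."""

    values: np.ndarray  # (n_features,)
    time: float | None = None
    source_task: str | None = None


def weights_to_pattern(
    weights: np.ndarray,
    training_data: np.ndarray,
    labels: np.ndarray | None = None,
) -> ActivationPattern:
    """Multiply classifier weights with the training-data covariance.

    Parameters
    ----------
    weights : (n_features,) classifier weight vector.
    training_data : (n_exemplars, n_features) the exact exemplars the
        classifier was trained on.
    labels : optional per-exemplar class labels; when given, class means are
        removed before estimating the (pooled, 1/(n-1)-normalized) covariance,
        otherwise the grand mean is removed.
    """
    X = np.asarray(training_data, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 training exemplars (covariance undefined)")
    if X.shape[1] != w.shape[0]:
        raise ValueError("weights and training data feature dimensions differ")
    if labels is None:
        centered = X - X.mean(axis=0)
    else:
        labels = np.asarray(labels)
        centered = X.astype(float).copy()
        for lab in np.unique(labels):
            m = labels == lab
            centered[m] -= X[m].mean(axis=0)
    cov = centered.T @ centered / (X.shape[0] - 1)
    return ActivationPattern(values=cov @ w)


def pattern_topography(
    patterns: list[ActivationPattern],
    channels: list[str],
) -> pd.DataFrame:
    """Summarize patterns as mean absolute value per channel and time.

    Patterns (one per pairwise classifier and time point) are rectified and
    then averaged within each (time, task) cell; the result is a long-format
    table with columns channel, time, task, mean_abs_pattern, ready for CSV
    export or scalp plotting.
    """
    if not patterns:
        raise ValueError("no patterns given")
    rows = []
    for p in patterns:
        if len(p.values) != len(channels):
            raise ValueError("pattern length does not match channel list")
        rows.append(
            pd.DataFrame(
                {
                    "channel": channels,
                    "time": p.time,
                    "task": p.source_task,
                    "abs_pattern": np.abs(p.values),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    out = (
        table.groupby(["channel", "time", "task"], dropna=False, sort=False)[
            "abs_pattern"
        ]
        .mean()
        .reset_index()
        .rename(columns={"abs_pattern": "mean_abs_pattern"})
    )
    return out
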