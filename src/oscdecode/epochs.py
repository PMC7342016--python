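"""Epoched EEG container and basic trial-level operations."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

TASKS = ("perception", "imagery")


@dataclass
class EpochSet:
    """Epoched multichannel trials with task and object labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Voltage traces in microvolt.
    task : ndarray of str, shape (n_trials,)
        Either ``"perception"`` or ``"imagery"`` per trial.
    object_id : ndarray of int, shape (n_trials,)
        Condition labels ``1..n_objects``.
    times : ndarray, shape (n_times,)
        Time axis in ms relative to stimulus / word onset; uniform spacing
        ``1000 / sampling_rate``.
    channels : list of str
        Ordered channel names.
    sampling_rate : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    task: np.ndarray
    object_id: np.ndarray
    times: np.ndarray
    channels: list[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.task = np.asarray(self.task, dtype=object).astype(str)
        self.object_id = np.asarray(self.object_id, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        n_trials, n_channels, n_times = self.data.shape
        if len(self.task) != n_trials or len(self.object_id) != n_trials:
            raise ValueError("label length does not match trial count")
        if len(self.channels) != n_channels:
            raise ValueError("channel list does not match data")
        if len(self.times) != n_times:
            raise ValueError("time axis does not match data")
        dt = np.diff(self.times)
        if n_times > 1:
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sampling_rate, rtol=1e-6, atol=1e-6):
                raise ValueError("time spacing inconsistent with sampling_rate")
        bad = set(self.task) - set(TASKS)
        if bad:
            raise ValueError(f"unknown task labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_task(self, task: str) -> "EpochSet":
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        mask = self.task == task
        return replace(
            self,
            data=self.data[mask],
            task=self.task[mask],
            object_id=self.object_id[mask],
        )

    def select_channels(self, names: list[str]) -> "EpochSet":
        from .montage import channel_indices

        idx = channel_indices(self.channels, names)
        return replace(
            self,
            data=self.data[:, idx, :],
            channels=[self.channels[i] for i in idx],
        )

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Restrict the time axis to ``[tmin, tmax)`` ms."""
        mask = (self.times >= tmin) & (self.times < tmax)
        if not mask.any():
            raise ValueError("crop window contains no samples")
        return replace(self, data=self.data[:, :, mask], times=self.times[mask])

    def baseline_correct(self, window: tuple[float, float] = (-600.0, 0.0)) -> "EpochSet":
        """Subtract the pre-stimulus mean per channel and trial (broadband use)."""
        lo, hi = window
        mask = (self.times >= lo) & (self.times < hi)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        baseline = self.data[:, :, mask].mean(axis=-1, keepdims=True)
        return replace(self, data=self.data - baseline)


def concatenate_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack trial sets that share channels, times and sampling rate."""
    first = parts[0]
    for p in parts[1:]:
        if p.channels != first.channels or not np.array_equal(p.times, first.times):
            raise ValueError("epoch sets are not compatible")
    return replace(
        first,
        data=np.concatenate([p.data for p in parts], axis=0),
        task=np.concatenate([p.task for p in parts]),
        object_id=np.concatenate([p.object_id for p in parts]),
    )


def align_to_offset(epochs: EpochSet, word_duration_ms: np.ndarray) -> EpochSet:
    """Re-reference the imagery time axis to the offset of the cue word.

    Each trial is shifted left by its own word duration (so 0 ms marks word
    offset) and all trials are cropped to the window valid for every trial.

    Parameters
    ----------
    word_duration_ms : array, shape (n_trials,)
        Per-trial auditory word durations in ms (non-negative).
    """
    durations = np.asarray(word_duration_ms, dtype=float)
    if durations.shape != (epochs.n_trials,):
        raise ValueError("need one word duration per trial")
    if np.any(durations < 0):
        raise ValueError("word durations must be non-negative")
    dt = 1000.0 / epochs.sampling_rate
    shifts = np.round(durations / dt).astype(int)
    span = epochs.data.shape[-1]
    max_shift = int(shifts.max())
    if max_shift >= span:
        raise ValueError("word duration exceeds epoch length")
    keep = span - max_shift
    out = np.empty((epochs.n_trials, epochs.data.shape[1], keep), dtype=epochs.data.dtype)
    for i, s in enumerate(shifts):
        out[i] = epochs.data[i, :, s : s + keep]
    # sample j of shifted trial i sat at times[j + s_i] relative to onset,
    # i.e. times[j] relative to word offset (up to rounding of d_i to samples)
    new_times = epochs.times[:keep]
    return replace(epochs, data=out, times=new_times)
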