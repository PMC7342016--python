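"""Synthetic multi-participant EEG with a known shared oscillatory code.

Each trial is the sum of three parts:

1. 1/f^beta Gaussian background noise, independent per channel (unit variance),
2. an ongoing, spatially broad 10 Hz background oscillation with random phase
   and per-trial amplitude (so single trials show both alpha enhancement and
   suppression relative to baseline), and
3. the planted object code: a band-limited oscillation at the center of
   ``shared_band`` whose channel loading is the participant's object pattern
   (restricted to posterior channels), whose envelope is nonzero only inside
   the task's latency window (50 ms raised-cosine ramps at the edges), and
   whose phase is uniformly random per trial unless ``phase_locked`` is set.

The object patterns are identical for the two tasks — that is the ground
truth "shared representation" every downstream analysis is asked to recover.
With random per-trial phases the planted code is induced power only: it is
invisible to trial-averaged broadband analysis but recoverable from
single-trial oscillatory power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import montage
from .epochs import EpochSet


@dataclass
class SimConfig:
    """Ground-truth generation parameters.

    Windows and latencies are ms intervals relative to stimulus / word onset.
    ``snr`` is the amplitude of the planted (unit-norm) pattern oscillation
    relative to the unit-variance per-channel background noise.
    """

    n_participants: int = 38
    n_channels: int = 63
    n_objects: int = 12
    trials_per_object_per_task: int = 80
    sampling_rate: float = 1000.0
    perception_window: tuple[float, float] = (-600.0, 1100.0)
    imagery_window: tuple[float, float] = (-600.0, 3100.0)
    shared_band: tuple[float, float] = (8.0, 13.0)
    perception_latency: tuple[float, float] = (200.0, 600.0)
    imagery_latency: tuple[float, float] = (600.0, 2300.0)
    snr: float = 1.2
    posterior_fraction: float = 0.25
    phase_locked: bool = False
    noise_exponent: float = 1.0
    background_alpha_amp: float = 0.5
    background_alpha_freq: float = 10.0
    ramp_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not (0 < self.posterior_fraction <= 1):
            raise ValueError("posterior_fraction must be in (0, 1]")
        for name in ("perception", "imagery"):
            lo, hi = getattr(self, f"{name}_window")
            if lo > -600.0:
                raise ValueError(
                    f"{name}_window must include >= 600 ms pre-stimulus padding"
                )
            llo, lhi = getattr(self, f"{name}_latency")
            if not (lo <= llo < lhi <= hi):
                raise ValueError(f"{name} latency window outside epoch window")

    @property
    def carrier_freq(self) -> float:
        return 0.5 * (self.shared_band[0] + self.shared_band[1])


@dataclass
class GroundTruth:
    """What was planted for one participant."""

    object_patterns: np.ndarray  # (n_objects, n_channels), zero off signal channels
    signal_channels: list[str]
    shared_band: tuple[float, float]
    latency_windows: dict[str, tuple[float, float]]
    carrier_freq: float
    phases: dict[str, np.ndarray] = field(default_factory=dict)  # per-trial phases


def _participant_rng(config: SimConfig, participant_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(participant_index,))
    return np.random.default_rng(ss)


def _channel_names(n_channels: int) -> list[str]:
    if n_channels == len(montage.EASYCAP_63):
        return list(montage.EASYCAP_63)
    return [f"CH{i:02d}" for i in range(n_channels)]


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, int], n_times: int, exponent: float
) -> np.ndarray:
    """1/f^exponent noise, unit variance per trace, synthesized spectrally."""
    n_freqs = n_times // 2 + 1
    freqs = np.fft.rfftfreq(n_times)
    amp = np.zeros(n_freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((*shape, n_freqs)) + 1j * rng.standard_normal((*shape, n_freqs))
    ) * amp
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _envelope(times_s: np.ndarray, latency_s: tuple[float, float], ramp_s: float) -> np.ndarray:
    """Unit plateau inside the latency window, raised-cosine ramps at its edges.

    The ramps live inside the window so signal energy outside it is exactly 0.
    """
    lo, hi = latency_s
    env = np.zeros_like(times_s)
    inside = (times_s >= lo) & (times_s < hi)
    env[inside] = 1.0
    if ramp_s > 0:
        up = inside & (times_s < lo + ramp_s)
        env[up] = 0.5 * (1 - np.cos(np.pi * (times_s[up] - lo) / ramp_s))
        down = inside & (times_s >= hi - ramp_s)
        env[down] = 0.5 * (1 - np.cos(np.pi * (hi - times_s[down]) / ramp_s))
    return env


def _draw_patterns(
    rng: np.random.Generator,
    n_objects: int,
    n_signal: int,
    model_features: np.ndarray | None,
) -> np.ndarray:
    """Unit-norm object loadings over the signal channels.

    Without a model: independent standard-normal rows.  With a model feature
    matrix (n_objects x n_features): a random linear read-out of the z-scored
    features, so pattern correlations approximate feature correlations and the
    cohort shares the model's representational geometry.
    """
    if model_features is None:
        pat = rng.standard_normal((n_objects, n_signal))
    else:
        feats = np.asarray(model_features, dtype=float)
        if feats.shape[0] != n_objects:
            raise ValueError("model feature matrix must have one row per object")
        mu = feats.mean(axis=1, keepdims=True)
        sd = feats.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature row")
        z = (feats - mu) / sd
        w = rng.standard_normal((feats.shape[1], n_signal)) / np.sqrt(feats.shape[1])
        pat = z @ w
    pat /= np.linalg.norm(pat, axis=1, keepdims=True)
    return pat


@dataclass
class ParticipantEpochs:
    """The two task recordings of one participant (different epoch lengths)."""

    perception: EpochSet
    imagery: EpochSet

    def __iter__(self):
        yield self.perception
        yield self.imagery

    def __getitem__(self, task: str) -> EpochSet:
        if task == "perception":
            return self.perception
        if task == "imagery":
            return self.imagery
        raise KeyError(task)


def generate_participant(
    config: SimConfig,
    participant_index: int,
    model_features: np.ndarray | None = None,
) -> tuple[EpochSet, GroundTruth]:
    """One participant's epochs for both tasks plus the planted ground truth.

    Deterministic given ``(config.seed, participant_index)``.
    """
    rng = _participant_rng(config, participant_index)
    channels = _channel_names(config.n_channels)
    n_signal = max(1, int(round(config.posterior_fraction * config.n_channels)))
    signal_names = montage.posterior_signal_channels(channels, n_signal)
    signal_idx = montage.channel_indices(channels, signal_names)

    loadings = _draw_patterns(rng, config.n_objects, n_signal, model_features)
    patterns = np.zeros((config.n_objects, config.n_channels))
    patterns[:, signal_idx] = loadings

    bg_topo = np.clip(rng.normal(1.0, 0.3, size=config.n_channels), 0.0, None)

    dt = 1.0 / config.sampling_rate
    task_data: dict[str, np.ndarray] = {}
    task_phases: dict[str, np.ndarray] = {}
    objects_per_task: dict[str, np.ndarray] = {}
    for task in ("perception", "imagery"):
        win = getattr(config, f"{task}_window")
        latency = getattr(config, f"{task}_latency")
        n_times = int(round((win[1] - win[0]) / 1000.0 * config.sampling_rate))
        times_s = win[0] / 1000.0 + np.arange(n_times) * dt
        n_trials = config.n_objects * config.trials_per_object_per_task
        objects = np.repeat(
            np.arange(1, config.n_objects + 1), config.trials_per_object_per_task
        )

        data = _pink_noise(
            rng, (n_trials, config.n_channels), n_times, config.noise_exponent
        )

        # ongoing broad 10 Hz background, random phase + amplitude per trial
        bg_phase = rng.uniform(0, 2 * np.pi, size=n_trials)
        bg_amp = rng.gamma(shape=4.0, scale=0.25, size=n_trials)
        osc = np.cos(
            2 * np.pi * config.background_alpha_freq * times_s[None, :] + bg_phase[:, None]
        )
        data += (
            config.background_alpha_amp
            * bg_amp[:, None, None]
            * bg_topo[None, :, None]
            * osc[:, None, :]
        )

        # planted object-specific band-limited oscillation
        env = _envelope(times_s, (latency[0] / 1000.0, latency[1] / 1000.0),
                        config.ramp_ms / 1000.0)
        if config.phase_locked:
            phases = np.zeros(n_trials)
        else:
            phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        carrier = np.cos(
            2 * np.pi * config.carrier_freq * times_s[None, :] + phases[:, None]
        )
        signal_t = config.snr * env[None, :] * carrier  # (n_trials, n_times)
        data += patterns[objects - 1][:, :, None] * signal_t[:, None, :]

        task_data[task] = data
        task_phases[task] = phases
        objects_per_task[task] = objects

    # the two tasks have different epoch lengths, so they cannot share one
    # trial x channel x time array; return them as a perception/imagery pair
    truth = GroundTruth(
        object_patterns=patterns,
        signal_channels=signal_names,
        shared_band=config.shared_band,
        latency_windows={
            "perception": config.perception_latency,
            "imagery": config.imagery_latency,
        },
        carrier_freq=config.carrier_freq,
        phases=task_phases,
    )
    epochs = {}
    for task in ("perception", "imagery"):
        win = getattr(config, f"{task}_window")
        n_times = task_data[task].shape[-1]
        times = win[0] + np.arange(n_times) * 1000.0 / config.sampling_rate
        epochs[task] = EpochSet(
            data=task_data[task],
            task=np.array([task] * task_data[task].shape[0]),
            object_id=objects_per_task[task],
            times=times,
            channels=channels,
            sampling_rate=config.sampling_rate,
        )
    return ParticipantEpochs(epochs["perception"], epochs["imagery"]), truth


def generate_cohort(
    config: SimConfig,
    model_features: np.ndarray | None = None,
) -> list[tuple[ParticipantEpochs, GroundTruth]]:
    """Independent participants; independent pattern draws per participant.

    When ``model_features`` is given, every participant's patterns realize the
    same representational geometry (pattern dissimilarities approximate the
    model's 1-Pearson RDM) through participant-specific random read-outs.
    """
    if config.n_participants < 1:
        raise ValueError("need at least one participant")
    return [
        generate_participant(config, i, model_features=model_features)
        for i in range(config.n_participants)
    ]
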