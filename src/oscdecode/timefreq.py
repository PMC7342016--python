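"""Morlet time-frequency decomposition of induced oscillatory power.

The decomposition convolves every trial and channel with complex Morlet
wavelets of a fixed temporal support (default 600 ms at every frequency, so
spectral bandwidth shrinks with frequency), takes the magnitude of the complex
coefficient per time point ("absolute power", computed before any trial
averaging, hence induced rather than evoked power), normalizes it in dB
against a pre-stimulus baseline, averages it into 20 ms bins (50 Hz temporal
resolution) and finally aggregates the 20 logarithmically spaced frequency
bins (5-31 Hz) into theta (5-7 Hz, 5 bins), alpha (8-13 Hz, 6 bins) and beta
(14-31 Hz, 9 bins) bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft

from .epochs import EpochSet

#: nominal integer band edges (inclusive) used throughout
DEFAULT_BANDS: dict[str, tuple[int, int]] = {
    "theta": (5, 7),
    "alpha": (8, 13),
    "beta": (14, 31),
}


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmically spaced wavelet center frequencies (Hz)."""

    centers: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if len(c) < 1 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("grid centers must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band and the grid bins it aggregates."""

    name: str
    nominal_range: tuple[int, int]
    member_bins: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.member_bins)


@dataclass
class TFEpochs:
    """Trial x channel x frequency-bin x time (induced) power.

    ``power`` holds wavelet coefficient magnitudes before normalization and
    dB values relative to baseline afterwards (``normalized`` flag).
    """

    power: np.ndarray  # (n_trials, n_channels, n_bins, n_times)
    times: np.ndarray  # ms
    grid: FrequencyGrid
    channels: list[str]
    task: np.ndarray
    object_id: np.ndarray
    sampling_rate: float  # temporal resolution of `times`, Hz
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None

    def select_channels(self, names: list[str]) -> "TFEpochs":
        from .montage import channel_indices

        idx = channel_indices(self.channels, names)
        return replace(
            self,
            power=self.power[:, idx, :, :],
            channels=[self.channels[i] for i in idx],
        )

    def crop(self, tmin: float, tmax: float) -> "TFEpochs":
        mask = (self.times >= tmin) & (self.times < tmax)
        if not mask.any():
            raise ValueError("crop window contains no samples")
        return replace(self, power=self.power[..., mask], times=self.times[mask])


def log_spaced_grid(f_min: float, f_max: float, n_bins: int = 20) -> FrequencyGrid:
    """Geometric grid ``f_min * (f_max/f_min)**(i/(n_bins-1))``, i = 0..n_bins-1."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    centers = f_min * (f_max / f_min) ** (np.arange(n_bins) / (n_bins - 1))
    return FrequencyGrid(tuple(centers))


def assign_bands(
    grid: FrequencyGrid,
    nominal_ranges: dict[str, tuple[int, int]] | None = None,
) -> list[BandSpec]:
    """Assign every grid bin to the band whose integer range contains it.

    Bin centers are rounded to the nearest integer Hz before testing
    membership; every bin must land in exactly one range and every band must
    receive at least one bin.  With the default 20-bin 5-31 Hz grid this
    yields the 5/6/9 theta/alpha/beta split.
    """
    ranges = nominal_ranges if nominal_ranges is not None else DEFAULT_BANDS
    members: dict[str, list[int]] = {name: [] for name in ranges}
    for i, center in enumerate(grid.centers):
        rounded = int(np.floor(center + 0.5))  # round half up, not to even
        hits = [name for name, (lo, hi) in ranges.items() if lo <= rounded <= hi]
        if len(hits) != 1:
            raise ValueError(
                f"bin {i} ({center:.3f} Hz, rounds to {rounded}) matches "
                f"{len(hits)} band ranges"
            )
        members[hits[0]].append(i)
    for name, bins in members.items():
        if not bins:
            raise ValueError(f"band {name!r} received no frequency bins")
    return [
        BandSpec(name=name, nominal_range=tuple(ranges[name]), member_bins=tuple(bins))
        for name, bins in members.items()
    ]


def morlet_wavelet(
    freq: float, sampling_rate: float, length_ms: float = 600.0, edge_sigmas: float = 3.0
) -> np.ndarray:
    """Complex Morlet wavelet with fixed temporal support ``length_ms``.

    The Gaussian envelope's standard deviation is ``(length_ms/2)/edge_sigmas``
    so the truncation edges sit at ``edge_sigmas`` sigma.  A zero-mean
    correction term keeps the wavelet admissible at low frequencies, and the
    amplitude is scaled so a unit-amplitude sinusoid at ``freq`` yields a
    coefficient magnitude of 1.
    """
    if freq <= 0 or length_ms <= 0:
        raise ValueError("freq and length_ms must be positive")
    half = length_ms / 2000.0  # s
    n_half = int(round(half * sampling_rate))
    t = np.arange(-n_half, n_half + 1) / sampling_rate
    sigma = half / edge_sigmas
    envelope = np.exp(-(t**2) / (2 * sigma**2))
    carrier = np.exp(2j * np.pi * freq * t)
    # admissibility: subtract the (tiny) DC component of the windowed carrier
    correction = np.exp(-0.5 * (2 * np.pi * freq * sigma) ** 2)
    wavelet = (carrier - correction) * envelope
    wavelet /= envelope.sum() / 2.0
    return wavelet


def morlet_power(
    epochs: EpochSet,
    grid: FrequencyGrid,
    wavelet_length_ms: float = 600.0,
    dtype=np.float32,
) -> TFEpochs:
    """Single-trial wavelet magnitude per channel, frequency bin and time.

    The epoch must start at least half a wavelet before stimulus onset (the
    pre-stimulus padding that keeps edge effects away from the analysis
    window); the convolution itself is zero-padded at the epoch edges, so the
    outermost ``wavelet_length/2`` of the epoch is attenuated and should be
    covered by padding rather than analysed.
    """
    pre = -epochs.times[0]
    if pre < wavelet_length_ms / 2:
        raise ValueError(
            f"pre-stimulus padding ({pre:.0f} ms) shorter than half the "
            f"wavelet ({wavelet_length_ms / 2:.0f} ms)"
        )
    if epochs.times[-1] - epochs.times[0] < wavelet_length_ms:
        raise ValueError("epoch shorter than the wavelet")
    wavelets = [
        morlet_wavelet(f, epochs.sampling_rate, wavelet_length_ms) for f in grid.centers
    ]
    n_trials, n_channels, n_times = epochs.data.shape
    n_kernel = len(wavelets[0])
    half = (n_kernel - 1) // 2
    out = np.empty((n_trials, n_channels, len(grid), n_times), dtype=dtype)
    # FFT the data once and reuse it across all wavelet frequencies; single
    # precision halves time and memory and is ample for dB power
    work_dtype = np.complex64 if dtype == np.float32 else np.complex128
    L = sfft.next_fast_len(n_times + n_kernel - 1, real=False)
    data = epochs.data.astype(np.float32 if dtype == np.float32 else np.float64)
    D = sfft.fft(data, n=L, axis=-1).astype(work_dtype)
    for fi, wav in enumerate(wavelets):
        K = sfft.fft(wav.astype(work_dtype), n=L)
        coef = sfft.ifft(D * K, axis=-1)
        out[:, :, fi, :] = np.abs(coef[..., half : half + n_times])
    return TFEpochs(
        power=out,
        times=epochs.times.copy(),
        grid=grid,
        channels=list(epochs.channels),
        task=epochs.task.copy(),
        object_id=epochs.object_id.copy(),
        sampling_rate=epochs.sampling_rate,
        normalized=False,
    )


def baseline_normalize(
    tf: TFEpochs, baseline_window: tuple[float, float] = (-500.0, -300.0)
) -> TFEpochs:
    """dB change relative to the pre-stimulus baseline, per trial/channel/bin.

    value -> 10 * log10(value / mean over the baseline window).
    """
    if tf.normalized:
        raise ValueError("TFEpochs already normalized")
    lo, hi = baseline_window
    mask = (tf.times >= lo) & (tf.times <= hi)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = tf.power[..., mask].mean(axis=-1, keepdims=True, dtype=tf.power.dtype)
    if np.any(base <= 0):
        raise ValueError("nonpositive baseline mean; cannot form dB ratio")
    power = np.divide(tf.power, base)
    np.log10(power, out=power)
    power *= np.asarray(10.0, dtype=power.dtype)
    return replace(tf, power=power, normalized=True, baseline_window=(lo, hi))


def downsample(tf: TFEpochs, target_rate: float = 50.0) -> TFEpochs:
    """Average power in non-overlapping bins of ``1000/target_rate`` ms.

    Bins are left-closed/right-open and anchored at the first sample of the
    epoch; the output timestamp is the bin start.  An incomplete trailing bin
    is dropped.
    """
    factor = tf.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of target_rate")
    factor = int(round(factor))
    if factor == 1:
        return replace(tf, power=tf.power.copy(), times=tf.times.copy())
    n_times = tf.power.shape[-1]
    n_out = n_times // factor
    if n_out == 0:
        raise ValueError("epoch shorter than one output bin")
    trimmed = tf.power[..., : n_out * factor]
    shape = trimmed.shape[:-1] + (n_out, factor)
    power = trimmed.reshape(shape).mean(axis=-1, dtype=np.float64)
    times = tf.times[: n_out * factor : factor].copy()
    return replace(
        tf, power=power.astype(tf.power.dtype), times=times, sampling_rate=float(target_rate)
    )


def band_vectors(tf: TFEpochs, band: BandSpec, mode: str = "average") -> np.ndarray:
    """Unfold band-limited power into per-trial pattern vectors.

    mode="average"     -> (n_trials, n_channels, n_times): bins averaged, one
                          value per electrode (a 63-element vector for the
                          reference montage).
    mode="concatenate" -> (n_trials, n_members * n_channels, n_times): bins
                          stacked along the feature axis.
    """
    if len(band) == 0:
        raise ValueError("empty band")
    if max(band.member_bins) >= tf.power.shape[2]:
        raise ValueError("band refers to bins outside the grid")
    sub = tf.power[:, :, list(band.member_bins), :]  # (tr, ch, m, t)
    if mode == "average":
        return sub.mean(axis=2)
    if mode == "concatenate":
        n_trials, n_channels, m, n_times = sub.shape
        return sub.transpose(0, 2, 1, 3).reshape(n_trials, m * n_channels, n_times)
    raise ValueError(f"unknown mode {mode!r}")


def decompose(
    epochs: EpochSet,
    grid: FrequencyGrid | None = None,
    wavelet_length_ms: float = 600.0,
    baseline_window: tuple[float, float] = (-500.0, -300.0),
    target_rate: float = 50.0,
) -> TFEpochs:
    """Full decomposition chain: Morlet -> dB baseline -> 50 Hz bins.

    Numerically equivalent to composing :func:`morlet_power`,
    :func:`baseline_normalize` and :func:`downsample`, but processes one
    wavelet frequency at a time so the full-rate 4-D power array is never
    materialized (the per-frequency intermediates are the memory bound).
    """
    if grid is None:
        grid = log_spaced_grid(5.0, 31.0, 20)
    pre = -epochs.times[0]
    if pre < wavelet_length_ms / 2:
        raise ValueError(
            f"pre-stimulus padding ({pre:.0f} ms) shorter than half the "
            f"wavelet ({wavelet_length_ms / 2:.0f} ms)"
        )
    factor = epochs.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of target_rate")
    factor = int(round(factor))

    n_trials, n_channels, n_times = epochs.data.shape
    n_out = n_times // factor
    lo, hi = baseline_window
    bmask = (epochs.times >= lo) & (epochs.times <= hi)
    if not bmask.any():
        raise ValueError("baseline window outside epoch")

    wavelets = [
        morlet_wavelet(f, epochs.sampling_rate, wavelet_length_ms) for f in grid.centers
    ]
    n_kernel = len(wavelets[0])
    half = (n_kernel - 1) // 2
    L = sfft.next_fast_len(n_times + n_kernel - 1, real=False)
    D = sfft.fft(epochs.data.astype(np.float32), n=L, axis=-1)
    out = np.empty((n_trials, n_channels, len(grid), n_out), dtype=np.float32)
    ten = np.float32(10.0)
    for fi, wav in enumerate(wavelets):
        K = sfft.fft(wav.astype(np.complex64), n=L)
        power = np.abs(sfft.ifft(D * K, axis=-1)[..., half : half + n_times])
        base = power[..., bmask].mean(axis=-1, keepdims=True, dtype=np.float32)
        if np.any(base <= 0):
            raise ValueError("nonpositive baseline mean; cannot form dB ratio")
        power /= base
        np.log10(power, out=power)
        power *= ten
        out[:, :, fi, :] = power[..., : n_out * factor].reshape(
            n_trials, n_channels, n_out, factor
        ).mean(axis=-1, dtype=np.float32)
    return TFEpochs(
        power=out,
        times=epochs.times[: n_out * factor : factor].copy(),
        grid=grid,
        channels=list(epochs.channels),
        task=epochs.task.copy(),
        object_id=epochs.object_id.copy(),
        sampling_rate=float(target_rate),
        normalized=True,
        baseline_window=(lo, hi),
    )
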