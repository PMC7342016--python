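"""Sensor montage utilities for a 63-channel 10-10 EEG layout.

The reference montage is a 64-electrode EASYCAP arrangement referenced to Fz,
leaving 63 data channels.  For spatial localization the scalp is split into an
anterior half (frontal, fronto-temporal, temporal and central rows) and a
posterior half (centro-parietal, parietal, parieto-occipital and occipital
rows); central and temporal channels belong to both halves, so the two halves
overlap and together cover all 63 electrodes (35 anterior, 37 posterior).
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

# 63 data channels (10-10 names, Fz used as online reference and absent).
EASYCAP_63: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

# Letter groups per half; central (C) and temporal (T) rows are in both.
ANTERIOR_GROUPS = frozenset({"Fp", "AF", "F", "FT", "FC", "T", "C"})
POSTERIOR_GROUPS = frozenset({"C", "T", "CP", "TP", "P", "PO", "O"})

# Rows ordered from the back of the head forward; used to pick the channels
# that carry a planted posterior pattern in simulations.
_POSTERIOR_ONLY_ORDER = ("O", "PO", "P", "TP", "CP")

_NAME_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def channel_group(name: str) -> str:
    """Return the 10-10 row label of a channel name, e.g. ``'CP5' -> 'CP'``.

    Raises ``ValueError`` for names that do not follow the ``<letters><index>``
    convention (index is a digit string or ``z`` for midline).
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unrecognized channel name: {name!r}")
    group = m.group(1)
    if group not in ANTERIOR_GROUPS | POSTERIOR_GROUPS:
        raise ValueError(f"channel {name!r} belongs to unknown row {group!r}")
    return group


def electrode_halves(channels: Sequence[str]) -> dict[str, list[str]]:
    """Split channel names into overlapping anterior/posterior halves.

    Returns ``{"anterior": [...], "posterior": [...]}`` preserving the input
    order.  Central and temporal channels appear in both lists.
    """
    halves: dict[str, list[str]] = {"anterior": [], "posterior": []}
    for name in channels:
        group = channel_group(name)
        if group in ANTERIOR_GROUPS:
            halves["anterior"].append(name)
        if group in POSTERIOR_GROUPS:
            halves["posterior"].append(name)
    return halves


def posterior_signal_channels(channels: Sequence[str], n_signal: int) -> list[str]:
    """Pick ``n_signal`` channels for a planted posterior pattern.

    Channels are taken from rows exclusive to the posterior half, ordered from
    the occipital pole forward, so that an anterior-half analysis sees none of
    them.  For montages that do not use 10-10 names the last ``n_signal``
    channels are returned instead.
    """
    if n_signal <= 0 or n_signal > len(channels):
        raise ValueError("n_signal must be in 1..n_channels")
    try:
        groups = {name: channel_group(name) for name in channels}
    except ValueError:
        return list(channels[-n_signal:])
    picked: list[str] = []
    for row in _POSTERIOR_ONLY_ORDER:
        picked.extend(name for name in channels if groups[name] == row)
    if len(picked) < n_signal:
        raise ValueError(
            f"montage has only {len(picked)} posterior-exclusive channels, "
            f"{n_signal} requested"
        )
    return picked[:n_signal]


def channel_indices(channels: Sequence[str], subset: Iterable[str]) -> list[int]:
    """Indices of ``subset`` names within ``channels`` (order of ``channels``)."""
    wanted = set(subset)
    missing = wanted - set(channels)
    if missing:
        raise ValueError(f"channels not in montage: {sorted(missing)}")
    return [i for i, name in enumerate(channels) if name in wanted]
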