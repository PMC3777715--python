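"""Electrode montage constants for the 29-channel 10-20 recording layout.

The montage is the 29 Ag/AgCl scalp sites of an extended international
10-20 layout with a nose reference, plus vertical and horizontal EOG
channels used only for ocular-artifact regression.
"""

from __future__ import annotations

#: Scalp EEG channels, in recording order.
MONTAGE_29: tuple[str, ...] = (
    "Fp1", "Fp2", "AFz", "Fz", "F4", "F8", "F3", "F7",
    "FCz", "FC4", "FT8", "FC3", "FT7",
    "Cz", "C4", "T8", "C3", "T7",
    "CPz", "CP4", "CP3",
    "Pz", "P4", "P8", "P3", "P7",
    "Oz", "O2", "O1",
)

#: Ocular channels recorded alongside the EEG.
EOG_CHANNELS: tuple[str, str] = ("VEOG", "HEOG")

#: Fronto-central / centro-parietal sites carrying the planted alpha deficit.
DEFAULT_EFFECT_CHANNELS: frozenset[str] = frozenset({"F4", "FC3", "FC4", "Cz", "CPz"})

#: Conventional EEG frequency bands, Hz (low edge, high edge).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 50.0),
}

N_CHANNELS = len(MONTAGE_29)
N_PAIRS = N_CHANNELS * (N_CHANNELS - 1) // 2  # 406 unordered channel pairs


def channel_index(labels: tuple[str, ...] | list[str], name: str) -> int:
    """Index of ``name`` in ``labels``, with a helpful error."""
    try:
        return list(labels).index(name)
    except ValueError:
        raise KeyError(f"channel {name!r} not present in montage {list(labels)}") from None
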