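"""Core in-memory containers: raw recordings and epoched data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .montage import EOG_CHANNELS, MONTAGE_29


@dataclass
class Recording:
    """A single subject's multichannel recording, in microvolts.

    Parameters
    ----------
    subject_id
        Subject token, e.g. ``"P001"``.
    fs
        Sampling rate in Hz.
    channel_labels
        Channel names in row order of ``samples``. Scalp channels must be
        drawn from the 29-site montage; EOG channels are optional.
    samples
        ``(n_channels, n_samples)`` array of voltages in microvolts.
    meta
        Free-form provenance (planted artifact positions, simulation
        latents, EOG regression coefficients, ...).
    """

    subject_id: str
    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.samples.shape[0]} sample rows"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_labels if c not in EOG_CHANNELS)

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channel_labels) if c not in EOG_CHANNELS],
            dtype=int,
        )

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            i = self.channel_labels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording {self.subject_id}") from None
        return self.samples[i]

    def validate_montage(self) -> None:
        """Raise unless the scalp channels are exactly the 29-site montage."""
        if self.eeg_labels != MONTAGE_29:
            raise ValueError(
                f"recording {self.subject_id}: scalp channels do not match the "
                f"29-site montage (got {self.eeg_labels})"
            )


@dataclass
class EpochSet:
    """Epoched multichannel data: ``(n_epochs, n_channels, n_samples)`` in uV.

    ``rejected_mask`` flags epochs whose pre-baseline voltage exceeded the
    artifact threshold; rejected epochs are retained in ``data`` so that
    selection can skip them while preserving temporal order.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    rejected_mask: np.ndarray
    band: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel label count does not match epoch data")
        if self.rejected_mask.shape != (self.data.shape[0],):
            raise ValueError("rejected_mask must have one flag per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def retained(self) -> np.ndarray:
        """Data of the non-rejected epochs, in temporal order."""
        return self.data[~self.rejected_mask]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected_mask).sum())
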