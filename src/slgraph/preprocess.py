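"""Preprocessing chain: EOG regression, epoching/rejection, decimation, band filters.

The chain reproduces a standard resting-EEG cleaning pipeline: ocular
artifacts are regressed out using the recorded EOG channels, the record is
cut into consecutive 2-s epochs, epochs with any scalp sample exceeding
+/-150 uV are rejected, the first 10 clean baseline-corrected epochs are
kept, the data are decimated from 1000 to 250 Hz, and five band-pass
filtered copies (delta through gamma) are produced for the connectivity
stage. All filters are zero-phase (forward-backward Butterworth), which
matters because the synchronization measure downstream is phase-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording
from .montage import BANDS, EOG_CHANNELS

__all__ = [
    "PreprocessConfig",
    "correct_eog",
    "epoch_and_reject",
    "downsample",
    "bandpass",
    "select_epochs",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the cleaning chain (defaults follow the study design)."""

    epoch_seconds: float = 2.0
    reject_uV: float = 150.0
    target_fs: float = 250.0
    n_keep: int = 10
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    filter_order: int = 4

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} edges must be strictly increasing")


def correct_eog(rec: Recording) -> Recording:
    """Remove ocular contamination from scalp channels by linear regression.

    Each scalp channel is regressed on VEOG and HEOG (plus an intercept)
    over the whole recording and the fitted EOG contribution is
    subtracted; the propagation coefficients are stored in
    ``meta['eog_betas']`` as ``{label: (beta_veog, beta_heog)}``. The EOG
    channels themselves pass through unmodified.
    """
    for name in EOG_CHANNELS:
        if name not in rec.channel_labels:
            raise ValueError(
                f"recording {rec.subject_id}: EOG channel {name!r} required for "
                "ocular correction is missing"
            )
    veog = rec.channel("VEOG")
    heog = rec.channel("HEOG")
    X = np.column_stack([np.ones_like(veog), veog, heog])
    corrected = rec.samples.copy()
    betas: dict[str, tuple[float, float]] = {}
    eeg_idx = rec.eeg_indices
    coef, *_ = np.linalg.lstsq(X, rec.samples[eeg_idx].T, rcond=None)
    for row, ci in enumerate(eeg_idx):
        b_v, b_h = float(coef[1, row]), float(coef[2, row])
        corrected[ci] = rec.samples[ci] - b_v * veog - b_h * heog
        betas[rec.channel_labels[ci]] = (b_v, b_h)
    meta = dict(rec.meta)
    meta["eog_betas"] = betas
    return Recording(subject_id=rec.subject_id, fs=rec.fs,
                     channel_labels=rec.channel_labels, samples=corrected, meta=meta)


def epoch_and_reject(rec: Recording, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Cut into consecutive non-overlapping epochs and flag artifacts.

    The rejection rule is applied to the scalp channels only, before
    baseline correction: an epoch is rejected if any single sample exceeds
    the threshold in absolute value. Retained and rejected epochs are then
    baseline-corrected by subtracting each channel's within-epoch mean.
    Only scalp channels are carried into the returned EpochSet; the EOG
    channels have served their purpose by this point.
    """
    cfg = cfg or PreprocessConfig()
    epoch_len = int(round(cfg.epoch_seconds * rec.fs))
    n_epochs = rec.n_samples // epoch_len
    if n_epochs < 1:
        raise ValueError(
            f"recording {rec.subject_id} shorter than one epoch "
            f"({rec.n_samples} < {epoch_len} samples)"
        )
    eeg = rec.samples[rec.eeg_indices][:, : n_epochs * epoch_len]
    data = eeg.reshape(eeg.shape[0], n_epochs, epoch_len).transpose(1, 0, 2).copy()
    rejected = (np.abs(data) > cfg.reject_uV).any(axis=(1, 2))
    if rejected.all():
        raise ValueError(f"all epochs rejected for recording {rec.subject_id}")
    data -= data.mean(axis=2, keepdims=True)  # baseline correction
    return EpochSet(data=data, fs=rec.fs, channel_labels=rec.eeg_labels,
                    rejected_mask=rejected, subject_id=rec.subject_id)


def select_epochs(ep: EpochSet, n_keep: int) -> EpochSet:
    """Keep the first ``n_keep`` artifact-free epochs, in temporal order."""
    clean = np.flatnonzero(~ep.rejected_mask)
    if clean.size < n_keep:
        raise ValueError(
            f"only {clean.size} clean epochs available, {n_keep} requested"
        )
    keep = clean[:n_keep]
    return EpochSet(data=ep.data[keep], fs=ep.fs, channel_labels=ep.channel_labels,
                    rejected_mask=np.zeros(n_keep, dtype=bool), band=ep.band,
                    subject_id=ep.subject_id)


def downsample(ep: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Anti-alias filter and decimate each epoch to the target rate.

    The low-pass cutoff sits at 0.4x the target rate (100 Hz for 250 Hz
    output), comfortably above the highest analysis band edge (50 Hz).
    A unit decimation factor returns the data unchanged.
    """
    cfg = cfg or PreprocessConfig()
    ratio = ep.fs / cfg.target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"sampling rate {ep.fs} is not an integer multiple of target "
            f"{cfg.target_fs}"
        )
    if q == 1:
        return ep
    sos = signal.butter(cfg.filter_order, 0.4 * cfg.target_fs, btype="lowpass",
                        fs=ep.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ep.data, axis=2)
    return EpochSet(data=filtered[:, :, ::q], fs=cfg.target_fs,
                    channel_labels=ep.channel_labels,
                    rejected_mask=ep.rejected_mask.copy(), band=ep.band,
                    subject_id=ep.subject_id)


def bandpass(ep: EpochSet, band: str, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Zero-phase Butterworth band-pass into one of the analysis bands."""
    cfg = cfg or PreprocessConfig()
    if band not in cfg.bands:
        raise ValueError(f"unknown band {band!r}; configured: {sorted(cfg.bands)}")
    lo, hi = cfg.bands[band]
    if ep.fs < 2 * hi:
        raise ValueError(
            f"band {band!r} upper edge {hi} Hz violates Nyquist at fs={ep.fs}"
        )
    sos = signal.butter(cfg.filter_order, (lo, hi), btype="bandpass", fs=ep.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, ep.data, axis=2)
    return EpochSet(data=filtered, fs=ep.fs, channel_labels=ep.channel_labels,
                    rejected_mask=ep.rejected_mask.copy(), band=band,
                    subject_id=ep.subject_id)


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig | None = None,
    bands: list[str] | None = None,
) -> dict[str, EpochSet]:
    """Full chain: EOG correction -> epoch/reject -> select -> decimate -> bands.

    Returns one band-filtered EpochSet per requested band (all configured
    bands by default).
    """
    cfg = cfg or PreprocessConfig()
    corrected = correct_eog(rec)
    epochs = epoch_and_reject(corrected, cfg)
    selected = select_epochs(epochs, cfg.n_keep)
    decimated = downsample(selected, cfg)
    out: dict[str, EpochSet] = {}
    for band in bands if bands is not None else list(cfg.bands):
        out[band] = bandpass(decimated, band, cfg)
    return out
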