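"""Synthetic resting-state EEG cohorts with a planted connectivity deficit.

The generator emulates the study design this package analyses: a two-group
cohort (bipolar-disorder patients vs. healthy controls) of eyes-closed
resting recordings on the 29-channel montage plus two EOG channels. Each
channel is a convex mixture of band-limited latent sources shared across
channels (the coupled part) and private band-limited noise,

    x_c(t) = sum_b a_b * [ c_{b,c} * s_b(t) + (1 - c_{b,c}) * p_{b,c}(t) ],

where ``s_b`` is the per-band shared source, ``p_{b,c}`` private noise,
``c_{b,c}`` the coupling strength in [0, 1] and ``a_b`` a fixed band
amplitude profile. Patients receive a reduced alpha-band coupling on a
fronto-central/centro-parietal channel set, which is the ground truth the
downstream synchronization-likelihood and network statistics must recover.

Clinical covariates (age, sex, IQ, education) and symptom scores
(YMRS, MADRS) are drawn to match the study's demographic table; the MADRS
score can be coupled to a per-subject latent severity with a controllable
correlation so that score-vs-network correlations are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .containers import Recording
from .montage import BANDS, DEFAULT_EFFECT_CHANNELS, EOG_CHANNELS, MONTAGE_29

__all__ = [
    "CohortSpec",
    "SubjectMeta",
    "generate_cohort",
    "plant_artifacts",
    "generate_scores",
]

# Relative RMS amplitude of each band before overall scaling; alpha dominates
# an eyes-closed resting spectrum, gamma is weakest.
_BAND_AMPLITUDE = {"delta": 1.0, "theta": 0.8, "alpha": 1.3, "beta": 0.6, "gamma": 0.3}

# Study demographics (group mean, SD) used for covariate sampling.
_DEMOGRAPHICS = {
    "patient": {"age": (41.2, 10.5), "iq": (102.8, 17.5), "education": (12.3, 3.2),
                "p_female": 32 / 57, "ymrs": (12.5, 10.7)},
    "control": {"age": (40.1, 10.6), "iq": (106.1, 14.7), "education": (14.2, 2.9),
                "p_female": 52 / 87, "ymrs": (0.0, 0.0)},
}

_MADRS_MEAN, _MADRS_SD = 13.0, 11.1


def _default_band_coupling() -> dict[str, dict[str, float]]:
    coupling = {b: {"control": 0.4, "patient": 0.4} for b in BANDS}
    coupling["gamma"] = {"control": 0.3, "patient": 0.3}
    # planted deficit: patients lose alpha coupling over the effect channels
    coupling["alpha"] = {"control": 0.6, "patient": 0.3}
    return coupling


@dataclass(frozen=True)
class SubjectMeta:
    """Demographic and clinical metadata for one subject."""

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "male" | "female"
    iq: float
    education: float
    ymrs: int
    madrs: int

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        if self.ymrs < 0 or self.madrs < 0:
            raise ValueError("clinical scores must be non-negative")


@dataclass
class CohortSpec:
    """Configuration of a synthetic two-group cohort.

    Defaults mirror the study conditions: 57 patients and 87 controls,
    120-s recordings at 1000 Hz on the 29-channel montage, with the
    patients' alpha-band coupling reduced over F4/FC3/FC4/Cz/CPz.
    """

    n_patients: int = 57
    n_controls: int = 87
    n_channels: int = 29
    fs: float = 1000.0
    duration: float = 120.0
    band_coupling: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_band_coupling
    )
    effect_channels: frozenset[str] = DEFAULT_EFFECT_CHANNELS
    artifact_rate: float = 2.0  # expected artifact epochs per recording
    score_coupling: float = 0.35  # corr(MADRS, latent alpha severity) in patients
    coupling_sd: float = 0.08  # between-subject SD of coupling strengths
    eog_leak: float = 0.12  # VEOG propagation coefficient into scalp channels
    rms_uV: float = 30.0  # per-channel RMS after scaling
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels != len(MONTAGE_29):
            raise ValueError(
                f"n_channels must equal the montage size {len(MONTAGE_29)}, "
                f"got {self.n_channels}"
            )
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        highest_edge = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * highest_edge:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({highest_edge} Hz)"
            )
        unknown = set(self.effect_channels) - set(MONTAGE_29)
        if unknown:
            raise ValueError(f"effect channels not in montage: {sorted(unknown)}")
        for band, per_group in self.band_coupling.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            for grp, c in per_group.items():
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"coupling must lie in [0,1], got {band}/{grp}={c}")
        if not -1.0 <= self.score_coupling <= 1.0:
            raise ValueError("score_coupling must lie in [-1, 1]")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")


def _band_sos(lo: float, hi: float, fs: float) -> np.ndarray:
    return signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = float(np.sqrt(np.mean(x**2)))
    return x / r if r > 0 else x


def _band_noise(rng: np.random.Generator, n: int, sos: np.ndarray) -> np.ndarray:
    return _unit_rms(signal.sosfiltfilt(sos, rng.standard_normal(n)))


def _eog_pair(rng: np.random.Generator, n: int, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Vertical/horizontal EOG: slow drift plus blink-like raised cosines."""
    sos = signal.butter(2, 3.0, btype="lowpass", fs=fs, output="sos")
    veog = 25.0 * _unit_rms(signal.sosfiltfilt(sos, rng.standard_normal(n)))
    heog = 18.0 * _unit_rms(signal.sosfiltfilt(sos, rng.standard_normal(n)))
    n_blinks = rng.poisson(10.0 * n / fs / 60.0)  # ~10 blinks/min
    blink_len = int(round(0.3 * fs))
    pulse = 250.0 * np.hanning(blink_len)
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(1, n - blink_len)))
        veog[start:start + blink_len] += pulse
    return veog, heog


def _subject_coupling(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], float]:
    """Per-channel coupling vectors for each band, plus the alpha latent.

    The returned latent is the subject's (jittered) alpha coupling on the
    effect channels; it drives the MADRS correlation for patients.
    """
    couplings: dict[str, np.ndarray] = {}
    alpha_latent = 0.0
    effect_idx = np.array([c in spec.effect_channels for c in MONTAGE_29])
    for band in BANDS:
        per_group = spec.band_coupling.get(band, {"control": 0.0, "patient": 0.0})
        base_control = float(per_group.get("control", 0.0))
        base_own = float(per_group.get(group, base_control))
        jitter = float(rng.normal(0.0, spec.coupling_sd))
        vec = np.full(len(MONTAGE_29), np.clip(base_control + jitter, 0.0, 1.0))
        if group == "patient":
            # patient coupling map applies only on the effect channels
            vec[effect_idx] = np.clip(base_own + jitter, 0.0, 1.0)
        if band == "alpha":
            alpha_latent = float(vec[effect_idx].mean()) if effect_idx.any() else float(vec.mean())
        couplings[band] = vec
    return couplings, alpha_latent


def _synth_recording(
    spec: CohortSpec, subject_id: str, group: str, rng: np.random.Generator
) -> Recording:
    n = int(round(spec.duration * spec.fs))
    sos_by_band = {b: _band_sos(lo, hi, spec.fs) for b, (lo, hi) in BANDS.items()}
    shared = {b: _band_noise(rng, n, sos_by_band[b]) for b in BANDS}
    couplings, alpha_latent = _subject_coupling(spec, group, rng)

    eeg = np.zeros((len(MONTAGE_29), n))
    for ci in range(len(MONTAGE_29)):
        x = np.zeros(n)
        for band in BANDS:
            c = couplings[band][ci]
            private = _band_noise(rng, n, sos_by_band[band])
            x += _BAND_AMPLITUDE[band] * (c * shared[band] + (1.0 - c) * private)
        eeg[ci] = x
    eeg *= spec.rms_uV / np.sqrt(np.mean(eeg**2, axis=1, keepdims=True))

    veog, heog = _eog_pair(rng, n, spec.fs)
    eeg += spec.eog_leak * veog + 0.5 * spec.eog_leak * heog

    samples = np.vstack([eeg, veog[None, :], heog[None, :]])
    labels = MONTAGE_29 + EOG_CHANNELS
    meta = {
        "group": group,
        "alpha_coupling_latent": alpha_latent,
        "eog_leak": (spec.eog_leak, 0.5 * spec.eog_leak),
    }
    return Recording(subject_id=subject_id, fs=spec.fs, channel_labels=labels,
                     samples=samples, meta=meta)


def _sample_meta(
    subject_id: str, group: str, rng: np.random.Generator
) -> dict[str, object]:
    d = _DEMOGRAPHICS[group]
    age = float(np.clip(rng.normal(*d["age"]), 20.0, 58.0))
    sex = "female" if rng.random() < d["p_female"] else "male"
    iq = float(rng.normal(*d["iq"]))
    education = float(np.clip(rng.normal(*d["education"]), 6.0, 22.0))
    ymrs = int(max(0, round(rng.normal(*d["ymrs"])))) if group == "patient" else 0
    return {"subject_id": subject_id, "group": group, "age": round(age, 1),
            "sex": sex, "iq": round(iq, 1), "education": round(education, 1),
            "ymrs": ymrs}


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], list[SubjectMeta]]:
    """Simulate a full two-group cohort of recordings plus metadata.

    Deterministic under ``spec.seed``: one master seed spawns independent
    per-subject streams, so cohorts are bit-identical across runs.

    Patients' MADRS scores are anti-correlated with their latent alpha
    coupling at ``spec.score_coupling`` (lower coupling, higher depression
    score); controls score zero on both clinical scales.
    """
    spec.validate()
    n_total = spec.n_patients + spec.n_controls
    children = np.random.SeedSequence(spec.seed).spawn(n_total + 1)
    score_rng_seed = children[-1]

    recordings: list[Recording] = []
    meta_rows: list[dict[str, object]] = []
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    counters = {"patient": 0, "control": 0}
    for i, group in enumerate(groups):
        counters[group] += 1
        sid = ("P%03d" if group == "patient" else "C%03d") % counters[group]
        rng = np.random.default_rng(children[i])
        rec = _synth_recording(spec, sid, group, rng)
        if spec.artifact_rate > 0:
            rec = plant_artifacts(rec, spec.artifact_rate,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        recordings.append(rec)
        meta_rows.append(_sample_meta(sid, group, rng))

    # MADRS: coupled to the patients' latent alpha severity.
    patient_idx = [i for i, g in enumerate(groups) if g == "patient"]
    madrs = {i: 0 for i in range(n_total)}
    if patient_idx:
        latents = np.array(
            [recordings[i].meta["alpha_coupling_latent"] for i in patient_idx]
        )
        if len(patient_idx) >= 3 and np.std(latents) > 0:
            scores = generate_scores(-latents, spec,
                                     seed=int(np.random.default_rng(score_rng_seed)
                                              .integers(0, 2**31 - 1)))
        else:
            rng = np.random.default_rng(score_rng_seed)
            scores = np.maximum(
                0, np.round(rng.normal(_MADRS_MEAN, _MADRS_SD, len(patient_idx)))
            ).astype(int)
        for i, s in zip(patient_idx, scores):
            madrs[i] = int(s)

    metas = [SubjectMeta(madrs=madrs[i], **meta_rows[i]) for i in range(n_total)]
    return recordings, metas


def plant_artifacts(
    recording: Recording, rate: float, seed: int, epoch_seconds: float = 2.0
) -> Recording:
    """Insert high-amplitude transients into randomly chosen epochs.

    Each artifact is a 200-ms raised-cosine pulse of 400 uV added to one
    randomly chosen scalp channel, centered in its epoch, so it
    unambiguously crosses the +/-150 uV rejection threshold. The number of
    artifacts is Poisson(``rate``), capped at the epoch count; planted
    epoch indices are recorded in ``meta['artifact_epochs']``.
    """
    if rate < 0:
        raise ValueError("artifact rate must be non-negative")
    rng = np.random.default_rng(seed)
    epoch_len = int(round(epoch_seconds * recording.fs))
    n_epochs = recording.n_samples // epoch_len
    n_art = min(int(rng.poisson(rate)), n_epochs)
    samples = recording.samples.copy()
    planted: list[int] = []
    channels: list[str] = []
    if n_art > 0:
        epochs = np.sort(rng.choice(n_epochs, size=n_art, replace=False))
        pulse_len = int(round(0.2 * recording.fs))
        pulse = 400.0 * 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(pulse_len) / pulse_len))
        eeg_idx = recording.eeg_indices
        for e in epochs:
            ci = int(rng.choice(eeg_idx))
            start = e * epoch_len + (epoch_len - pulse_len) // 2
            samples[ci, start:start + pulse_len] += pulse
            planted.append(int(e))
            channels.append(recording.channel_labels[ci])
    meta = dict(recording.meta)
    meta["artifact_epochs"] = planted
    meta["artifact_channels"] = channels
    return Recording(subject_id=recording.subject_id, fs=recording.fs,
                     channel_labels=recording.channel_labels, samples=samples,
                     meta=meta)


def generate_scores(
    metrics: Sequence[float] | np.ndarray, spec: CohortSpec, seed: int
) -> np.ndarray:
    """Draw MADRS-like integer scores correlated with a per-subject metric.

    The population correlation between the scores (before clipping) and
    ``metrics`` equals ``spec.score_coupling``; the marginal distribution
    emulates the study's MADRS summary (mean 13.0, SD 11.1), rounded and
    clipped to non-negative integers.
    """
    m = np.asarray(metrics, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("metrics must be a 1-D vector of at least 2 values")
    sd = m.std()
    if sd == 0:
        raise ValueError("metric vector is constant; correlation undefined")
    rho = float(spec.score_coupling)
    rng = np.random.default_rng(seed)
    z = (m - m.mean()) / sd
    latent = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(m.size)
    raw = _MADRS_MEAN + _MADRS_SD * latent
    return np.maximum(0, np.round(raw)).astype(int)


def meta_to_frame(metas: Iterable[SubjectMeta]):
    """Tidy metadata table (one row per subject)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id, "group": m.group, "age": m.age,
                "sex": m.sex, "iq": m.iq, "education": m.education,
                "ymrs": m.ymrs, "madrs": m.madrs,
            }
            for m in metas
        ]
    )
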