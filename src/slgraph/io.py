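"""File formats: delimited recordings, EDF, SL matrices, metadata tables.

Recordings travel either as European Data Format (EDF, 16-bit) or as a
human-inspectable tab-delimited matrix (one column per channel, header
row of labels, leading comment line carrying the subject id and sampling
rate). EDF reading is delegated to mne; a minimal EDF writer is
implemented here since the simulated cohorts must be exportable without
any optional dependency. SL matrices are written as tab-delimited square
tables with a JSON sidecar manifest (subject, band, embedding
parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording
from .sl import EmbeddingParams, SLMatrix

__all__ = [
    "write_recording",
    "read_recording",
    "write_edf",
    "write_sl_matrix",
    "read_sl_matrix",
    "write_metadata",
    "read_metadata",
]


# ---------------------------------------------------------------------------
# delimited recordings


def _write_tsv(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# subject={rec.subject_id} fs={rec.fs!r}\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.17g", delimiter="\t")


def _read_tsv(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# subject=... fs=...' comment line")
        fields = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        for key in ("subject", "fs"):
            if key not in fields:
                raise ValueError(f"{path}: header field {key!r} missing")
        try:
            fs = float(fields["fs"])
        except ValueError:
            raise ValueError(f"{path}: header field 'fs' is not numeric") from None
        labels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {len(labels)} labels but {data.shape[1]} sample columns"
        )
    return Recording(subject_id=fields["subject"], fs=fs,
                     channel_labels=tuple(labels), samples=data.T)


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (one 1-s data record per second).

    The sampling rate must be an integer; a trailing partial second is
    truncated. Physical units are microvolts; quantization error is
    bounded by the per-channel physical range divided by 2^16.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {rec.fs}")
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_sig = len(rec.channel_labels)
    data = rec.samples[:, : n_rec * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    with open(path, "wb") as fh:
        header_bytes = 256 * (1 + n_sig)
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(rec.subject_id, 80))
        fh.write(_edf_field("slgraph recording", 80))
        fh.write(_edf_field("01.01.01", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_rec, 8))
        fh.write(_edf_field(1, 8))
        fh.write(_edf_field(n_sig, 4))
        for lab in rec.channel_labels:
            fh.write(_edf_field(lab, 16))
        for _ in rec.channel_labels:
            fh.write(_edf_field("AgAgCl electrode", 80))
        for _ in rec.channel_labels:
            fh.write(_edf_field("uV", 8))
        for v in pmin:
            fh.write(_edf_field(f"{v:.2f}"[:8], 8))
        for v in pmax:
            fh.write(_edf_field(f"{v:.2f}"[:8], 8))
        for _ in rec.channel_labels:
            fh.write(_edf_field(dmin, 8))
        for _ in rec.channel_labels:
            fh.write(_edf_field(dmax, 8))
        for _ in rec.channel_labels:
            fh.write(_edf_field("", 80))
        for _ in rec.channel_labels:
            fh.write(_edf_field(fs, 8))
        for _ in rec.channel_labels:
            fh.write(_edf_field("", 32))
        for r in range(n_rec):
            for s in range(n_sig):
                fh.write(digital[s, r * fs:(r + 1) * fs].tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(
            str(path), eog=["VEOG", "HEOG"], preload=True, verbose="error"
        )
    except Exception as err:  # mne raises various parse errors
        raise ValueError(f"{path}: failed to parse EDF header ({err})") from err
    data = raw.get_data(units={t: "uV" for t in raw.get_channel_types()})
    return Recording(subject_id=path.stem, fs=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names), samples=data)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as ``tsv`` or ``edf`` (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "tsv":
        _write_tsv(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from ``tsv`` or ``edf``; units are microvolts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# SL matrices and metadata


def write_sl_matrix(
    m: SLMatrix, path: str | Path, params: EmbeddingParams | None = None
) -> None:
    """Square tab-delimited matrix with label header + JSON sidecar manifest."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(m.labels) + "\n")
        np.savetxt(fh, m.values, fmt="%.17g", delimiter="\t")
    manifest = {
        "subject_id": m.subject_id,
        "band": m.band,
        "labels": list(m.labels),
        "params": asdict(params) if params is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))


def read_sl_matrix(path: str | Path) -> SLMatrix:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    subject_id = band = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        manifest = json.loads(sidecar.read_text())
        subject_id = manifest.get("subject_id")
        band = manifest.get("band")
    return SLMatrix(values=values, labels=tuple(labels), subject_id=subject_id,
                    band=band)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "iq", "education", "ymrs", "madrs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata columns missing: {sorted(missing)}")
    return df
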